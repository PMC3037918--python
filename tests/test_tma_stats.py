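"""Staining statistics: exact tests, rank tests, odds ratios, logistic fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rankscreen as rs
from rankscreen.errors import DataError

from oracles import (
    chi2_textbook,
    fisher_exact_enumeration,
    permutation_kruskal_p,
    permutation_rank_sum_p,
)

NORMAL_SCORES = [0] * 20 + [2]
PAC_NODM_SCORES = [0] * 28 + [1] * 7 + [2] * 2
PAC_DM_SCORES = [0] * 5 + [1] * 3 + [2] * 1 + [3] * 1


class TestBinarize:
    @pytest.mark.parametrize("score, expected", [(0, 0), (1, 1), (2, 1), (3, 1)])
    def test_default_cutoff(self, score, expected):
        assert rs.binarize_stain(score) == expected

    def test_custom_cutoff(self):
        assert rs.binarize_stain(2, cutoff=3) == 0

    def test_invalid_score(self):
        with pytest.raises(DataError):
            rs.binarize_stain(4)


class TestAssembleCohort:
    def make(self, labels):
        return pd.DataFrame(
            {"sample_id": range(len(labels)), "diagnosis_label": labels}
        )

    def test_empty_exclusion_is_identity(self):
        df = self.make(["a", "b"])
        kept, tally = rs.assemble_cohort(df, set())
        assert len(kept) == 2 and tally == {}

    def test_all_excluded(self):
        df = self.make(["a", "a", "b"])
        kept, tally = rs.assemble_cohort(df, {"a", "b"})
        assert kept.empty and tally == {"a": 2, "b": 1}

    def test_mixed_exclusion(self):
        labels = ["PaC"] * 7 + ["chronic pancreatitis"] * 3
        kept, tally = rs.assemble_cohort(self.make(labels), {"chronic pancreatitis"})
        assert len(kept) == 7
        assert tally == {"chronic pancreatitis": 3}


class TestContingency:
    def test_reference_binary_table(self, reference_cohort):
        df = reference_cohort.copy()
        df["positive"] = rs.binarize_stain(df["score"].to_numpy())
        ct = rs.build_contingency(df, "group", "positive")
        assert ct.loc["normal", 1] == 1 and ct.loc["normal", 0] == 20
        assert ct.loc["PaC", 1] == 18 and ct.loc["PaC", 0] == 42

    def test_three_strata_positives(self, reference_cohort):
        df = reference_cohort.copy()
        df["positive"] = rs.binarize_stain(df["score"].to_numpy())
        df["stratum"] = rs.stratify_dm(df)
        ct = rs.build_contingency(df, "stratum", "positive")
        assert ct.loc["normal", 1] == 1
        assert ct.loc["PaC no DM", 1] == 9
        assert ct.loc["PaC-DM", 1] == 5

    def test_single_sample(self):
        df = pd.DataFrame({"a": ["x"], "b": ["y"]})
        ct = rs.build_contingency(df, "a", "b")
        assert ct.to_numpy().tolist() == [[1]]

    def test_empty_cohort_errors(self):
        with pytest.raises(DataError):
            rs.build_contingency(pd.DataFrame(columns=["a", "b"]), "a", "b")


class TestFisher:
    def test_balanced_table(self):
        assert rs.fisher_exact_2x2([[2, 2], [2, 2]]).p_value == 1.0

    def test_small_table_vs_enumeration(self):
        table = [[1, 4], [3, 2]]
        assert rs.fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_exact_enumeration(table), abs=1e-10
        )

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = rs.fisher_exact_2x2([[0, 0], [3, 4]])
        assert result.p_value == 1.0

    def test_doubling_rule_at_least_min_likelihood(self):
        table = [[1, 9], [8, 2]]
        p_min = rs.fisher_exact_2x2(table).p_value
        p_double = rs.fisher_exact_2x2(table, rule="double").p_value
        assert p_double >= p_min - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40)
    def test_random_tables_match_enumeration(self, seed):
        """Exact-arithmetic enumeration agreement on all tables with n <= 30."""
        rng = np.random.default_rng(seed)
        cells = rng.multinomial(int(rng.integers(4, 31)), [0.25] * 4).reshape(2, 2)
        if (cells.sum(0) == 0).any() or (cells.sum(1) == 0).any():
            return
        assert rs.fisher_exact_2x2(cells).p_value == pytest.approx(
            fisher_exact_enumeration(cells), abs=1e-10
        )


class TestChi2:
    def test_independent_table_statistic_zero(self):
        assert rs.pearson_chi2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0, abs=1e-12)
        assert rs.pearson_chi2([[10, 20], [5, 10]]).p_value == pytest.approx(1.0)

    def test_reference_binary_table(self):
        result = rs.pearson_chi2([[1, 20], [18, 42]])
        assert result.statistic == pytest.approx(5.52, abs=0.01)
        assert result.df == 1

    def test_zero_margin_errors(self):
        with pytest.raises(DataError):
            rs.pearson_chi2([[0, 0], [3, 4]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_random_2x3_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 20, size=(2, 3))
        stat, df, p = chi2_textbook(table)
        result = rs.pearson_chi2(table)
        assert result.statistic == pytest.approx(stat, abs=1e-10)
        assert result.df == df
        assert result.p_value == pytest.approx(p, abs=1e-10)


class TestRankTests:
    def test_identical_groups(self):
        result = rs.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_all_tied_values(self):
        assert rs.wilcoxon_rank_sum([2, 2], [2, 2, 2]).p_value == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(DataError):
            rs.wilcoxon_rank_sum([], [1.0])

    def test_reference_pacdm_vs_normal(self):
        result = rs.wilcoxon_rank_sum(NORMAL_SCORES, PAC_DM_SCORES)
        assert result.p_value == pytest.approx(0.004, abs=5e-4)

    def test_significant_instance_matches_permutation(self):
        """In the significance tail the normal approximation tracks the
        exhaustive permutation p closely even at 4+4 tied scores."""
        a, b = [0, 0, 0, 1], [2, 2, 3, 3]
        p_perm = permutation_rank_sum_p(a, b)  # 2/70
        assert abs(rs.wilcoxon_rank_sum(a, b).p_value - p_perm) < 0.02

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20)
    def test_small_groups_tail_agreement_with_permutation(self, seed):
        """Tail agreement: wherever the exact permutation p is <= 0.05 the
        approximation lands within 0.05 of it (the approximation is known
        to understate large p under heavy ties, so the body is not
        compared)."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=4).tolist()
        b = rng.integers(0, 4, size=4).tolist()
        if len(set(a + b)) == 1:
            return
        p_perm = permutation_rank_sum_p(a, b)
        if p_perm <= 0.05:
            assert abs(rs.wilcoxon_rank_sum(a, b).p_value - p_perm) < 0.05

    def test_kw_two_identical_groups(self):
        result = rs.kruskal_wallis([[1, 2, 2], [1, 2, 2]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_kw_all_identical_guarded(self):
        result = rs.kruskal_wallis([[3, 3], [3, 3, 3]])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_kw_matches_independent_formula(self):
        groups = [[1, 2, 2], [3, 1, 0], [2, 3, 3]]
        # from-scratch: H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1), tie-divided
        pooled = np.concatenate(groups)
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        n = len(pooled)
        offsets = np.cumsum([0] + [len(g) for g in groups])
        h = sum(
            ranks[offsets[i]: offsets[i + 1]].sum() ** 2 / len(g)
            for i, g in enumerate(groups)
        )
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
        assert rs.kruskal_wallis(groups).statistic == pytest.approx(h, abs=1e-10)

    def test_kw_significant_instance_matches_permutation(self):
        groups = [[0, 0, 1], [1, 2, 2], [3, 3, 2]]
        p_perm = permutation_kruskal_p(groups)  # 3/140
        assert abs(rs.kruskal_wallis(groups).p_value - p_perm) < 0.02

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_two_group_kw_equals_squared_rank_sum_z(self, seed):
        """Tie-corrected KW chi-square == z^2 of the rank-sum test for k=2."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=int(rng.integers(2, 10))).tolist()
        b = rng.integers(0, 4, size=int(rng.integers(2, 10))).tolist()
        if len(set(a + b)) == 1:
            return
        wrs = rs.wilcoxon_rank_sum(a, b)
        kw = rs.kruskal_wallis([a, b])
        assert kw.statistic == pytest.approx(wrs.statistic**2, abs=1e-9)
        assert kw.p_value == pytest.approx(wrs.p_value, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20)
    def test_sample_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=8)
        b = rng.integers(0, 4, size=6)
        before = rs.wilcoxon_rank_sum(a, b)
        after = rs.wilcoxon_rank_sum(rng.permutation(a), rng.permutation(b))
        assert before.statistic == pytest.approx(after.statistic, abs=1e-12)


class TestBonferroni:
    def test_single_p_unchanged(self):
        assert rs.bonferroni([0.01]) == [0.01]

    def test_three_p_scaled(self):
        np.testing.assert_allclose(
            rs.bonferroni([0.004, 0.07, 0.09]), [0.012, 0.21, 0.27]
        )

    def test_capped_at_one(self):
        assert rs.bonferroni([0.5, 0.9]) == [1.0, 1.0]

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            rs.bonferroni([1.5])


class TestOddsRatio:
    def test_reference_table(self):
        result = rs.odds_ratio_woolf([[18, 42], [1, 20]])
        assert result.odds_ratio == pytest.approx(8.571, abs=1e-3)
        assert result.ci_low == pytest.approx(1.0677, abs=1e-3)
        assert not result.haldane_corrected

    def test_balanced_table_symmetric_ci(self):
        result = rs.odds_ratio_woolf([[5, 5], [5, 5]])
        assert result.odds_ratio == pytest.approx(1.0)
        assert np.log(result.ci_low) == pytest.approx(-np.log(result.ci_high), abs=1e-12)

    def test_zero_cell_haldane(self):
        result = rs.odds_ratio_woolf([[0, 10], [5, 5]])
        assert result.haldane_corrected
        assert result.ci_low <= result.odds_ratio <= result.ci_high

    def test_zero_diagonal_undefined(self):
        with pytest.raises(DataError):
            rs.odds_ratio_woolf([[0, 5], [3, 0]])

    def test_matches_statsmodels_table2x2(self):
        import statsmodels.api as sm

        table = np.array([[18, 42], [1, 20]])
        t22 = sm.stats.Table2x2(table)
        result = rs.odds_ratio_woolf(table)
        assert result.odds_ratio == pytest.approx(t22.oddsratio, abs=1e-10)
        lo, hi = t22.oddsratio_confint()
        assert result.ci_low == pytest.approx(lo, abs=1e-10)
        assert result.ci_high == pytest.approx(hi, abs=1e-10)


class TestLogistic:
    def test_crude_or_equals_cross_product_ratio(self):
        """Saturated 2x2 logistic: exp(coef) == ad/bc exactly."""
        y = np.array([1] * 18 + [0] * 42 + [1] * 1 + [0] * 20, dtype=float)
        x = np.array([1.0] * 60 + [0.0] * 21)
        X = pd.DataFrame({"intercept": 1.0, "pac": x})
        result = rs.logistic_fit(y, X)
        assert result.status == "ok"
        assert result.table.loc["pac", "odds_ratio"] == pytest.approx(18 * 20 / 42, abs=1e-6)

    def test_constant_predictor_degenerate(self):
        y = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        X = pd.DataFrame({"intercept": 1.0, "c": 1.0}, index=range(6))
        assert rs.logistic_fit(y, X).status == "degenerate"

    def test_single_class_outcome_errors(self):
        X = pd.DataFrame({"intercept": np.ones(6), "x": np.arange(6.0)})
        with pytest.raises(DataError):
            rs.logistic_fit(np.zeros(6), X)

    def test_separation_flagged(self):
        x = np.arange(10.0)
        y = (x > 4).astype(float)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        assert rs.logistic_fit(y, X).status == "separation"

    def test_monte_carlo_recovery(self):
        """Estimated log-OR over 50 seeds centers on the true value 1.0."""
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.binomial(1, 0.5, size=500).astype(float)
            logit_p = -0.5 + 1.0 * x
            y = rng.random(500) < 1 / (1 + np.exp(-logit_p))
            X = pd.DataFrame({"intercept": 1.0, "x": x})
            result = rs.logistic_fit(y.astype(float), X)
            estimates.append(result.table.loc["x", "coef"])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 1.0) < 3 * se


class TestSummaries:
    def test_median_range_format(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "age": [26.0, 59.0, 79.0, 45.0, 64.0, 79.0],
                "sex": ["F", "M", "F", "M", "M", "F"],
                "dm": pd.array([True, False, False, True, True, False], dtype="boolean"),
                "tobacco": pd.array([None] * 6, dtype="boolean"),
                "alcohol": pd.array([None] * 6, dtype="boolean"),
            }
        )
        summary = rs.summarize_cohort(df).set_index("characteristic")
        assert summary.loc["Age", "a"] == "59 (26-79)"

    def test_identical_groups_p_one(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 4 + ["b"] * 4,
                "age": [50.0, 60.0, 70.0, 80.0] * 2,
                "sex": ["F", "F", "M", "M"] * 2,
            }
        )
        summary = rs.summarize_cohort(df).set_index("characteristic")
        assert summary.loc["Age", "p"] == pytest.approx(1.0)
        assert summary.loc["Female", "p"] == pytest.approx(1.0)

    def test_rank_sum_consistency_on_synthetic_cohort(self):
        cfg = rs.TMACohortConfig(
            group_sizes={"normal": 30, "PaC": 40},
            score_probs={"normal": (0.9, 0.1, 0, 0), "PaC": (0.5, 0.3, 0.15, 0.05)},
            covariate_params={
                "normal": rs.CovariateParams(age_mean=55),
                "PaC": rs.CovariateParams(age_mean=65),
            },
            seed=9,
        )
        cohort = rs.generate_tma_cohort(cfg)
        summary = rs.summarize_cohort(cohort).set_index("characteristic")
        direct = rs.wilcoxon_rank_sum(
            cohort.loc[cohort["group"] == "PaC", "age"],
            cohort.loc[cohort["group"] == "normal", "age"],
        )
        assert summary.loc["Age", "p"] == pytest.approx(direct.p_value, abs=1e-12)


class TestAnalyzeStainingCohort:
    def test_reference_results_block(self, reference_cohort):
        res = rs.analyze_staining_cohort(reference_cohort)
        assert res["binary_table"]["cells"] == [[1, 20], [18, 42]]
        assert res["fisher_exact"]["p_value"] == pytest.approx(0.0183, abs=1e-3)
        assert res["odds_ratio"]["odds_ratio"] == pytest.approx(8.571, abs=1e-3)
        assert res["stratified"]["positive"] == {"normal": 1, "PaC no DM": 9, "PaC-DM": 5}

    def test_json_serializable(self, reference_cohort):
        import json

        json.dumps(rs.analyze_staining_cohort(reference_cohort))

    def test_cutoff_changes_binarization(self, reference_cohort):
        res = rs.analyze_staining_cohort(reference_cohort, cutoff=2)
        # at cutoff 2 only scores 2-3 count as positive: 1 normal, 6 PaC
        assert res["binary_table"]["cells"][0][0] == 1
        assert res["binary_table"]["cells"][1][0] == 6
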