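"""Validation statistics for ordinal immunohistochemistry staining cohorts.

Implements the statistical toolkit used to validate a candidate marker on a
tissue microarray: staining binarization (positive = score >= cutoff),
cohort assembly with exclusion tallies, contingency tables, Fisher's exact
test (two-sided by the minimum-likelihood rule), Pearson chi-square,
tie-corrected Wilcoxon rank-sum and Kruskal-Wallis tests, Bonferroni
adjustment, Woolf odds-ratio confidence intervals, and binary logistic
regression.

Conventions:

* The rank-sum test uses the normal approximation with tie-corrected
  variance and *no* continuity correction, so that for two groups its
  squared z statistic equals the tie-corrected Kruskal-Wallis chi-square
  exactly.
* Pairwise group contrasts operate on the 0-3 score, not the binarized
  variable; binary comparisons use Fisher's exact test (expected cells in
  sparse staining tables are routinely below 5).
* A 2x2 table with any zero cell gets the Haldane-Anscombe +0.5 correction
  before the odds ratio is formed, and the result is flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import DataError

logger = logging.getLogger(__name__)

SCORE_LEVELS = (0, 1, 2, 3)

#: the three analysis strata defined jointly by group and diabetes status
STRATA = ("normal", "PaC no DM", "PaC-DM")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    adjusted: bool = False
    n_comparisons: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)
        if self.adjusted and self.n_comparisons is None:
            raise ValueError("adjusted result must record n_comparisons")


@dataclass
class OddsRatioResult:
    """Odds ratio with a Woolf (log-scale Wald) confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    haldane_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("odds ratio must lie inside its confidence interval")


@dataclass
class LogisticResult:
    """Per-predictor estimates from a binary logistic fit.

    ``status`` is ``"ok"``, ``"separation"`` (diverging coefficients:
    estimates are unreliable and reported for diagnosis only) or
    ``"degenerate"`` (rank-deficient design: no estimates).
    """

    table: pd.DataFrame
    status: str = "ok"
    converged: bool = True


# ---------------------------------------------------------------------------
# cohort handling
# ---------------------------------------------------------------------------


def binarize_stain(score: int | np.ndarray | pd.Series, cutoff: int = 1):
    """Positive staining indicator: 1 iff score >= cutoff (default 1)."""
    arr = np.asarray(score)
    if not np.isin(arr, SCORE_LEVELS).all():
        raise DataError(f"staining scores must lie in {SCORE_LEVELS}")
    out = (arr >= cutoff).astype(int)
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def assemble_cohort(
    samples: pd.DataFrame, exclusion_labels: Iterable[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop samples whose diagnosis label is excluded; tally exclusions."""
    excl = set(exclusion_labels)
    mask = samples["diagnosis_label"].isin(excl)
    tally = samples.loc[mask, "diagnosis_label"].value_counts().to_dict()
    return samples.loc[~mask].reset_index(drop=True), {k: int(v) for k, v in tally.items()}


def stratify_dm(samples: pd.DataFrame) -> pd.Series:
    """Assign each core to normal / PaC no DM / PaC-DM (NA when unknown).

    Normal cores form one stratum regardless of diabetes status; tumor
    cores with missing diabetes status are excluded from stratified
    analyses (returned as NA).
    """
    out = pd.Series(pd.NA, index=samples.index, dtype="object")
    out[samples["group"] == "normal"] = "normal"
    pac = samples["group"] == "PaC"
    out[pac & (samples["dm"] == False)] = "PaC no DM"  # noqa: E712 (nullable boolean)
    out[pac & (samples["dm"] == True)] = "PaC-DM"  # noqa: E712
    return out


def build_contingency(
    samples: pd.DataFrame, row_factor: str, col_factor: str
) -> pd.DataFrame:
    """Cross-tabulate two factor columns into a contingency table.

    Rows with a missing value in either factor are dropped, with the count
    logged; an empty cohort is an error.
    """
    if samples.empty:
        raise DataError("cannot build a contingency table from an empty cohort")
    sub = samples[[row_factor, col_factor]]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info(
            "build_contingency(%s x %s): dropped %d rows with missing factor values",
            row_factor, col_factor, n_dropped,
        )
    if complete.empty:
        raise DataError("no complete cases for the requested factors")
    return pd.crosstab(complete[row_factor], complete[col_factor])


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise DataError("contingency cells must be non-negative integers")
    return arr


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table, rule: str = "min_likelihood") -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The default two-sided p sums hypergeometric probabilities of all
    tables (margins fixed) no more likely than the observed one; the
    alternative ``rule="double"`` doubles the smaller one-sided tail
    (capped at 1).  A degenerate margin (zero row or column total) carries
    no information: p = 1 with a warning.
    """
    arr = _as_2x2(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return TestResult("fisher_exact", statistic=float("nan"), p_value=1.0)
    a = int(arr[0, 0])
    r1, r2 = int(arr[0].sum()), int(arr[1].sum())
    c1 = int(arr[:, 0].sum())
    odds, p_min = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    if rule == "min_likelihood":
        p = float(p_min)
    elif rule == "double":
        dist = stats.hypergeom(r1 + r2, r1, c1)
        p = float(min(1.0, 2.0 * min(dist.cdf(a), dist.sf(a - 1))))
    else:
        raise ValueError(f"unknown two-sided rule {rule!r}")
    return TestResult("fisher_exact", statistic=float(odds), p_value=min(p, 1.0))


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("chi-square undefined for a table with a zero margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult("pearson_chi2", statistic=float(stat), p_value=float(p), df=int(df))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test, tie-corrected normal approximation.

    z = (W - mu) / sigma with W the rank sum of the first group (average
    ranks for ties), mu = n1 (N + 1) / 2 and
    sigma^2 = (n1 n2 / 12) [(N + 1) - sum(t^3 - t) / (N (N - 1))].
    No continuity correction is applied.  When all values across both
    groups are identical the test carries no information: z = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("rank-sum test needs two non-empty groups")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = stats.rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return TestResult("wilcoxon_rank_sum", statistic=0.0, p_value=1.0)
    z = (w - mu) / np.sqrt(var)
    return TestResult(
        "wilcoxon_rank_sum", statistic=float(z), p_value=float(2 * stats.norm.sf(abs(z)))
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis test across k groups (chi-square, k-1 df)."""
    if len(groups) < 2:
        raise DataError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DataError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.unique(pooled).size == 1:  # all observations identical: C = 0
        return TestResult("kruskal_wallis", statistic=0.0, p_value=1.0, df=df)
    stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", statistic=float(stat), p_value=float(p), df=df)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p * m capped at 1, order preserved."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise DataError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]


def odds_ratio_woolf(table, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio ad/bc with the Woolf log-scale confidence interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction of all
    four cells (flagged in the result).  A zero diagonal (a = d = 0 or
    b = c = 0 before correction with both diagonals empty) leaves the
    ratio undefined.
    """
    arr = _as_2x2(table)
    a, b, c, d = arr.ravel()
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise DataError("odds ratio undefined: a full diagonal of the table is zero")
    corrected = False
    if (arr == 0).any():
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - z * se)),
        ci_high=float(np.exp(np.log(or_) + z * se)),
        level=level,
        haldane_corrected=corrected,
    )


def logistic_fit(outcome, predictors, level: float = 0.95) -> LogisticResult:
    """Binary logistic regression by Newton/IRLS maximum likelihood.

    `predictors` is a design matrix that already includes the intercept
    column.  Convergence at max coefficient change < 1e-8 within 100
    iterations.  Complete separation and rank-deficient designs are
    detected and reported as a distinct status rather than silent numbers.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors)
    if y.size <= X.shape[1]:
        raise DataError("need more observations than predictors")
    if np.unique(y).size < 2:
        raise DataError("outcome must contain both classes")
    empty = pd.DataFrame(
        columns=["coef", "se", "odds_ratio", "ci_low", "ci_high", "p_value"],
        index=X.columns,
        dtype=float,
    )
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        return LogisticResult(empty, status="degenerate", converged=False)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        except (PerfectSeparationWarning, np.linalg.LinAlgError, Exception) as exc:
            if isinstance(exc, (PerfectSeparationWarning, np.linalg.LinAlgError)) or (
                "Perfect separation" in str(exc)
            ):
                return LogisticResult(empty, status="separation", converged=False)
            raise
    z = stats.norm.ppf(0.5 + level / 2.0)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(fit.params - z * fit.bse),
            "ci_high": np.exp(fit.params + z * fit.bse),
            "p_value": fit.pvalues,
        }
    )
    converged = bool(fit.mle_retvals.get("converged", True))
    if np.abs(fit.params).max() > 20:  # coefficients this large mean quasi-separation
        separated = True
    return LogisticResult(
        table, status="separation" if separated else "ok", converged=converged
    )


# ---------------------------------------------------------------------------
# cohort-level reports
# ---------------------------------------------------------------------------


def summarize_cohort(
    samples: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = ("age",),
    categorical: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group clinical summary with bivariate p-values.

    Continuous variables are reported as ``median (min-max)`` and compared
    by the rank-sum test (Kruskal-Wallis when there are more than two
    groups); categorical variables as ``count (%)`` compared by Fisher's
    exact test (chi-square beyond 2x2).  Missing covariates are excluded
    per variable (complete-case), with the analyzed denominators logged
    and returned.
    """
    if samples.empty:
        raise DataError("cannot summarize an empty cohort")
    if categorical is None:
        categorical = {
            "Female": "sex",
            "History of Tobacco Use": "tobacco",
            "History of Alcohol Use": "alcohol",
            "Diabetes Mellitus": "dm",
        }
        categorical = {k: v for k, v in categorical.items() if v in samples.columns}
    groups = sorted(samples[group_col].dropna().unique())
    rows = []
    for var in continuous:
        sub = samples[[group_col, var]].dropna()
        per_group = {g: sub.loc[sub[group_col] == g, var].to_numpy() for g in groups}
        cells = {
            g: f"{np.median(v):g} ({v.min():g}-{v.max():g})" if v.size else "-"
            for g, v in per_group.items()
        }
        nonempty = [v for v in per_group.values() if v.size]
        if len(nonempty) < 2:
            p = np.nan
        elif len(groups) == 2:
            p = wilcoxon_rank_sum(nonempty[0], nonempty[1]).p_value
        else:
            p = kruskal_wallis(nonempty).p_value
        logger.info("summarize_cohort: %s analyzed on n=%d complete cases", var, len(sub))
        rows.append({"characteristic": var.capitalize(), **cells, "p": p, "n_analyzed": len(sub)})
    for label, col in categorical.items():
        sub = samples[[group_col, col]].dropna()
        if sub.empty:
            continue
        if col == "sex":
            positive = sub[col] == "F"
        else:
            positive = sub[col].astype(bool)
        ct = pd.crosstab(sub[group_col], positive)
        cells = {}
        for g in groups:
            n_g = int((sub[group_col] == g).sum())
            k = int(positive[sub[group_col] == g].sum())
            cells[g] = f"{k} ({100 * k / n_g:.0f}%)" if n_g else "-"
        if ct.shape == (2, 2):
            p = fisher_exact_2x2(ct.to_numpy()).p_value
        elif 0 in ct.shape or 1 in ct.shape:
            p = np.nan
        else:
            p = pearson_chi2(ct.to_numpy()).p_value
        logger.info("summarize_cohort: %s analyzed on n=%d complete cases", label, len(sub))
        rows.append({"characteristic": label, **cells, "p": p, "n_analyzed": len(sub)})
    return pd.DataFrame(rows)


def analyze_staining_cohort(samples: pd.DataFrame, cutoff: int = 1) -> dict:
    """Full staining analysis of a normal-vs-tumor TMA cohort.

    Produces the two-group binary comparison (Fisher, chi-square, odds
    ratio with Woolf CI, crude logistic), the three-stratum comparisons
    (Kruskal-Wallis on binary and on the 0-3 score), and the pairwise
    score rank-sum tests with Bonferroni adjustment.  Returns a nested,
    JSON-serializable dict.
    """
    df = samples.copy()
    df["positive"] = binarize_stain(df["score"].to_numpy(), cutoff=cutoff)
    df["stratum"] = stratify_dm(df)
    groups = sorted(df["group"].dropna().unique())
    if len(groups) != 2:
        raise DataError(f"expected two diagnosis groups, got {groups}")
    ref, other = ("normal", [g for g in groups if g != "normal"][0]) if "normal" in groups else groups

    binary_ct = build_contingency(df, "group", "positive")
    # orient rows (reference, comparison) x columns (positive, negative)
    t22 = np.array(
        [
            [binary_ct.loc[ref].get(1, 0), binary_ct.loc[ref].get(0, 0)],
            [binary_ct.loc[other].get(1, 0), binary_ct.loc[other].get(0, 0)],
        ],
        dtype=int,
    )
    fisher = fisher_exact_2x2(t22)
    chi2 = pearson_chi2(t22)
    # odds of staining in the comparison group relative to the reference
    or_table = t22[::-1]
    oddsr = odds_ratio_woolf(or_table)
    X = pd.DataFrame(
        {"intercept": 1.0, "is_" + other: (df["group"] == other).astype(float)}
    )
    logit_res = logistic_fit(df["positive"].to_numpy(), X)

    score_ct = build_contingency(df, "group", "score")
    score_wrs = wilcoxon_rank_sum(
        df.loc[df["group"] == ref, "score"], df.loc[df["group"] == other, "score"]
    )
    score_chi2 = pearson_chi2(score_ct.to_numpy()) if (score_ct.to_numpy().sum(0) > 0).all() else None

    strata_present = [s for s in STRATA if (df["stratum"] == s).any()]
    strat = {}
    if len(strata_present) >= 2:
        by = {s: df.loc[df["stratum"] == s] for s in strata_present}
        strat["n"] = {s: int(len(by[s])) for s in strata_present}
        strat["positive"] = {s: int(by[s]["positive"].sum()) for s in strata_present}
        strat["kruskal_wallis_binary"] = _result_dict(
            kruskal_wallis([by[s]["positive"].to_numpy() for s in strata_present])
        )
        strat["kruskal_wallis_score"] = _result_dict(
            kruskal_wallis([by[s]["score"].to_numpy() for s in strata_present])
        )
        pairs = [
            (a, b) for i, a in enumerate(strata_present) for b in strata_present[i + 1:]
        ]
        raw = [
            wilcoxon_rank_sum(by[a]["score"].to_numpy(), by[b]["score"].to_numpy())
            for a, b in pairs
        ]
        adj = bonferroni([r.p_value for r in raw])
        strat["pairwise_rank_sum"] = [
            {
                "groups": [a, b],
                "z": r.statistic,
                "p_raw": r.p_value,
                "p_bonferroni": p_adj,
                "n_comparisons": len(pairs),
            }
            for (a, b), r, p_adj in zip(pairs, raw, adj)
        ]

    return {
        "cutoff": cutoff,
        "groups": {ref: int((df["group"] == ref).sum()), other: int((df["group"] == other).sum())},
        "binary_table": {
            "rows": [ref, other],
            "columns": ["positive", "negative"],
            "cells": t22.tolist(),
        },
        "fisher_exact": _result_dict(fisher),
        "pearson_chi2": _result_dict(chi2),
        "odds_ratio": {
            "odds_ratio": oddsr.odds_ratio,
            "ci_low": oddsr.ci_low,
            "ci_high": oddsr.ci_high,
            "level": oddsr.level,
            "haldane_corrected": oddsr.haldane_corrected,
        },
        "logistic": {
            "status": logit_res.status,
            "converged": logit_res.converged,
            "table": logit_res.table.round(10).to_dict(orient="index"),
        },
        "score_table": {
            "rows": list(map(str, score_ct.index)),
            "columns": [int(c) for c in score_ct.columns],
            "cells": score_ct.to_numpy().tolist(),
        },
        "score_rank_sum": _result_dict(score_wrs),
        "score_chi2": _result_dict(score_chi2) if score_chi2 else None,
        "stratified": strat,
    }


def _result_dict(result: TestResult) -> dict:
    return {
        "method": result.method,
        "statistic": None if np.isnan(result.statistic) else result.statistic,
        "df": result.df,
        "p_value": result.p_value,
    }
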