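"""Seeded synthetic data with the structure the screen assumes.

Real disease-expression compendia aggregate hundreds of independent
microarray studies over many platforms, each measuring an incomplete,
platform-specific slice of the genome, with disease and matched normal
arrays per study.  Nothing at that scale can ship with a package, and no
per-study sample sizes or noise levels are published for such compendia, so
the generator here emulates the *structure*: per-disease groups of studies,
log-scale Gaussian expression with gene-specific baselines, genes planted
to be upregulated in chosen diseases, and independent per-study gene
dropout mimicking platform incompleteness.  Because the downstream statistic
is rank-based and therefore distribution-free, the Gaussian baseline is a
modelling convenience, not an assumption the pipeline needs.

The module also generates susceptibility / biofluid gene lists with a
controllable forced overlap (so planted candidates can be made to survive
the whole cascade), ordinal-score TMA cohorts from per-group multinomial
staining distributions, and a deterministic reference cohort reproducing
the published marginal staining-score counts of an FABP-1 pancreatic
adenocarcinoma tissue microarray (21 normal and 60 tumor cores).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit, logit

from .datasets import ExpressionDataset
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

#: spread of per-gene baseline means on the log-expression scale; chosen so
#: that a shift of a few noise SDs moves a gene a long way through the ranks
#: without saturating them.
BASELINE_MEAN = 8.0
BASELINE_SD = 2.0


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic gene identifiers ``G00000 .. G<n-1>``."""
    return [f"G{i:05d}" for i in range(n_genes)]


def disease_labels(n_diseases: int) -> list[str]:
    return [f"disease_{j:02d}" for j in range(n_diseases)]


class CompendiumConfig(BaseModel):
    """Shape and effect structure of a synthetic compendium.

    ``effect_shift`` is the mean upward shift of planted genes in disease
    samples, in units of the baseline noise SD (``noise_sd``).  A shift of
    0 yields a null compendium in which planted and non-planted genes are
    generatively identical.  ``missing_gene_fraction`` is the probability
    that any given gene is absent from a study's platform, independently
    per study.
    """

    n_diseases: int = Field(default=3, ge=1)
    n_datasets_per_disease: int = Field(default=3, ge=1)
    n_genes: int = Field(default=500, ge=2)
    n_samples_per_group: int = Field(default=10, ge=1)
    planted_up_genes: dict[str, set[str]] = Field(default_factory=dict)
    effect_shift: float = Field(default=2.0, ge=0.0)
    noise_sd: float = Field(default=1.0, gt=0.0)
    missing_gene_fraction: float = Field(default=0.1, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _planted_in_universe(self) -> "CompendiumConfig":
        universe = set(gene_universe(self.n_genes))
        labels = set(disease_labels(self.n_diseases))
        for disease, genes in self.planted_up_genes.items():
            if disease not in labels:
                raise ConfigurationError(f"planted disease {disease!r} not in {sorted(labels)}")
            stray = set(genes) - universe
            if stray:
                raise ConfigurationError(f"planted genes outside universe: {sorted(stray)[:5]}")
        return self


def baseline_means(config: CompendiumConfig) -> pd.Series:
    """Per-gene baseline log-expression means for a config (deterministic).

    These are the same draws :func:`generate_compendium` uses internally.
    A bounded rank statistic cannot detect upregulation of a gene that
    already sits at the top of the expression hierarchy, so experiments
    planting recoverable effects should plant them on genes with rank
    headroom — which this helper makes possible without regenerating data.
    """
    rng = np.random.default_rng(config.seed)
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    return pd.Series(mu, index=gene_universe(config.n_genes))


def mid_baseline_genes(config: CompendiumConfig, n: int) -> list[str]:
    """The `n` genes closest to the median baseline expression level."""
    mu = baseline_means(config)
    order = (mu - mu.median()).abs().sort_values(kind="mergesort")
    return sorted(order.index[:n])


def generate_compendium(config: CompendiumConfig) -> list[ExpressionDataset]:
    """Generate one :class:`ExpressionDataset` per (disease, study) pair.

    Expression of gene g in any sample is ``mu_g + eps`` with
    ``mu_g ~ N(BASELINE_MEAN, BASELINE_SD^2)`` fixed across the whole
    compendium and ``eps ~ N(0, noise_sd^2)`` independent per measurement;
    genes planted for a disease get ``+ effect_shift * noise_sd`` in that
    disease's disease-state samples only.  Per study, each gene is dropped
    from the platform independently with probability
    ``missing_gene_fraction``.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array(gene_universe(config.n_genes))
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    n = config.n_samples_per_group
    datasets: list[ExpressionDataset] = []
    for disease in disease_labels(config.n_diseases):
        planted = np.isin(genes, sorted(config.planted_up_genes.get(disease, set())))
        for k in range(config.n_datasets_per_disease):
            dataset_id = f"{disease}_ds{k:02d}"
            keep = rng.random(config.n_genes) >= config.missing_gene_fraction
            if keep.sum() < 2:  # a platform must measure at least two genes
                keep[:2] = True
            g_idx = np.flatnonzero(keep)
            values = mu[g_idx, None] + rng.normal(
                0.0, config.noise_sd, size=(g_idx.size, 2 * n)
            )
            # first n columns are disease-state samples
            values[planted[g_idx], :n] += config.effect_shift * config.noise_sd
            sample_ids = [f"{dataset_id}_dz{i:03d}" for i in range(n)] + [
                f"{dataset_id}_nm{i:03d}" for i in range(n)
            ]
            matrix = pd.DataFrame(values, index=genes[g_idx], columns=sample_ids)
            annotations = pd.DataFrame(
                {
                    "disease_concept": disease,
                    "state": ["disease"] * n + ["normal"] * n,
                    "tissue": "tissue_00",
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
            datasets.append(ExpressionDataset(dataset_id, matrix, annotations))
    return datasets


def generate_gene_lists(
    universe: Iterable[str],
    susceptibility_fraction: float,
    biofluid_fraction: float,
    overlap_with: Iterable[str] = (),
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Draw susceptibility and biofluid gene lists from a universe.

    Each list is drawn without replacement at the exact size
    ``round(fraction * |universe|)`` (at least the size of the forced
    overlap), and every gene in ``overlap_with`` is included in both lists.
    Lists are returned sorted, so output is reproducible from the seed.
    """
    universe = sorted(set(universe))
    overlap = sorted(set(overlap_with))
    if set(overlap) - set(universe):
        raise ConfigurationError("overlap_with must be a subset of the universe")
    for name, frac in (("susceptibility", susceptibility_fraction), ("biofluid", biofluid_fraction)):
        if not 0.0 < frac <= 1.0:
            raise ConfigurationError(f"{name}_fraction must lie in (0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    rest = [g for g in universe if g not in set(overlap)]

    def draw(fraction: float) -> list[str]:
        size = max(round(fraction * len(universe)), len(overlap))
        extra = rng.choice(len(rest), size=size - len(overlap), replace=False)
        return sorted(overlap + [rest[i] for i in extra])

    return draw(susceptibility_fraction), draw(biofluid_fraction)


# ---------------------------------------------------------------------------
# TMA cohorts
# ---------------------------------------------------------------------------


class CovariateParams(BaseModel):
    """Per-group clinical covariate distributions for cohort simulation."""

    age_mean: float = 62.0
    age_sd: float = Field(default=10.0, gt=0.0)
    female_p: float = Field(default=0.5, ge=0.0, le=1.0)
    dm_p: float = Field(default=0.2, ge=0.0, le=1.0)
    tobacco_p: float = Field(default=0.5, ge=0.0, le=1.0)
    alcohol_p: float = Field(default=0.35, ge=0.0, le=1.0)


class TMACohortConfig(BaseModel):
    """Group sizes, staining-score distributions, and covariates.

    ``age_staining_slope`` switches on a proportional-odds dependence of
    the staining score on age (log-odds of exceeding each score cutpoint
    per year above the group mean); at the default 0.0 covariates are
    generated but carry no information about staining, so there is no
    confounding to adjust for.
    """

    group_sizes: dict[str, int]
    score_probs: dict[str, tuple[float, float, float, float]]
    covariate_params: dict[str, CovariateParams] = Field(default_factory=dict)
    age_staining_slope: float = 0.0
    seed: int = 0

    @field_validator("group_sizes")
    @classmethod
    def _positive_sizes(cls, v: dict[str, int]) -> dict[str, int]:
        if any(n < 1 for n in v.values()):
            raise ConfigurationError("group sizes must be positive")
        return v

    @model_validator(mode="after")
    def _probs_normalized(self) -> "TMACohortConfig":
        for group, probs in self.score_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(f"score_probs for {group!r} must sum to 1")
        missing = set(self.group_sizes) - set(self.score_probs)
        if missing:
            raise ConfigurationError(f"no score_probs for groups {sorted(missing)}")
        return self


def _scores_with_age_effect(
    rng: np.random.Generator, probs: np.ndarray, ages: np.ndarray, age_mean: float, slope: float
) -> np.ndarray:
    """Sample scores from a proportional-odds tilt of the base distribution."""
    cum = np.cumsum(probs)[:-1]  # P(score <= k), k = 0..2
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    # older samples shift probability mass toward higher scores
    shifted = expit(logit(cum)[None, :] - slope * (ages - age_mean)[:, None])
    u = rng.random(ages.size)
    return (u[:, None] > shifted).sum(axis=1)


def generate_tma_cohort(config: TMACohortConfig) -> pd.DataFrame:
    """Simulate a TMA cohort with exact per-group sizes.

    Scores are multinomial draws from each group's ``score_probs`` (tilted
    by age when ``age_staining_slope`` is nonzero); ages are Gaussian,
    binary covariates Bernoulli.  Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for group in sorted(config.group_sizes):
        n = config.group_sizes[group]
        cov = config.covariate_params.get(group, CovariateParams())
        probs = np.asarray(config.score_probs[group], dtype=float)
        ages = np.round(rng.normal(cov.age_mean, cov.age_sd, size=n), 1)
        if config.age_staining_slope != 0.0:
            scores = _scores_with_age_effect(
                rng, probs, ages, cov.age_mean, config.age_staining_slope
            )
        else:
            scores = rng.choice(4, size=n, p=probs)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{group}_{i:03d}" for i in range(n)],
                    "group": group,
                    "score": scores.astype(int),
                    "dm": pd.array(rng.random(n) < cov.dm_p, dtype="boolean"),
                    "age": ages,
                    "sex": np.where(rng.random(n) < cov.female_p, "F", "M"),
                    "tobacco": pd.array(rng.random(n) < cov.tobacco_p, dtype="boolean"),
                    "alcohol": pd.array(rng.random(n) < cov.alcohol_p, dtype="boolean"),
                    "diagnosis_label": group,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# Published marginal staining-score counts of the FABP-1 pancreatic TMA
# reference cohort.  The 60 tumor cores split into 37 without diabetes
# (scores 0/1/2/3 = 28/7/2/0), 10 with diabetes (5/3/1/1), and 13 whose
# diabetes status is unknown (9/2/2/0, the remainder of the 42/12/5/1
# tumor margin); 3 of the 21 normal cores come from diabetic patients,
# none of which stained.
_REFERENCE_STRATA = (
    # (group, dm, score counts for 0..3)
    ("normal", False, (17, 0, 1, 0)),
    ("normal", True, (3, 0, 0, 0)),
    ("PaC", False, (28, 7, 2, 0)),
    ("PaC", True, (5, 3, 1, 1)),
    ("PaC", None, (9, 2, 2, 0)),
)


def reference_tma_cohort() -> pd.DataFrame:
    """Deterministic 81-core FABP-1 staining cohort (21 normal, 60 tumor).

    Clinical covariates other than diabetes status are not reconstructible
    from marginal counts and are left missing.
    """
    rows = []
    for group, dm, counts in _REFERENCE_STRATA:
        for score, count in enumerate(counts):
            for _ in range(count):
                rows.append((group, dm, score))
    df = pd.DataFrame(rows, columns=["group", "dm", "score"])
    df.insert(0, "sample_id", [f"core_{i:03d}" for i in range(len(df))])
    df["dm"] = pd.array(df["dm"], dtype="boolean")
    df["age"] = np.nan
    df["sex"] = pd.NA
    df["tobacco"] = pd.array([pd.NA] * len(df), dtype="boolean")
    df["alcohol"] = pd.array([pd.NA] * len(df), dtype="boolean")
    df["diagnosis_label"] = np.where(
        df["group"] == "normal", "normal pancreas", "pancreatic adenocarcinoma"
    )
    return df
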