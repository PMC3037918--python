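"""Rank-normalized expression change across a disease compendium.

The compendium statistic works on ranks so that arrays from different
platforms, scanners, and normalization pipelines become comparable.  Within
each array the G measured genes are ranked and rescaled to [0, 1] with

    rho = (r - 1) / (G - 1),

where ``r`` is the 1-based average rank of the gene's value within that
array.  The per-gene change measure for a disease contrast is then

    delta = mean(rho | disease samples) - mean(rho | normal samples),

which is bounded in [-1, +1]: delta = +1 exactly when a gene sits at the
bottom rank of every normal array and at the top rank of every disease
array, and delta = -1 in the mirrored case.  Being a difference of ranks,
delta is invariant under any strictly increasing transform applied to an
array and is antisymmetric under exchange of the disease and normal labels.

Per-dataset deltas are aggregated across the studies annotated to a disease
as a sample-size-weighted mean; genes not measured on a platform simply do
not contribute (no zero imputation, which would shrink delta asymmetrically
across platforms).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .errors import DataError

RankScope = Literal["sample", "pooled"]

#: columns of the per-gene delta table
DELTA_COLUMNS = (
    "gene",
    "disease",
    "delta",
    "n_datasets",
    "n_disease_samples",
    "n_normal_samples",
)


def rank_normalize_sample(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rescale one array's values to normalized ranks in [0, 1].

    Ties receive the average rank; with no ties the minimum maps to 0 and
    the maximum to 1.  Output order matches input order.

    Raises
    ------
    DataError
        If fewer than two values are given (the rescaling is undefined) or
        any value is non-finite.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise DataError("expected a 1-D vector of expression values")
    if v.size < 2:
        raise DataError("rank normalization needs at least two genes")
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite expression value in sample")
    r = stats.rankdata(v, method="average")
    return (r - 1.0) / (v.size - 1.0)


def _normalized_rank_matrix(matrix: pd.DataFrame, scope: RankScope) -> pd.DataFrame:
    """Normalized ranks for every column (scope='sample') or jointly pooled."""
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise DataError("rank normalization needs at least two genes")
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite expression value in matrix")
    if scope == "sample":
        ranks = stats.rankdata(values, method="average", axis=0)
        normed = (ranks - 1.0) / (values.shape[0] - 1.0)
    elif scope == "pooled":
        flat = stats.rankdata(values.ravel(), method="average")
        normed = ((flat - 1.0) / (flat.size - 1.0)).reshape(values.shape)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown rank scope {scope!r}")
    return pd.DataFrame(normed, index=matrix.index, columns=matrix.columns)


def _contrast_samples(dataset: ExpressionDataset, disease: str) -> tuple[list[str], list[str]]:
    dz = dataset.samples_for(disease, "disease")
    nm = dataset.samples_for(disease, "normal")
    return dz, nm


def gene_delta(
    dataset: ExpressionDataset,
    gene: str,
    disease: str,
    scope: RankScope = "sample",
) -> float | None:
    """Rank-normalized expression change of one gene in one study.

    Returns ``None`` when the gene was not measured on this study's
    platform — a distinguishable "not measured" outcome, never coerced to
    zero.  Raises :class:`DataError` when the contrast has an empty
    disease or normal group.
    """
    dz, nm = _contrast_samples(dataset, disease)
    if not dz or not nm:
        raise DataError(
            f"{dataset.dataset_id}: contrast for {disease!r} needs >=1 disease "
            f"and >=1 normal sample (got {len(dz)}/{len(nm)})"
        )
    if gene not in dataset.matrix.index:
        return None
    cols = dz + nm
    normed = _normalized_rank_matrix(dataset.matrix[cols], scope)
    row = normed.loc[gene]
    return float(row[dz].mean() - row[nm].mean())


def dataset_deltas(
    dataset: ExpressionDataset, disease: str, scope: RankScope = "sample"
) -> pd.Series:
    """Vectorized per-gene delta for one study (all measured genes)."""
    dz, nm = _contrast_samples(dataset, disease)
    if not dz or not nm:
        raise DataError(
            f"{dataset.dataset_id}: contrast for {disease!r} needs >=1 disease "
            f"and >=1 normal sample (got {len(dz)}/{len(nm)})"
        )
    normed = _normalized_rank_matrix(dataset.matrix[dz + nm], scope)
    return normed[dz].mean(axis=1) - normed[nm].mean(axis=1)


def aggregate_deltas(
    datasets: Iterable[ExpressionDataset],
    disease: str,
    weighted: bool = True,
    scope: RankScope = "sample",
) -> pd.DataFrame:
    """Aggregate per-gene deltas for a disease across all qualifying studies.

    A study qualifies when it annotates at least one disease and one normal
    sample to the contrast.  Per-gene deltas are combined as a weighted mean
    with weight equal to the number of contributing samples in the study
    (``weighted=False`` switches to the unweighted mean).  Genes missing
    from a study's platform contribute nothing to their own aggregate.

    Returns a table with columns ``gene, disease, delta, n_datasets,
    n_disease_samples, n_normal_samples``.  If no study qualifies, an empty
    table is returned together with a warning — never a silent success.
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    n_ds: dict[str, int] = {}
    n_dz: dict[str, int] = {}
    n_nm: dict[str, int] = {}
    n_qualifying = 0
    for ds in datasets:
        dz, nm = _contrast_samples(ds, disease)
        if not dz or not nm:
            continue
        n_qualifying += 1
        deltas = dataset_deltas(ds, disease, scope)
        w = float(len(dz) + len(nm)) if weighted else 1.0
        for gene, d in deltas.items():
            num[gene] = num.get(gene, 0.0) + w * d
            den[gene] = den.get(gene, 0.0) + w
            n_ds[gene] = n_ds.get(gene, 0) + 1
            n_dz[gene] = n_dz.get(gene, 0) + len(dz)
            n_nm[gene] = n_nm.get(gene, 0) + len(nm)
    if n_qualifying == 0:
        warnings.warn(
            f"no dataset provides a disease/normal contrast for {disease!r}; "
            "returning an empty delta table",
            stacklevel=2,
        )
        return pd.DataFrame(columns=list(DELTA_COLUMNS))
    genes = sorted(num)
    table = pd.DataFrame(
        {
            "gene": genes,
            "disease": disease,
            "delta": [num[g] / den[g] for g in genes],
            "n_datasets": [n_ds[g] for g in genes],
            "n_disease_samples": [n_dz[g] for g in genes],
            "n_normal_samples": [n_nm[g] for g in genes],
        }
    )
    return table


def write_delta_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_delta_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
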