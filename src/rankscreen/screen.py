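"""Candidate biomarker filter cascade.

Starting from per-disease rank-delta tables, candidates for a circulating
disease marker must survive three successive filters:

1. **Selective upregulation** — delta in the target disease at or above a
   threshold, while in every comparator disease in which the gene is
   measured the delta stays at or below a ceiling (default 0.0).  Genes
   unmeasured in a comparator are retained but flagged, since dropping them
   would penalize platform gaps rather than biology.
2. **Susceptibility intersection** — the gene is on an externally curated
   disease-susceptibility list.
3. **Biofluid detectability** — the protein product is known to be
   detectable in blood or urine, a prerequisite for a serum/urine assay and
   for a tumor-derived factor to act on distant target tissues.

The final candidates are the ``top_n`` genes by target delta among those
passing all three stages.  Each filter only removes genes, so the cascade
is monotone, and the two list filters commute.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .datasets import ExpressionDataset
from .errors import DataError
from .rank_delta import RankScope, aggregate_deltas


class ScreenConfig(BaseModel):
    """Parameters of the filter cascade.

    ``up_threshold`` defaults to 0.10, just below the deltas observed for
    top-ranked selectively upregulated genes in compendium screens of this
    kind (roughly 0.12-0.19); ``comparator_max_delta`` defaults to 0.0,
    i.e. "not upregulated at all" in comparator diseases.
    """

    target_disease: str
    comparator_diseases: list[str] = Field(default_factory=list)
    up_threshold: float = 0.10
    comparator_max_delta: float = 0.0
    top_n: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _threshold_order(self) -> "ScreenConfig":
        if not self.up_threshold > self.comparator_max_delta:
            raise ValueError("up_threshold must exceed comparator_max_delta")
        return self


def normalize_gene_id(gene: str) -> str:
    """Case-fold and strip whitespace so list identifiers match platform IDs."""
    return gene.strip().casefold()


def _normalized_set(genes: Iterable[str]) -> set[str]:
    return {normalize_gene_id(g) for g in genes}


def selective_upregulation(deltas: pd.DataFrame, config: ScreenConfig) -> set[str]:
    """Genes upregulated in the target disease but not in comparators.

    `deltas` is a long-format delta table (columns ``gene, disease,
    delta``) covering the target and any comparator diseases.  A gene
    passes when its target delta >= ``up_threshold`` and, for every
    comparator in which it is measured, its delta <= ``comparator_max_delta``.
    """
    wide = deltas.pivot(index="gene", columns="disease", values="delta")
    if config.target_disease not in wide.columns:
        raise DataError(f"target disease {config.target_disease!r} absent from delta table")
    target = wide[config.target_disease].dropna()
    passing = set(target.index[target >= config.up_threshold])
    for comp in config.comparator_diseases:
        if comp not in wide.columns:
            continue  # unmeasured everywhere: vacuously retained
        comp_delta = wide[comp]
        too_high = comp_delta.index[comp_delta > config.comparator_max_delta]
        passing -= set(too_high)
    return passing


def intersect_susceptibility(genes: Iterable[str], susceptibility: Iterable[str]) -> set[str]:
    """Genes also on the disease-susceptibility list (identifier-normalized)."""
    keep = _normalized_set(susceptibility)
    return {g for g in genes if normalize_gene_id(g) in keep}


def filter_biofluid(genes: Iterable[str], biofluid: Iterable[str]) -> set[str]:
    """Genes whose protein product is detectable in blood or urine."""
    keep = _normalized_set(biofluid)
    return {g for g in genes if normalize_gene_id(g) in keep}


def run_screen(
    datasets: Sequence[ExpressionDataset],
    susceptibility: Iterable[str],
    biofluid: Iterable[str],
    config: ScreenConfig,
    weighted: bool = True,
    scope: RankScope = "sample",
) -> pd.DataFrame:
    """Run the full cascade and return a per-gene candidate report.

    The report covers every gene measured in the target disease, sorted by
    target delta (descending, gene id as tie-break), with one column per
    comparator delta and boolean flags for each stage.  ``final_candidate``
    marks the ``top_n`` genes by target delta among those passing all
    stages; it implies all three stage flags.
    """
    tables = [aggregate_deltas(datasets, config.target_disease, weighted, scope)]
    for comp in config.comparator_diseases:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # a comparator may have no data at all
            tables.append(aggregate_deltas(datasets, comp, weighted, scope))
    deltas = pd.concat(tables, ignore_index=True)
    if deltas.empty or config.target_disease not in set(deltas["disease"]):
        raise DataError(f"no delta data for target disease {config.target_disease!r}")

    wide = deltas.pivot(index="gene", columns="disease", values="delta")
    target = wide[config.target_disease].dropna()
    selective = selective_upregulation(deltas, config)
    susceptible = intersect_susceptibility(target.index, susceptibility)
    in_biofluid = filter_biofluid(target.index, biofluid)

    report = pd.DataFrame({"gene": target.index, "target_delta": target.to_numpy()})
    for comp in config.comparator_diseases:
        col = f"delta_{comp}"
        report[col] = (
            wide[comp].reindex(target.index).to_numpy() if comp in wide.columns else float("nan")
        )
    comp_cols = [f"delta_{c}" for c in config.comparator_diseases]
    report["n_unmeasured_comparators"] = (
        report[comp_cols].isna().sum(axis=1) if comp_cols else 0
    )
    report["passed_selectivity"] = report["gene"].isin(selective)
    report["in_susceptibility_list"] = report["gene"].isin(susceptible)
    report["in_biofluid_list"] = report["gene"].isin(in_biofluid)
    report = report.sort_values(
        ["target_delta", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    passed_all = (
        report["passed_selectivity"]
        & report["in_susceptibility_list"]
        & report["in_biofluid_list"]
    )
    final = passed_all & (passed_all.cumsum() <= config.top_n)
    report["final_candidate"] = final
    return report


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
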