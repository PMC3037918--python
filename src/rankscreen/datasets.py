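"""Containers and on-disk formats for expression compendia and TMA cohorts.

An expression compendium is a collection of independent studies.  Each study
(`ExpressionDataset`) carries a gene x sample matrix and a per-sample
annotation table assigning every array to a disease concept, a tissue, and a
state (``disease`` or ``normal``).  On disk a dataset is a pair of
tab-separated files: ``<id>.expr.tsv`` (rows = gene IDs, columns = sample
IDs) and ``<id>.samples.tsv`` (columns ``sample_id``, ``disease_concept``,
``state``, ``tissue``).

Tissue-microarray cohorts are flat CSV tables with one row per core
(``sample_id, group, score, dm, age, sex, tobacco, alcohol,
diagnosis_label``); gene lists are newline-delimited text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

VALID_STATES = frozenset({"disease", "normal"})

#: columns required in a sample-annotation table
ANNOTATION_COLUMNS = ("disease_concept", "state", "tissue")

#: columns of a TMA cohort table
TMA_COLUMNS = (
    "sample_id",
    "group",
    "score",
    "dm",
    "age",
    "sex",
    "tobacco",
    "alcohol",
    "diagnosis_label",
)


@dataclass
class ExpressionDataset:
    """One study's gene x sample matrix plus per-sample annotations.

    Parameters
    ----------
    dataset_id : str
        Unique identifier of the study.
    matrix : pandas.DataFrame
        Expression values, genes in rows, samples in columns.
    annotations : pandas.DataFrame
        Indexed by sample id, with columns ``disease_concept``, ``state``
        (``disease`` or ``normal``) and ``tissue``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing:
            raise DataError(f"{self.dataset_id}: annotation columns missing: {missing}")
        bad_states = set(self.annotations["state"]) - VALID_STATES
        if bad_states:
            raise DataError(f"{self.dataset_id}: invalid sample states {sorted(bad_states)}")
        if set(self.matrix.columns) != set(self.annotations.index):
            raise DataError(
                f"{self.dataset_id}: matrix samples and annotation rows disagree"
            )
        if self.matrix.index.has_duplicates:
            raise DataError(f"{self.dataset_id}: duplicate gene identifiers")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_genes(self) -> int:
        return len(self.matrix.index)

    def samples_for(self, disease: str, state: str) -> list[str]:
        """Sample ids annotated to `disease` in the given `state`."""
        ann = self.annotations
        mask = (ann["disease_concept"] == disease) & (ann["state"] == state)
        return list(ann.index[mask])


def write_dataset(dataset: ExpressionDataset, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.matrix.to_csv(outdir / f"{dataset.dataset_id}.expr.tsv", sep="\t", index_label="gene")
    dataset.annotations.to_csv(
        outdir / f"{dataset.dataset_id}.samples.tsv", sep="\t", index_label="sample_id"
    )


def read_dataset(outdir: str | os.PathLike, dataset_id: str) -> ExpressionDataset:
    outdir = Path(outdir)
    matrix = pd.read_csv(outdir / f"{dataset_id}.expr.tsv", sep="\t", index_col="gene")
    annotations = pd.read_csv(
        outdir / f"{dataset_id}.samples.tsv", sep="\t", index_col="sample_id"
    )
    return ExpressionDataset(dataset_id, matrix, annotations)


def write_compendium(datasets: Iterable[ExpressionDataset], outdir: str | os.PathLike) -> None:
    """Write every dataset of a compendium into one directory."""
    for ds in datasets:
        write_dataset(ds, outdir)


def read_compendium(outdir: str | os.PathLike) -> list[ExpressionDataset]:
    """Load every ``*.expr.tsv`` / ``*.samples.tsv`` pair in a directory."""
    outdir = Path(outdir)
    ids = sorted(p.name[: -len(".expr.tsv")] for p in outdir.glob("*.expr.tsv"))
    if not ids:
        raise DataError(f"no expression datasets found in {outdir}")
    return [read_dataset(outdir, i) for i in ids]


def write_gene_list(genes: Sequence[str], path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | os.PathLike) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_tma_cohort(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    cohort.to_csv(path, index=False)


def read_tma_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TMA cohort CSV, coercing flags to nullable booleans."""
    df = pd.read_csv(path)
    missing = [c for c in TMA_COLUMNS if c not in df.columns and c != "diagnosis_label"]
    if missing:
        raise DataError(f"TMA cohort missing columns: {missing}")
    if "diagnosis_label" not in df.columns:
        df["diagnosis_label"] = df["group"]
    for col in ("dm", "tobacco", "alcohol"):
        df[col] = df[col].astype("boolean")
    df["score"] = df["score"].astype(int)
    bad = ~df["score"].isin((0, 1, 2, 3))
    if bad.any():
        raise DataError(f"scores outside 0-3 for samples {list(df.loc[bad, 'sample_id'])}")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def validate_tma_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check in-memory cohort invariants (score range, required columns)."""
    missing = [c for c in TMA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"TMA cohort missing columns: {missing}")
    scores = np.asarray(df["score"])
    if not np.isin(scores, (0, 1, 2, 3)).all():
        raise DataError("staining scores must lie in 0-3")
    return df
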