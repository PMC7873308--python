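"""Expression/annotation table I/O and trait-matrix construction.

The interchange format is plain TSV: expression matrices are gene x sample
with gene identifiers in the first column and sample identifiers in the
header; sample annotations are two-column (sample id, stage label).
Expression values are assumed to be on a log2 scale throughout the package
(fold changes then reduce to mean differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleAnnotation",
    "TraitMatrix",
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "write_annotation",
    "make_trait_matrix",
]


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps each sample to one of an ordered list of disease stages.

    Parameters
    ----------
    stages
        Series indexed by sample id with stage labels as values.
    stage_order
        The ordered stage labels (e.g. normal -> metastatic). Ordinal codes
        0..K-1 follow this order.
    """

    stages: pd.Series
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        order = tuple(self.stage_order)
        object.__setattr__(self, "stage_order", order)
        if len(set(order)) != len(order):
            raise ValueError(f"stage names are not unique: {order}")
        if not order:
            raise ValueError("stage_order is empty")
        if self.stages.index.has_duplicates:
            dups = self.stages.index[self.stages.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)}")
        unknown = set(self.stages) - set(order)
        if unknown:
            raise ValueError(f"samples assigned to unknown stages: {sorted(unknown)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.stages.index

    @property
    def n_samples(self) -> int:
        return len(self.stages)

    @property
    def ordinal(self) -> pd.Series:
        """Ordinal stage codes 0..K-1 per sample, in stage order."""
        code = {s: i for i, s in enumerate(self.stage_order)}
        return self.stages.map(code).astype(int)

    def samples_in(self, stage: str) -> pd.Index:
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}; known: {self.stage_order}")
        return self.stages.index[self.stages == stage]

    def reindex(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        """Restrict/reorder to the given samples (positional alignment)."""
        missing = [s for s in sample_ids if s not in self.stages.index]
        if missing:
            raise KeyError(f"samples without annotation: {missing}")
        return SampleAnnotation(self.stages.loc[list(sample_ids)], self.stage_order)


@dataclass(frozen=True)
class TraitMatrix:
    """Sample x stage 0/1 indicator matrix plus the ordinal stage vector."""

    indicators: pd.DataFrame  # samples x stages, entries in {0, 1}
    ordinal: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.indicators.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("trait indicators must be 0/1")
        if not (vals.sum(axis=1) == 1).all():
            raise ValueError("each sample must belong to exactly one stage")

    @property
    def stage_order(self) -> tuple[str, ...]:
        return tuple(self.indicators.columns)


def read_expression_table(path: str | Path, missing_policy: str = "strict") -> pd.DataFrame:
    """Read a gene x sample expression TSV.

    ``missing_policy`` is ``"strict"`` (any missing value or duplicated gene
    id is an error) or ``"drop"`` (genes with missing values are dropped;
    duplicated gene ids are still an error).
    """
    if missing_policy not in ("strict", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique()
        raise ValueError(f"{path}: duplicate sample ids: {list(dups)}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene ids: {list(dups)}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    if df.isna().any().any():
        if missing_policy == "strict":
            bad = df.index[df.isna().any(axis=1)]
            raise ValueError(f"{path}: missing values in genes {list(bad[:10])}")
        df = df.dropna(axis=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(Path(path), sep="\t", index_label="gene")


def read_annotation(path: str | Path, stage_order: Sequence[str] | None = None) -> SampleAnnotation:
    """Read a two-column (sample id, stage) TSV.

    If ``stage_order`` is omitted the stages are ordered by first appearance
    in the file.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (sample, stage), got {df.shape[1]}")
    sample_col, stage_col = df.columns
    stages = pd.Series(df[stage_col].to_numpy(), index=pd.Index(df[sample_col], name="sample"))
    if stage_order is None:
        stage_order = tuple(dict.fromkeys(stages))
    return SampleAnnotation(stages, tuple(stage_order))


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    pd.DataFrame({"sample": annotation.sample_ids, "stage": annotation.stages.to_numpy()}).to_csv(
        Path(path), sep="\t", index=False
    )


def make_trait_matrix(
    annotation: SampleAnnotation, sample_order: Sequence[str] | None = None
) -> TraitMatrix:
    """Build the sample x stage 0/1 indicator matrix.

    ``sample_order`` (typically the expression matrix column order) fixes the
    row order for positional alignment with eigengenes; defaults to
    annotation order.
    """
    ann = annotation if sample_order is None else annotation.reindex(sample_order)
    ind = pd.DataFrame(
        {stage: (ann.stages == stage).astype(int) for stage in ann.stage_order},
        index=ann.sample_ids,
    )
    return TraitMatrix(ind, ann.ordinal)
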