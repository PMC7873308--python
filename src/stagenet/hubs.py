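"""Hub-gene extraction, DEG overlap, edge export and heatmap preparation.

Hub genes of a module are its members with the highest eigengene-based
connectivity (kME to the module's own eigengene). The hub pool across the
modules of interest is intersected with the multi-comparison DEG set, and
co-expression edges among chosen genes are exported as a plain TSV edge
list for graph tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleAnnotation
from .network import ModulePartition

__all__ = [
    "HubGeneSet",
    "OverlapReport",
    "top_hub_genes",
    "hub_deg_overlap",
    "coexpression_edges",
    "heatmap_matrix",
]


@dataclass
class HubGeneSet:
    """Per-module ordered (gene, kME) hub lists, restricted to members."""

    hubs: dict[str, pd.Series]  # module -> kME indexed by gene, descending
    k: int

    @property
    def pool(self) -> set[str]:
        out: set[str] = set()
        for s in self.hubs.values():
            out |= set(s.index)
        return out

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"module": m, "rank": i + 1, "gene": g, "kme": v}
            for m, s in self.hubs.items()
            for i, (g, v) in enumerate(s.items())
        ]
        return pd.DataFrame(rows, columns=["module", "rank", "gene", "kme"])


def top_hub_genes(
    kme: pd.DataFrame, partition: ModulePartition, modules: list[str], k: int = 20
) -> HubGeneSet:
    """Top-k members of each module by kME to the module's own eigengene.

    Ties are broken lexicographically by gene id. Modules smaller than k
    return all members with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hubs: dict[str, pd.Series] = {}
    for module in modules:
        if module not in kme.columns:
            raise KeyError(f"module {module!r} has no kME column")
        members = partition.members(module)
        if len(members) == 0:
            raise KeyError(f"module {module!r} has no members in the partition")
        if len(members) < k:
            warnings.warn(f"module {module!r} has {len(members)} genes < k={k}; returning all")
        scores = kme.loc[members, module]
        ranked = scores.iloc[np.lexsort((scores.index, -scores.to_numpy()))]
        hubs[module] = ranked.head(k)
    return HubGeneSet(hubs=hubs, k=k)


@dataclass
class OverlapReport:
    """Overlap of the hub pool with a DEG set, per module and in total."""

    per_module: pd.DataFrame  # module, n_hubs, n_overlap, genes
    overlap_genes: set[str] = field(repr=False)
    hub_pool_size: int = 0
    deg_pool_size: int = 0

    @property
    def total_overlap(self) -> int:
        return len(self.overlap_genes)


def hub_deg_overlap(hubs: HubGeneSet, deg_intersection: set[str]) -> OverlapReport:
    """Intersect each module's hub list with the DEG set."""
    deg_intersection = set(deg_intersection)
    rows: list[dict[str, object]] = []
    total: set[str] = set()
    for module, series in hubs.hubs.items():
        overlap = sorted(set(series.index) & deg_intersection)
        total |= set(overlap)
        rows.append(
            {
                "module": module,
                "n_hubs": len(series),
                "n_overlap": len(overlap),
                "genes": ",".join(overlap),
            }
        )
    return OverlapReport(
        per_module=pd.DataFrame(rows, columns=["module", "n_hubs", "n_overlap", "genes"]),
        overlap_genes=total,
        hub_pool_size=len(hubs.pool),
        deg_pool_size=len(deg_intersection),
    )


def coexpression_edges(cor: pd.DataFrame, genes: list[str], threshold: float) -> pd.DataFrame:
    """Undirected |r| >= threshold edges among ``genes``, each pair once.

    Pairs are listed in lexicographic order with columns gene_a, gene_b,
    abs_r; no self-edges.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    unknown = [g for g in genes if g not in cor.index]
    if unknown:
        raise KeyError(f"genes absent from the correlation matrix: {unknown[:10]}")
    ordered = sorted(set(genes))
    sub = np.abs(cor.loc[ordered, ordered].to_numpy())
    ii, jj = np.triu_indices(len(ordered), k=1)
    keep = sub[ii, jj] >= threshold
    return pd.DataFrame(
        {
            "gene_a": np.array(ordered)[ii[keep]],
            "gene_b": np.array(ordered)[jj[keep]],
            "abs_r": sub[ii, jj][keep],
        }
    )


def heatmap_matrix(
    raw_expr: pd.DataFrame, genes: list[str], annotation: SampleAnnotation
) -> pd.DataFrame:
    """log2(x + 1)-transform of raw-scale expression, columns stage-ordered.

    Rows are restricted to ``genes``; columns are grouped by stage in stage
    order, keeping input order within a stage. Input must be non-negative
    (raw scale) — the caller chooses which matrix to pass.
    """
    missing = [g for g in genes if g not in raw_expr.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:10]}")
    sub = raw_expr.loc[list(genes)]
    if (sub.to_numpy() < 0).any():
        raise ValueError("heatmap_matrix expects non-negative raw-scale values")
    ann = annotation.reindex(sub.columns)
    order = [s for stage in ann.stage_order for s in sub.columns if ann.stages[s] == stage]
    return np.log2(sub[order] + 1.0)
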