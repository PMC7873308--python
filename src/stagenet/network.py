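"""Weighted co-expression network construction and module detection.

The construction follows the standard weighted network recipe: Pearson
correlation between gene profiles, unsigned soft-threshold adjacency
a_ij = |r_ij|^beta with beta chosen by the scale-free topology fit,
topological overlap TOM_ij as the clustering similarity, average-linkage
hierarchical clustering of 1 - TOM with a static tree cut, a minimum module
size, and iterative merging of modules with highly correlated eigengenes.
Modules are labelled by a fixed colour palette in decreasing size order;
unassigned genes are "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "MODULE_PALETTE",
    "GREY",
    "pairwise_correlation",
    "adjacency",
    "soft_threshold_scan",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "eigengene_connectivity",
    "ModulePartition",
    "ModuleEigengenes",
    "SoftThresholdReport",
]

# WGCNA's conventional colour vocabulary, assigned in decreasing size order.
MODULE_PALETTE: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
)
GREY = "grey"


def _check_square(m: pd.DataFrame, name: str) -> None:
    if m.shape[0] != m.shape[1] or not m.index.equals(m.columns):
        raise ValueError(f"{name} must be square with identical index and columns")


def pairwise_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation across samples (diagonal exactly 1)."""
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    values = expr.to_numpy()
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0][:10])
        raise ValueError(f"zero-variance genes (drop them first): {bad}")
    r = np.corrcoef(values)
    r = (r + r.T) / 2.0  # BLAS products are not bitwise symmetric
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def adjacency(cor: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    _check_square(cor, "correlation matrix")
    a = np.abs(cor.to_numpy()) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins connectivities into ``n_bins`` equal-width bins and regresses
    log10(frequency) on log10(mean connectivity) over non-empty bins.
    Returns (fit index = R^2 * sign(-slope), slope).
    """
    if np.ptp(k) == 0:
        warnings.warn("all connectivities identical; scale-free fit undefined")
        return 0.0, 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    which = np.digitize(k, edges[:-1]) - 1
    which = np.clip(which, 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    freq = counts / counts.sum()
    keep = (counts > 0) & (mean_k > 0) & (freq > 0)
    if keep.sum() < 2:
        warnings.warn("fewer than two usable connectivity bins; scale-free fit undefined")
        return 0.0, 0.0
    fit = linregress(np.log10(mean_k[keep]), np.log10(freq[keep]))
    r2 = fit.rvalue**2
    return float(r2 * np.sign(-fit.slope)), float(fit.slope)


@dataclass
class SoftThresholdReport:
    scan: pd.DataFrame  # per-beta: fit_index, slope, mean_k, median_k, max_k
    chosen_beta: int
    target_r2: float
    reached_target: bool  # False when the best-index fallback was used

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "" if self.reached_target else " (fallback: best fit index)"
        return f"chosen beta = {self.chosen_beta}{tag}\n{self.scan.to_string(index=False)}"


def soft_threshold_scan(
    cor: pd.DataFrame,
    betas: Sequence[int] = tuple(range(1, 13)),
    target_r2: float = 0.8,
) -> SoftThresholdReport:
    """Scan candidate powers and pick the smallest with fit index >= target.

    Falls back to the beta with maximal fit index (flagged in the report)
    when no candidate reaches the target.
    """
    betas = list(betas)
    if not betas:
        raise ValueError("betas is empty")
    rows = []
    for beta in betas:
        a = adjacency(cor, beta).to_numpy()
        k = a.sum(axis=0) - 1.0  # exclude the self-adjacency
        index, slope = _scale_free_fit(k)
        rows.append(
            {
                "beta": beta,
                "fit_index": index,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    scan = pd.DataFrame(rows)
    ok = scan[scan["fit_index"] >= target_r2]
    if len(ok):
        chosen = int(ok.iloc[0]["beta"])
        reached = True
    else:
        chosen = int(scan.loc[scan["fit_index"].idxmax(), "beta"])
        reached = False
    return SoftThresholdReport(scan=scan, chosen_beta=chosen, target_r2=target_r2,
                               reached_target=reached)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    _check_square(adj, "adjacency matrix")
    a = adj.to_numpy()
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    # (A @ A)_ij includes u = i and u = j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij
    l = a @ a - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    assert np.allclose(tom, tom.T, atol=1e-12)
    tom = (tom + tom.T) / 2.0  # exact symmetry despite BLAS rounding
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Gene -> module label assignment ("grey" = unassigned)."""

    labels: pd.Series
    min_size: int
    cut_height: float
    merge_height: float
    n_merges: int = 0

    @property
    def modules(self) -> list[str]:
        """Non-grey module labels in decreasing size order."""
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        grey = counts.pop(GREY) if GREY in counts.index else 0
        counts = counts.sort_values(ascending=False)
        if grey:
            counts[GREY] = grey
        return counts

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class ModuleEigengenes:
    """First-PC summary of each module: sample scores and variance explained.

    Eigengene columns have unit Euclidean norm and are sign-aligned with the
    module's mean standardized profile.
    """

    eigengenes: pd.DataFrame  # samples x modules
    variance_explained: pd.Series = field(repr=False)

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene profile in module; cannot standardize")
    return (values - mean) / sd


def _eigengene_of(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector (unit norm) of the standardized block."""
    z = _standardize(values)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return me, var_explained


def module_eigengene(expr: pd.DataFrame, partition: ModulePartition) -> ModuleEigengenes:
    """Eigengene (first principal component) of every non-grey module."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    cols, var = {}, {}
    for module in partition.modules:
        genes = partition.members(module)
        if len(genes) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes")
        me, ve = _eigengene_of(expr.loc[genes].to_numpy())
        cols[module] = me
        var[module] = ve
    return ModuleEigengenes(
        eigengenes=pd.DataFrame(cols, index=expr.columns),
        variance_explained=pd.Series(var, dtype=float),
    )


def eigengene_connectivity(expr: pd.DataFrame, eigengenes: ModuleEigengenes) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene."""
    me = eigengenes.eigengenes
    if not expr.columns.equals(me.index):
        raise ValueError("sample order of expression and eigengenes must match")
    x = expr.to_numpy()
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0][:10])
        raise ValueError(f"zero-variance genes: {bad}")
    xc = (x - x.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(x.shape[1]))
    m = me.to_numpy()
    mc = (m - m.mean(axis=0, keepdims=True))
    mc = mc / np.linalg.norm(mc, axis=0, keepdims=True)
    kme = np.clip(xc @ mc, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.index, columns=me.columns)


def _merge_correlated_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_height: float
) -> tuple[pd.Series, int]:
    """Iteratively merge the closest module pair while ME correlation > 1 - merge_height."""
    n_merges = 0
    if merge_height <= 0:
        return labels, 0
    while True:
        modules = [m for m in labels.unique() if m != GREY]
        if len(modules) < 2:
            return labels, n_merges
        partition = ModulePartition(labels, 0, 0.0, merge_height)
        me = module_eigengene(expr, partition).eigengenes
        cor = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_height:
            return labels, n_merges
        keep, drop = me.columns[min(i, j)], me.columns[max(i, j)]
        labels = labels.replace(drop, keep)
        n_merges += 1


def detect_modules(
    tom_diss: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 30,
    cut_height: float | None = None,
    merge_height: float = 0.25,
    min_kme: float = 0.5,
) -> ModulePartition:
    """Detect modules by average-linkage clustering of the TOM dissimilarity.

    The tree is cut at a static height (default 0.995 x the highest merge
    height); clusters smaller than ``min_size`` become grey; modules whose
    eigengenes correlate above 1 - ``merge_height`` are merged iteratively.
    A membership filter then sends genes whose eigengene-based connectivity
    (kME) to their own module falls below ``min_kme`` to grey — a static cut
    otherwise absorbs chance-correlated noise genes into modules — and the
    size filter is re-applied. Final labels follow the colour palette in
    decreasing size order.
    """
    _check_square(tom_diss, "TOM dissimilarity")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not tom_diss.index.equals(expr.index):
        raise ValueError("tom_diss and expression must list the same genes in the same order")
    n = tom_diss.shape[0]
    if n < min_size:
        warnings.warn(f"only {n} genes < min_size={min_size}; all grey")
        return ModulePartition(
            pd.Series(GREY, index=tom_diss.index), min_size, np.nan, merge_height
        )
    d = tom_diss.to_numpy()
    linkage = average(squareform((d + d.T) / 2.0, checks=False))
    max_height = linkage[:, 2].max()
    height = 0.995 * max_height if cut_height is None else cut_height
    if not 0 < height:
        raise ValueError(f"cut height must be positive, got {height}")
    raw = fcluster(linkage, t=height, criterion="distance")

    labels = pd.Series([f"cluster_{c}" for c in raw], index=tom_diss.index)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_size]
    labels[labels.isin(small)] = GREY

    labels, n_merges = _merge_correlated_modules(expr, labels, merge_height)

    if min_kme > 0 and (labels != GREY).any():
        provisional = ModulePartition(labels, min_size, float(height), merge_height)
        kme = eigengene_connectivity(expr, module_eigengene(expr, provisional))
        for module in provisional.modules:
            members = provisional.members(module)
            weak = members[kme.loc[members, module] < min_kme]
            labels[weak] = GREY
        sizes = labels.value_counts()
        small = sizes.index[(sizes < min_size) & (sizes.index != GREY)]
        labels[labels.isin(small)] = GREY

    # palette labels in decreasing size order, gene input order breaking ties
    final = pd.Series(GREY, index=labels.index)
    remaining = labels[labels != GREY]
    order = sorted(
        remaining.unique(),
        key=lambda m: (-(remaining == m).sum(), int(np.argmax((remaining == m).to_numpy()))),
    )
    for rank, cluster in enumerate(order):
        name = MODULE_PALETTE[rank] if rank < len(MODULE_PALETTE) else f"module{rank + 1}"
        final[labels == cluster] = name
    return ModulePartition(final, min_size, float(height), merge_height, n_merges)
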