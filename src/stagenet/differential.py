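"""Differential expression: fold-change calling and the SAM permutation test.

Fold changes are mean differences because expression is log2-scale. The SAM
(significance analysis of microarrays) statistic is the two-class unpaired
moderated difference d_i = (mean_B - mean_A) / (s_i + s0), where s_i is the
pooled standard-error term and the fudge factor s0 is a quantile (default
median) of the per-gene s_i. Significance is assessed against expected order
statistics from label permutations, with a permutation-based FDR estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SampleAnnotation

__all__ = [
    "log2_fold_change",
    "call_degs",
    "sam_statistic",
    "sam_permutation_fdr",
    "multiway_intersection",
    "SAMResult",
]


def _group_values(
    expr: pd.DataFrame, annotation: SampleAnnotation, stage: str, min_n: int = 1
) -> np.ndarray:
    samples = annotation.samples_in(stage)
    samples = [s for s in expr.columns if s in set(samples)]
    if len(samples) < min_n:
        raise ValueError(
            f"stage {stage!r} has {len(samples)} samples in the expression matrix; need >= {min_n}"
        )
    return expr[samples].to_numpy()


def log2_fold_change(
    expr: pd.DataFrame, annotation: SampleAnnotation, stage_a: str, stage_b: str
) -> pd.Series:
    """Per-gene mean(stage_b) - mean(stage_a); stage_a is the reference."""
    a = _group_values(expr, annotation, stage_a)
    b = _group_values(expr, annotation, stage_b)
    fc = pd.Series(b.mean(axis=1) - a.mean(axis=1), index=expr.index)
    fc.name = f"log2fc[{stage_b}-{stage_a}]"
    return fc


def call_degs(fc: pd.Series, cutoff: float = 1.0) -> pd.DataFrame:
    """Call genes differential at |log2FC| strictly greater than ``cutoff``.

    Returns a table with columns log2fc and direction (up/down/none).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    direction = pd.Series("none", index=fc.index)
    direction[fc > cutoff] = "up"
    direction[fc < -cutoff] = "down"
    return pd.DataFrame({"log2fc": fc, "direction": direction})


def deg_set(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table.index[deg_table["direction"] != "none"])


def _sam_d(
    a: np.ndarray, b: np.ndarray, s0: float | None, s0_quantile: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """d, s and the fudge factor for group matrices a, b (genes x samples)."""
    n_a, n_b = a.shape[1], b.shape[1]
    scale = (1.0 / n_a + 1.0 / n_b) / (n_a + n_b - 2)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt(scale * ss)
    if s0 is None:
        s0 = float(np.quantile(s, s0_quantile))
    d = (b.mean(axis=1) - a.mean(axis=1)) / (s + s0)
    return d, s, s0


def sam_statistic(
    expr: pd.DataFrame,
    annotation: SampleAnnotation,
    stage_a: str,
    stage_b: str,
    s0_quantile: float = 0.5,
) -> pd.DataFrame:
    """Per-gene SAM d-statistic for stage_b vs stage_a.

    Returns a table with columns d, s and attrs["s0"]. Both groups need at
    least two samples. With s0 = 0 the statistic is the pooled two-sample t.
    """
    a = _group_values(expr, annotation, stage_a, min_n=2)
    b = _group_values(expr, annotation, stage_b, min_n=2)
    d, s, s0 = _sam_d(a, b, None, s0_quantile)
    out = pd.DataFrame({"d": d, "s": s}, index=expr.index)
    out.attrs["s0"] = s0
    return out


@dataclass
class SAMResult:
    """Outcome of the SAM permutation analysis for one comparison."""

    d: pd.Series  # observed per-gene statistic
    expected: pd.Series  # expected order statistic aligned with each gene's rank
    significant: set[str]
    delta: float
    fdr: float  # median-based permutation FDR estimate, in [0, 1]
    n_permutations: int
    exhaustive: bool  # True when all distinct label assignments were enumerated
    s0: float
    q_raw: float = field(default=np.nan)  # unclipped FDR estimate


def _permutation_indices(
    n: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], bool]:
    total = math.comb(n, n_a)
    if total <= n_perm:
        idx = [np.array(c) for c in combinations(range(n), n_a)]
        return idx, True
    perms = [rng.permutation(n)[:n_a] for _ in range(n_perm)]
    return [np.sort(p) for p in perms], False


def sam_permutation_fdr(
    expr: pd.DataFrame,
    annotation: SampleAnnotation,
    stage_a: str,
    stage_b: str,
    delta: float,
    n_perm: int = 100,
    seed: int = 0,
    s0_quantile: float = 0.5,
) -> SAMResult:
    """SAM significance with the delta criterion and permutation FDR.

    Genes are ranked by d; the expected order statistic dbar_(i) is the mean
    over label permutations of the sorted permuted d. A gene is significant
    when |d_(i) - dbar_(i)| > delta. The FDR estimate is the median, over
    permutations, of the number of permuted d values beyond the observed
    significance thresholds, divided by the observed significant count and
    clipped to [0, 1]. All distinct group assignments are enumerated whenever
    their number does not exceed ``n_perm``; otherwise ``n_perm`` random
    assignments are drawn from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    a = _group_values(expr, annotation, stage_a, min_n=2)
    b = _group_values(expr, annotation, stage_b, min_n=2)
    pooled = np.hstack([a, b])
    n_a = a.shape[1]
    n = pooled.shape[1]

    d_obs, _, s0 = _sam_d(a, b, None, s0_quantile)
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    rng = np.random.default_rng(seed)
    perm_idx, exhaustive = _permutation_indices(n, n_a, n_perm, rng)
    perm_sorted = np.empty((len(perm_idx), len(d_obs)))
    all_idx = np.arange(n)
    for p, ia in enumerate(perm_idx):
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        d_p, _, _ = _sam_d(pooled[:, ia], pooled[:, ib], None, s0_quantile)
        perm_sorted[p] = np.sort(d_p)
    expected_sorted = perm_sorted.mean(axis=0)

    sig_mask_sorted = np.abs(d_sorted - expected_sorted) > delta
    genes_sorted = expr.index[order]
    significant = set(genes_sorted[sig_mask_sorted])

    pos = sig_mask_sorted & (d_sorted > expected_sorted)
    neg = sig_mask_sorted & (d_sorted < expected_sorted)
    cut_up = d_sorted[pos].min() if pos.any() else np.inf
    cut_low = d_sorted[neg].max() if neg.any() else -np.inf

    if significant:
        false_counts = ((perm_sorted >= cut_up) | (perm_sorted <= cut_low)).sum(axis=1)
        q_raw = float(np.median(false_counts)) / len(significant)
        fdr = float(np.clip(q_raw, 0.0, 1.0))
    else:
        q_raw = 0.0
        fdr = 0.0

    expected_by_gene = pd.Series(expected_sorted, index=genes_sorted).reindex(expr.index)
    return SAMResult(
        d=pd.Series(d_obs, index=expr.index, name="d"),
        expected=expected_by_gene.rename("expected"),
        significant=significant,
        delta=delta,
        fdr=fdr,
        n_permutations=len(perm_idx),
        exhaustive=exhaustive,
        s0=s0,
        q_raw=q_raw,
    )


def sam_delta_scan(
    expr: pd.DataFrame,
    annotation: SampleAnnotation,
    stage_a: str,
    stage_b: str,
    deltas: Sequence[float],
    n_perm: int = 100,
    seed: int = 0,
    s0_quantile: float = 0.5,
) -> pd.DataFrame:
    """Significant count and FDR estimate over a grid of delta values."""
    rows = []
    for delta in deltas:
        res = sam_permutation_fdr(
            expr, annotation, stage_a, stage_b, delta, n_perm=n_perm, seed=seed,
            s0_quantile=s0_quantile,
        )
        rows.append({"delta": delta, "n_significant": len(res.significant), "fdr": res.fdr})
    return pd.DataFrame(rows)


def multiway_intersection(deg_sets: Iterable[set[str]]) -> set[str]:
    """Intersection of DEG sets (membership only; direction is ignored)."""
    sets = [set(s) for s in deg_sets]
    if not sets:
        raise ValueError("need at least one gene set")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
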