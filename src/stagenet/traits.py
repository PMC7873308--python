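"""Module-trait correlation and stage-ordered progression-module selection.

Each module eigengene is correlated with the 0/1 stage indicator columns
(one-hot traits) and, as a trend summary, with the ordinal stage code
0..K-1. A "progression module" is one whose stage-ordered correlations rise
monotonically (within a small slack) from negative in the first stage to
positive in the last — the signature of a gene network gradually activated
through disease progression. Because sign and shape constraints alone admit
noise eigengenes at small n, the default selection additionally requires
the ordinal trend correlation to be significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleAnnotation, TraitMatrix
from .network import ModuleEigengenes

__all__ = [
    "ModuleTraitCorrelation",
    "module_trait_correlation",
    "ordinal_trait_correlation",
    "select_progression_modules",
]


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of columns of x vs columns of y, with two-sided t p-values."""
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation p-values")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    if (xn == 0).any() or (yn == 0).any():
        raise ValueError("constant column in correlation input")
    r = np.clip((xc.T @ yc) / np.outer(xn, yn), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


@dataclass
class ModuleTraitCorrelation:
    """Module x trait Pearson correlations and their t-test p-values."""

    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame
    n_samples: int


def module_trait_correlation(
    eigengenes: ModuleEigengenes, traits: TraitMatrix
) -> ModuleTraitCorrelation:
    """Correlate each eigengene with each 0/1 stage indicator column."""
    me = eigengenes.eigengenes
    if not me.index.equals(traits.indicators.index):
        raise ValueError("sample order of eigengenes and traits must match")
    r, p = _corr_with_p(me.to_numpy(), traits.indicators.to_numpy(dtype=float))
    cols = traits.indicators.columns
    return ModuleTraitCorrelation(
        r=pd.DataFrame(r, index=me.columns, columns=cols),
        p=pd.DataFrame(p, index=me.columns, columns=cols),
        n_samples=len(me),
    )


def ordinal_trait_correlation(
    eigengenes: ModuleEigengenes, annotation: SampleAnnotation
) -> pd.DataFrame:
    """Correlate each eigengene with the ordinal stage code 0..K-1."""
    me = eigengenes.eigengenes
    ann = annotation.reindex(me.index)
    if ann.stages.nunique() < 2:
        raise ValueError("need >= 2 stages present for the ordinal correlation")
    r, p = _corr_with_p(me.to_numpy(), ann.ordinal.to_numpy(dtype=float)[:, None])
    return pd.DataFrame({"r_ord": r[:, 0], "p_ord": p[:, 0]}, index=me.columns)


def select_progression_modules(
    mtc: ModuleTraitCorrelation,
    stage_order: tuple[str, ...] | list[str],
    epsilon: float = 0.05,
    ordinal: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the stage-ordered progression-module selection rule.

    A module is selected iff its correlation with the first stage is
    negative, with the last stage positive, and the stage-ordered sequence
    never drops by more than ``epsilon`` between consecutive stages. When an
    ``ordinal`` table (from :func:`ordinal_trait_correlation`) is supplied,
    the module's ordinal trend must additionally satisfy p_ord < ``alpha``.

    Returns a per-module report (selected modules first) with the ordered
    correlations and each verdict component.
    """
    stage_order = list(stage_order)
    if len(stage_order) < 2:
        raise ValueError("need >= 2 stages")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    missing = [s for s in stage_order if s not in mtc.r.columns]
    if missing:
        raise ValueError(f"stages absent from the correlation table: {missing}")
    r = mtc.r[stage_order]

    rows = []
    for module in r.index:
        seq = r.loc[module].to_numpy()
        starts_negative = bool(seq[0] < 0)
        ends_positive = bool(seq[-1] > 0)
        monotone = bool((np.diff(seq) >= -epsilon).all())
        rec: dict[str, object] = {"module": module}
        rec.update({f"r_{s}": seq[i] for i, s in enumerate(stage_order)})
        rec.update(
            starts_negative=starts_negative,
            ends_positive=ends_positive,
            monotone_within_eps=monotone,
        )
        selected = starts_negative and ends_positive and monotone
        if ordinal is not None:
            if module not in ordinal.index:
                raise ValueError(f"module {module!r} missing from ordinal table")
            rec["r_ord"] = float(ordinal.loc[module, "r_ord"])
            rec["p_ord"] = float(ordinal.loc[module, "p_ord"])
            rec["ordinal_significant"] = bool(rec["p_ord"] < alpha)
            selected = selected and rec["ordinal_significant"]
        rec["selected"] = selected
        rows.append(rec)
    report = pd.DataFrame(rows).set_index("module")
    report.attrs.update(epsilon=epsilon, alpha=alpha, used_ordinal=ordinal is not None)
    return report.sort_values("selected", ascending=False, kind="stable")
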