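"""Parameter-recovery benchmarks on planted synthetic data.

Each function runs the relevant slice of the pipeline on generated data
with known ground truth and scores the result: adjusted Rand index for
module recovery, sensitivity/false-selection rate for the stage-ordered
progression rule, top-k overlap for hub-gene ranking, and null behaviour
of both the selection rule and the SAM permutation test. The benchmark
configurations are fixed study conditions, not tuning knobs; see
docs/methods.md for how each was designed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import differential, network, traits as traits_mod
from .hubs import top_hub_genes
from .io import SampleAnnotation, make_trait_matrix
from .network import GREY, ModulePartition
from .synthetic import SyntheticConfig, SyntheticTruth, generate_expression

__all__ = [
    "RECOVERY_CONFIG",
    "SELECTION_CONFIG",
    "NULL_CONFIG",
    "HUB_CONFIG",
    "DEG_CONFIG",
    "SCAN_CONFIG",
    "detect_from_expression",
    "module_recovery_ari",
    "selection_outcomes",
    "selection_operating_characteristics",
    "null_selection_counts",
    "hub_recovery_overlap",
    "sam_null_significant_counts",
    "deg_exact_recovery",
]

# Module recovery: four independent-factor modules over pure-noise
# background, noise-to-factor ratio sigma_e/sigma_f = 0.25.
RECOVERY_CONFIG = SyntheticConfig(
    module_sizes=(50, 50, 50, 50),
    progression_flags=(False, False, False, False),
    n_background=200,
    noise_sd=0.1,
    factor_sd=0.4,
    n_shifted_degs=0,
)

# Progression selection: the generator defaults (two monotone + two flat
# modules, delta = 1, sigma_e = 0.2) without planted DEG shifts.
SELECTION_CONFIG = SyntheticConfig(n_shifted_degs=0)

# Full null: no stage effect anywhere.
NULL_CONFIG = SyntheticConfig(
    stage_effect=0.0,
    progression_flags=(False, False, False, False),
    n_shifted_degs=0,
)

# Hub ranking: one module whose loadings span a wide range so the top-k
# set is identifiable from n = 36 samples (see docs/methods.md).
HUB_CONFIG = SyntheticConfig(
    module_sizes=(30,),
    progression_flags=(False,),
    n_background=100,
    loading_range=(0.2, 1.0),
    noise_sd=0.1,
    n_shifted_degs=0,
)

# High-SNR planted DEGs, no stage-coupled modules.
DEG_CONFIG = SyntheticConfig(
    progression_flags=(False, False, False, False),
    noise_sd=0.05,
)

# Heterogeneous module sizes over a large noise background produce the
# heavy-tailed connectivity distribution a scale-free fit rewards.
SCAN_CONFIG = SyntheticConfig(
    module_sizes=(100, 60, 40, 25, 15),
    progression_flags=(False,) * 5,
    n_background=300,
    loading_range=(0.3, 1.0),
    noise_sd=0.2,
    n_shifted_degs=0,
)


def detect_from_expression(
    expr: pd.DataFrame, beta: int = 6, **detect_kwargs
) -> ModulePartition:
    """Correlation -> adjacency -> TOM -> module detection with defaults."""
    cor = network.pairwise_correlation(expr)
    tom = network.topological_overlap(network.adjacency(cor, beta))
    return network.detect_modules(1.0 - tom, expr, **detect_kwargs)


def module_recovery_ari(seeds: list[int], config: SyntheticConfig = RECOVERY_CONFIG) -> pd.Series:
    """Adjusted Rand index of detected vs planted partition, per seed."""
    out = {}
    for seed in seeds:
        expr, _, truth = generate_expression(replace(config, seed=seed))
        partition = detect_from_expression(expr)
        out[seed] = adjusted_rand_score(
            truth.module_of_gene.to_numpy(), partition.labels.to_numpy()
        )
    return pd.Series(out, name="ari")


def _matched_label(truth: SyntheticTruth, partition: ModulePartition, module: str) -> str | None:
    """Recovered label holding the majority of a planted module's genes."""
    counts = partition.labels.loc[truth.members(module)].value_counts()
    top = counts.index[0]
    return None if top == GREY else str(top)


def selection_outcomes(
    config: SyntheticConfig,
    seed: int,
    epsilon: float = 0.05,
    alpha: float = 0.05,
    use_ordinal: bool = True,
) -> tuple[dict[str, bool], set[str], int]:
    """Run detection + selection once.

    Returns (planted module -> was its matched recovered module selected,
    selected labels, number of detected modules).
    """
    expr, annotation, truth = generate_expression(replace(config, seed=seed))
    partition = detect_from_expression(expr)
    if not partition.modules:
        return {m: False for m in config.module_names}, set(), 0
    eigengenes = network.module_eigengene(expr, partition)
    traits = make_trait_matrix(annotation, sample_order=list(expr.columns))
    mtc = traits_mod.module_trait_correlation(eigengenes, traits)
    ordinal = traits_mod.ordinal_trait_correlation(eigengenes, annotation)
    report = traits_mod.select_progression_modules(
        mtc, annotation.stage_order, epsilon=epsilon,
        ordinal=ordinal if use_ordinal else None, alpha=alpha,
    )
    selected = set(report.index[report["selected"]])
    outcome = {
        m: _matched_label(truth, partition, m) in selected for m in config.module_names
    }
    return outcome, selected, len(partition.modules)


def selection_operating_characteristics(
    seeds: list[int], config: SyntheticConfig = SELECTION_CONFIG
) -> dict[str, float]:
    """Sensitivity and false-selection rate of the progression rule."""
    tp = fn = fp = tn = 0
    for seed in seeds:
        outcome, _, _ = selection_outcomes(config, seed)
        for module, progression in zip(config.module_names, config.progression_flags):
            hit = outcome[module]
            if progression and config.stage_effect != 0:
                tp, fn = tp + hit, fn + (not hit)
            else:
                fp, tn = fp + hit, tn + (not hit)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_selection_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "n_progression_trials": tp + fn,
        "n_flat_trials": fp + tn,
    }


def null_selection_counts(seeds: list[int], config: SyntheticConfig = NULL_CONFIG) -> pd.Series:
    """Number of selected modules per seed under the no-effect null."""
    return pd.Series(
        {seed: len(selection_outcomes(config, seed)[1]) for seed in seeds},
        name="n_selected",
    )


def hub_recovery_overlap(
    seeds: list[int], k: int = 20, config: SyntheticConfig = HUB_CONFIG
) -> pd.Series:
    """Overlap of kME top-k with the k highest-loading planted genes."""
    module = config.module_names[0]
    out = {}
    for seed in seeds:
        expr, _, truth = generate_expression(replace(config, seed=seed))
        labels = truth.module_of_gene.replace("background", GREY)
        partition = ModulePartition(labels, 2, np.nan, 0.0)
        eigengenes = network.module_eigengene(expr, partition)
        kme = network.eigengene_connectivity(expr, eigengenes)
        hubs = top_hub_genes(kme, partition, [module], k=k)
        true_top = set(truth.loadings[truth.module_of_gene == module].nlargest(k).index)
        out[seed] = len(true_top & set(hubs.hubs[module].index))
    return pd.Series(out, name="overlap")


def sam_null_significant_counts(
    seeds: list[int],
    config: SyntheticConfig = SELECTION_CONFIG,
    target_fdr: float = 0.05,
    deltas: np.ndarray | None = None,
    n_perm: int = 100,
) -> pd.Series:
    """SAM significant count at the FDR-controlling delta, labels permuted.

    For each seed the stage labels are shuffled, deltas are scanned, and the
    count at the smallest delta with estimated FDR <= ``target_fdr`` is
    recorded (0 when no delta qualifies).
    """
    if deltas is None:
        deltas = np.arange(0.1, 2.01, 0.1)
    out = {}
    for seed in seeds:
        expr, annotation, _ = generate_expression(replace(config, seed=seed))
        rng = np.random.default_rng(seed + 10_000)
        shuffled = pd.Series(
            rng.permutation(annotation.stages.to_numpy()), index=annotation.stages.index
        )
        null_ann = SampleAnnotation(shuffled, annotation.stage_order)
        scan = differential.sam_delta_scan(
            expr, null_ann, annotation.stage_order[0], annotation.stage_order[-1],
            deltas=deltas, n_perm=n_perm, seed=seed,
        )
        controlled = scan[scan["fdr"] <= target_fdr]
        out[seed] = int(controlled.iloc[0]["n_significant"]) if len(controlled) else 0
    return pd.Series(out, name="n_significant")


def deg_exact_recovery(seed: int = 0, config: SyntheticConfig = DEG_CONFIG) -> dict[str, object]:
    """Fold-change calling at cutoff 1 vs the planted DEG truth."""
    expr, annotation, truth = generate_expression(replace(config, seed=seed))
    fc = differential.log2_fold_change(
        expr, annotation, annotation.stage_order[0], annotation.stage_order[-1]
    )
    called = differential.deg_set(differential.call_degs(fc, 1.0))
    return {
        "n_called": len(called),
        "n_planted": len(truth.deg_genes),
        "exact_match": called == truth.deg_genes,
    }
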