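"""Synthetic four-stage expression data with planted co-expression modules.

The generator emulates a microarray study design with four ordered disease
stages (normal tissue, chronic pancreatitis, pancreatic cancer, metastatic
pancreatic cancer), nine samples per stage. Genes fall into planted modules
driven by one latent factor per module, plus pure-noise background genes.
A subset of modules is "progression" modules: their latent stage means rise
monotonically through the stage order, symmetric around zero, so that the
module eigengene correlates negatively with the first stage and positively
with the last. A subset of background genes receives a fixed mean shift in
designated stages, planting known differentially expressed genes.

All values are generated directly on the log2 scale, so fold changes are
mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleAnnotation, write_annotation, write_expression_table

__all__ = [
    "DEFAULT_STAGES",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_stage_design",
    "generate_expression",
    "planted_log2fc",
]

DEFAULT_STAGES: tuple[str, ...] = ("normal", "pancreatitis", "cancer", "metastatic")

BACKGROUND = "background"


def generate_stage_design(
    n_per_stage: int, stage_names: Sequence[str] = DEFAULT_STAGES
) -> SampleAnnotation:
    """Balanced design: ``n_per_stage`` samples for each stage, in order."""
    if n_per_stage < 2:
        raise ValueError(f"n_per_stage must be >= 2, got {n_per_stage}")
    stage_names = tuple(stage_names)
    if not stage_names:
        raise ValueError("stage_names is empty")
    if len(set(stage_names)) != len(stage_names):
        raise ValueError(f"stage names are not unique: {stage_names}")
    samples, labels = [], []
    for stage in stage_names:
        for i in range(n_per_stage):
            samples.append(f"{stage}_{i + 1:02d}")
            labels.append(stage)
    return SampleAnnotation(
        pd.Series(labels, index=pd.Index(samples, name="sample")), stage_names
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module generator.

    Defaults mirror the four-stage, nine-samples-per-stage design: four
    50-gene modules (two progression, two flat) over 200 background genes,
    stage effect delta = 1 log2 unit, per-gene noise sd 0.2, latent factor
    sd 0.4, and 50 background genes shifted by 1.5 log2 units in every
    diseased stage.
    """

    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    n_background: int = 200
    n_per_stage: int = 9
    stage_names: tuple[str, ...] = DEFAULT_STAGES
    stage_effect: float = 1.0  # delta, log2 units
    progression_flags: tuple[bool, ...] = (True, True, False, False)
    loading_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.2  # sigma_e
    factor_sd: float = 0.4  # sigma_f
    baseline: float = 8.0  # log2 units; keeps 2**x - 1 back-transforms positive
    n_shifted_degs: int = 50
    deg_shift: float = 1.5  # log2 units, added in deg_stages
    deg_stages: tuple[int, ...] = (1, 2, 3)  # ordinal codes receiving the shift
    seed: int = 0
    n_genes: int | None = None  # optional; validated against sizes if given

    def __post_init__(self) -> None:
        for name in ("module_sizes", "progression_flags", "stage_names", "deg_stages"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(self, "loading_range", tuple(self.loading_range))
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if len(self.progression_flags) != len(self.module_sizes):
            raise ValueError("progression_flags must match module_sizes in length")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.n_genes is not None and self.n_genes != sum(self.module_sizes) + self.n_background:
            raise ValueError(
                f"n_genes={self.n_genes} inconsistent with "
                f"sum(module_sizes)+n_background={sum(self.module_sizes) + self.n_background}"
            )
        if self.n_per_stage < 2:
            raise ValueError("n_per_stage must be >= 2")
        if self.noise_sd <= 0 or self.factor_sd <= 0:
            raise ValueError("noise_sd and factor_sd must be > 0")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("loading_range must be within [0, 1] with lo <= hi")
        if self.n_shifted_degs > self.n_background:
            raise ValueError("n_shifted_degs cannot exceed n_background")
        bad = [k for k in self.deg_stages if not 0 <= k < len(self.stage_names)]
        if bad:
            raise ValueError(f"deg_stages out of range: {bad}")

    @property
    def total_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background

    @property
    def module_names(self) -> tuple[str, ...]:
        return tuple(f"M{i + 1}" for i in range(len(self.module_sizes)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    module_of_gene: pd.Series  # gene -> module name or "background"
    loadings: pd.Series  # gene -> loading (0 for background)
    stage_means: pd.DataFrame  # module x stage latent means
    shifts: pd.DataFrame = field(repr=False)  # gene x stage planted mean shifts
    progression_modules: tuple[str, ...] = ()

    @property
    def deg_genes(self) -> set[str]:
        """Genes with a planted stage-specific mean shift."""
        return set(self.shifts.index[(self.shifts != 0).any(axis=1)])

    def members(self, module: str) -> pd.Index:
        return self.module_of_gene.index[self.module_of_gene == module]


def _stage_means(config: SyntheticConfig) -> pd.DataFrame:
    k = len(config.stage_names)
    ramp = config.stage_effect * (np.arange(k) - (k - 1) / 2.0)
    rows = [ramp if flag else np.zeros(k) for flag in config.progression_flags]
    return pd.DataFrame(rows, index=list(config.module_names), columns=list(config.stage_names))


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SampleAnnotation, SyntheticTruth]:
    """Generate (expression, annotation, truth) for the configured design.

    Per gene i in module m and sample s:
        x_is = baseline + loading_i * f_m(s) + shift_i(stage(s)) + eps_is
    with f_m(s) ~ N(stage_means[m, stage(s)], factor_sd^2) shared by all
    genes of m within sample s, and eps iid N(0, noise_sd^2). Background
    genes have loading 0. Identical seed gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    annotation = generate_stage_design(config.n_per_stage, config.stage_names)
    n = annotation.n_samples
    stage_idx = annotation.ordinal.to_numpy()

    gene_ids = [f"gene_{i + 1:04d}" for i in range(config.total_genes)]
    module_labels: list[str] = []
    for name, size in zip(config.module_names, config.module_sizes):
        module_labels += [name] * size
    module_labels += [BACKGROUND] * config.n_background
    module_of_gene = pd.Series(module_labels, index=pd.Index(gene_ids, name="gene"))

    lo, hi = config.loading_range
    loadings = np.zeros(config.total_genes)
    n_module_genes = sum(config.module_sizes)
    loadings[:n_module_genes] = rng.uniform(lo, hi, n_module_genes)

    stage_means = _stage_means(config)
    # latent factor per (module, sample)
    factors = stage_means.to_numpy()[:, stage_idx] + rng.normal(
        0.0, config.factor_sd, (len(config.module_sizes), n)
    )

    # planted DEG shifts live on background genes so they do not perturb
    # the module structure
    shifts = np.zeros((config.total_genes, len(config.stage_names)))
    background_positions = np.arange(n_module_genes, config.total_genes)
    deg_positions = rng.choice(background_positions, size=config.n_shifted_degs, replace=False)
    for k in config.deg_stages:
        shifts[deg_positions, k] = config.deg_shift

    signal = np.zeros((config.total_genes, n))
    row = 0
    for m, size in enumerate(config.module_sizes):
        signal[row : row + size] = loadings[row : row + size, None] * factors[m][None, :]
        row += size
    signal += shifts[:, stage_idx]

    values = config.baseline + signal + rng.normal(0.0, config.noise_sd, (config.total_genes, n))
    expr = pd.DataFrame(values, index=module_of_gene.index, columns=annotation.sample_ids)

    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        loadings=pd.Series(loadings, index=module_of_gene.index),
        stage_means=stage_means,
        shifts=pd.DataFrame(
            shifts, index=module_of_gene.index, columns=list(config.stage_names)
        ),
        progression_modules=tuple(
            name
            for name, flag in zip(config.module_names, config.progression_flags)
            if flag and config.stage_effect != 0
        ),
    )
    return expr, annotation, truth


def planted_log2fc(truth: SyntheticTruth, stage_a: str, stage_b: str) -> pd.Series:
    """Expected per-gene log2 fold change of stage_b over stage_a.

    For a gene in module m: loading_i * (stage_means[m, b] - stage_means[m, a])
    plus any planted shift difference; pure-background genes give 0.
    """
    for s in (stage_a, stage_b):
        if s not in truth.stage_means.columns:
            raise KeyError(f"unknown stage {s!r}; known: {list(truth.stage_means.columns)}")
    diff = truth.stage_means[stage_b] - truth.stage_means[stage_a]
    per_module = truth.module_of_gene.map(diff).fillna(0.0)
    fc = truth.loadings * per_module + truth.shifts[stage_b] - truth.shifts[stage_a]
    fc.name = f"log2fc[{stage_b}-{stage_a}]"
    return fc


def write_truth_tables(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"module": truth.module_of_gene, "loading": truth.loadings}
    ).to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene")
    truth.stage_means.to_csv(outdir / "truth_stage_means.tsv", sep="\t", index_label="module")
    truth.shifts.loc[sorted(truth.deg_genes)].to_csv(
        outdir / "truth_deg_shifts.tsv", sep="\t", index_label="gene"
    )


def write_dataset(
    expr: pd.DataFrame,
    annotation: SampleAnnotation,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    """Write expression, annotation and truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_table(expr, outdir / "expression.tsv")
    write_annotation(annotation, outdir / "annotation.tsv")
    write_truth_tables(truth, outdir)
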