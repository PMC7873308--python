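"""End-to-end pipeline: data (synthetic or loaded) -> QC -> DEG/SAM ->
network -> modules -> trait selection -> hubs.

A single :class:`PipelineConfig` drives the run; every stochastic step is
seeded from the config seed through a fixed per-stage offset, so a run is
bitwise-reproducible. All intermediate tables are written as TSV, and the
run report re-reads the written tables to audit its own counts.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list

from . import differential, hubs as hubs_mod, network, traits as traits_mod
from .io import (
    SampleAnnotation,
    make_trait_matrix,
    read_annotation,
    read_expression_table,
    write_annotation,
    write_expression_table,
)
from .synthetic import SyntheticConfig, generate_expression, write_truth_tables

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "cluster_samples_qc"]

log = logging.getLogger("stagenet")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (kept below 2**31)."""
    return (seed * 1009 + zlib.crc32(stage.encode())) % (2**31)


def cluster_samples_qc(expr: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Returns the dendrogram leaf order and the merge table (heights and the
    joined cluster ids), ready for external plotting.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = expr.to_numpy().T
    if (x.std(axis=1) == 0).any():
        bad = list(expr.columns[x.std(axis=1) == 0])
        raise ValueError(f"constant samples: {bad}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    from scipy.spatial.distance import squareform

    linkage = average(squareform(d, checks=False))
    order = [expr.columns[i] for i in leaves_list(linkage)]
    merges = pd.DataFrame(linkage, columns=["left", "right", "height", "size"])
    return order, merges


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    stage_order: tuple[str, ...] | None = None  # required with file input
    deg_cutoff: float = 1.0
    sam_delta: float = 1.0
    sam_n_perm: int = 100
    beta: int | None = 6  # None -> auto-scan
    scan_betas: tuple[int, ...] = tuple(range(1, 13))
    target_r2: float = 0.8
    min_module_size: int = 30
    cut_height: float | None = None  # None -> 0.995 x max merge height
    merge_height: float = 0.25
    epsilon: float = 0.05
    use_ordinal: bool = True
    alpha: float = 0.05
    hub_k: int = 20
    edge_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        file_input = self.expression_path is not None or self.annotation_path is not None
        if (self.synthetic is None) == (not file_input):
            raise ValueError("provide exactly one of: synthetic config, input paths")
        if file_input and (self.expression_path is None or self.annotation_path is None):
            raise ValueError("file input needs both expression_path and annotation_path")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    seed: int
    n_genes: int = 0
    n_samples: int = 0
    stage_order: tuple[str, ...] = ()
    deg_counts: dict[str, int] = field(default_factory=dict)
    n_deg_intersection: int = 0
    sam_significant: int = 0
    sam_fdr: float = 0.0
    beta: int = 0
    beta_fallback: bool = False
    n_modules: int = 0
    module_sizes: dict[str, int] = field(default_factory=dict)
    n_grey: int = 0
    selected_modules: tuple[str, ...] = ()
    hub_pool_size: int = 0
    hub_deg_overlap: int = 0
    n_edges: int = 0
    wall_clock_s: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[pd.DataFrame, SampleAnnotation]:
    if config.synthetic is not None:
        # the pipeline seed governs generation so one flag reruns everything
        syn = replace(config.synthetic, seed=derive_seed(config.seed, "simulate"))
        expr, annotation, truth = generate_expression(syn)
        write_expression_table(expr, outdir / "expression.tsv")
        write_annotation(annotation, outdir / "annotation.tsv")
        write_truth_tables(truth, outdir)
        return expr, annotation
    expr = read_expression_table(config.expression_path)
    annotation = read_annotation(config.annotation_path, config.stage_order)
    annotation = annotation.reindex(expr.columns)
    return expr, annotation


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute the full analysis and write all tables under ``outdir``."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        report.outputs[name.removesuffix(".tsv")] = str(path)

    expr, annotation = _load_inputs(config, outdir)
    stage_order = annotation.stage_order
    report.n_genes, report.n_samples = expr.shape
    report.stage_order = stage_order
    log.info("loaded %d genes x %d samples, stages %s", *expr.shape, stage_order)

    # QC: sample clustering
    leaf_order, merges = cluster_samples_qc(expr)
    save("qc_sample_dendrogram.tsv", merges, index=False)
    (outdir / "qc_leaf_order.txt").write_text("\n".join(leaf_order) + "\n")

    # DEG calling: first stage vs every later stage
    reference = stage_order[0]
    deg_sets = []
    for stage in stage_order[1:]:
        fc = differential.log2_fold_change(expr, annotation, reference, stage)
        table = differential.call_degs(fc, config.deg_cutoff)
        save(f"deg_{reference}_vs_{stage}.tsv", table, index_label="gene")
        genes = differential.deg_set(table)
        deg_sets.append(genes)
        report.deg_counts[f"{reference}_vs_{stage}"] = len(genes)
    intersection = differential.multiway_intersection(deg_sets)
    report.n_deg_intersection = len(intersection)
    pd.Series(sorted(intersection), name="gene").to_csv(
        outdir / "deg_intersection.tsv", sep="\t", index=False
    )
    report.outputs["deg_intersection"] = str(outdir / "deg_intersection.tsv")

    # SAM on the extreme comparison (first vs last stage)
    sam = differential.sam_permutation_fdr(
        expr, annotation, reference, stage_order[-1],
        delta=config.sam_delta, n_perm=config.sam_n_perm,
        seed=derive_seed(config.seed, "sam"),
    )
    sam_table = pd.DataFrame(
        {"d": sam.d, "expected": sam.expected, "significant": sam.d.index.isin(list(sam.significant))}
    )
    save("sam.tsv", sam_table, index_label="gene")
    report.sam_significant = len(sam.significant)
    report.sam_fdr = sam.fdr

    # network construction
    cor = network.pairwise_correlation(expr)
    if config.beta is None:
        scan = network.soft_threshold_scan(cor, config.scan_betas, config.target_r2)
        save("soft_threshold_scan.tsv", scan.scan, index=False)
        beta = scan.chosen_beta
        report.beta_fallback = not scan.reached_target
    else:
        beta = config.beta
    report.beta = beta
    adj = network.adjacency(cor, beta)
    tom = network.topological_overlap(adj)
    partition = network.detect_modules(
        1.0 - tom, expr,
        min_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_height=config.merge_height,
    )
    save("modules.tsv", partition.labels.rename("module").to_frame(), index_label="gene")
    sizes = partition.sizes()
    report.module_sizes = {m: int(s) for m, s in sizes.items()}
    report.n_modules = len(partition.modules)
    report.n_grey = int(sizes.get(network.GREY, 0))
    log.info("detected %d modules (grey: %d) at beta=%d", report.n_modules, report.n_grey, beta)

    if report.n_modules == 0:
        report.wall_clock_s = time.time() - t0
        (outdir / "run_report.json").write_text(report.to_json() + "\n")
        return report

    eigengenes = network.module_eigengene(expr, partition)
    save("eigengenes.tsv", eigengenes.eigengenes, index_label="sample")
    kme = network.eigengene_connectivity(expr, eigengenes)
    save("kme.tsv", kme, index_label="gene")

    # module-trait correlation and progression selection
    trait_matrix = make_trait_matrix(annotation, sample_order=list(expr.columns))
    mtc = traits_mod.module_trait_correlation(eigengenes, trait_matrix)
    save("module_trait_r.tsv", mtc.r, index_label="module")
    save("module_trait_p.tsv", mtc.p, index_label="module")
    ordinal = traits_mod.ordinal_trait_correlation(eigengenes, annotation)
    save("ordinal_trait.tsv", ordinal, index_label="module")
    selection = traits_mod.select_progression_modules(
        mtc, stage_order, epsilon=config.epsilon,
        ordinal=ordinal if config.use_ordinal else None, alpha=config.alpha,
    )
    save("progression_selection.tsv", selection, index_label="module")
    selected = tuple(selection.index[selection["selected"]])
    report.selected_modules = selected
    log.info("selected progression modules: %s", list(selected) or "none")

    # hub genes of selected modules, overlap with the DEG intersection
    hub_modules = list(selected) if selected else []
    if hub_modules:
        hub_set = hubs_mod.top_hub_genes(kme, partition, hub_modules, k=config.hub_k)
        save("hub_genes.tsv", hub_set.as_table(), index=False)
        overlap = hubs_mod.hub_deg_overlap(hub_set, intersection)
        save("hub_deg_overlap.tsv", overlap.per_module, index=False)
        report.hub_pool_size = overlap.hub_pool_size
        report.hub_deg_overlap = overlap.total_overlap
        edges = hubs_mod.coexpression_edges(cor, sorted(hub_set.pool), config.edge_threshold)
        save("hub_edges.tsv", edges, index=False)
        report.n_edges = len(edges)

    report.wall_clock_s = time.time() - t0
    (outdir / "run_report.json").write_text(report.to_json() + "\n")
    _audit(report, outdir)
    return report


def _audit(report: RunReport, outdir: Path) -> None:
    """Re-read written tables and check the report's counts against them."""
    for path in report.outputs.values():
        if not Path(path).exists():
            raise RuntimeError(f"report lists missing output {path}")
    modules = pd.read_csv(outdir / "modules.tsv", sep="\t", index_col=0)["module"]
    n_grey = int((modules == network.GREY).sum())
    n_modules = modules[modules != network.GREY].nunique()
    if (n_grey, n_modules) != (report.n_grey, report.n_modules):
        raise RuntimeError("module counts in report disagree with written table")
    for name, count in report.deg_counts.items():
        table = pd.read_csv(outdir / f"deg_{name.replace('_vs_', '_vs_')}.tsv", sep="\t")
        if int((table["direction"] != "none").sum()) != count:
            raise RuntimeError(f"DEG count mismatch for {name}")
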