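#!/usr/bin/env python
"""Stage-ordered progression-module selection and hub-gene analysis.

Correlates module eigengenes with the 0/1 stage traits and the ordinal
stage code, selects modules whose correlations rise monotonically from
negative (normal) to positive (metastatic), extracts each selected
module's top-20 kME hub genes, intersects them with the three-way DEG
intersection, and exports a co-expression edge list and a log2(x+1)
heatmap matrix. Writes results/progression/.
"""

from pathlib import Path

import pandas as pd

from stagenet import hubs as H, network, traits as T
from stagenet.io import make_trait_matrix, read_annotation, read_expression_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "progression"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_expression_table(ROOT / "data" / "expression.tsv")
    annotation = read_annotation(ROOT / "data" / "annotation.tsv").reindex(expr.columns)
    labels = pd.read_csv(ROOT / "network" / "modules.tsv", sep="\t", index_col=0)["module"]
    partition = network.ModulePartition(labels, 0, float("nan"), 0.0)
    eigengenes = network.module_eigengene(expr, partition)
    kme = pd.read_csv(ROOT / "network" / "kme.tsv", sep="\t", index_col=0)

    traits = make_trait_matrix(annotation, sample_order=list(expr.columns))
    mtc = T.module_trait_correlation(eigengenes, traits)
    mtc.r.to_csv(OUT / "module_trait_r.tsv", sep="\t", index_label="module")
    mtc.p.to_csv(OUT / "module_trait_p.tsv", sep="\t", index_label="module")
    ordinal = T.ordinal_trait_correlation(eigengenes, annotation)
    report = T.select_progression_modules(
        mtc, annotation.stage_order, epsilon=0.05, ordinal=ordinal, alpha=0.05
    )
    report.to_csv(OUT / "progression_selection.tsv", sep="\t", index_label="module")
    selected = list(report.index[report["selected"]])
    print("stage-ordered eigengene correlations:")
    print(mtc.r.round(2).to_string())
    print(f"selected progression modules: {selected or 'none'}")
    if not selected:
        return

    hub_set = H.top_hub_genes(kme, partition, selected, k=20)
    hub_set.as_table().to_csv(OUT / "hub_genes.tsv", sep="\t", index=False)
    degs = set(
        pd.read_csv(ROOT / "differential" / "deg_intersection.tsv", sep="\t")["gene"]
    )
    overlap = H.hub_deg_overlap(hub_set, degs)
    overlap.per_module.to_csv(OUT / "hub_deg_overlap.tsv", sep="\t", index=False)
    print(
        f"{overlap.total_overlap} of {overlap.hub_pool_size} hub genes overlap "
        f"the {overlap.deg_pool_size}-gene DEG intersection"
    )

    cor = network.pairwise_correlation(expr)
    edges = H.coexpression_edges(cor, sorted(hub_set.pool), threshold=0.5)
    edges.to_csv(OUT / "hub_edges.tsv", sep="\t", index=False)
    print(f"exported {len(edges)} co-expression edges (|r| >= 0.5) among hub genes")

    raw = (2.0 ** expr.loc[sorted(hub_set.pool)]) - 1.0  # back to raw scale
    heat = H.heatmap_matrix(raw, sorted(hub_set.pool), annotation)
    heat.to_csv(OUT / "hub_heatmap_log2p1.tsv", sep="\t", index_label="gene")
    print(f"heatmap matrix: {heat.shape[0]} genes x {heat.shape[1]} stage-ordered samples")


if __name__ == "__main__":
    main()
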