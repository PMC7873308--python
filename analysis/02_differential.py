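#!/usr/bin/env python
"""Differential expression over the disease course.

QC-clusters the samples, calls fold-change DEGs for normal vs each diseased
stage (|log2FC| > 1), runs the SAM permutation test on the extreme
comparison, and intersects the three DEG sets. Reads results/data/, writes
results/differential/.
"""

from pathlib import Path

import pandas as pd

from stagenet import differential as D
from stagenet.io import read_annotation, read_expression_table
from stagenet.pipeline import cluster_samples_qc

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "differential"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_expression_table(ROOT / "data" / "expression.tsv")
    annotation = read_annotation(ROOT / "data" / "annotation.tsv").reindex(expr.columns)
    reference = annotation.stage_order[0]

    leaf_order, merges = cluster_samples_qc(expr)
    merges.to_csv(OUT / "qc_sample_dendrogram.tsv", sep="\t", index=False)
    stages = [annotation.stages[s] for s in leaf_order]
    blocks = 1 + sum(a != b for a, b in zip(stages, stages[1:]))
    print(f"sample dendrogram: {blocks} stage blocks across {len(leaf_order)} leaves")

    deg_sets = []
    for stage in annotation.stage_order[1:]:
        fc = D.log2_fold_change(expr, annotation, reference, stage)
        table = D.call_degs(fc, cutoff=1.0)
        table.to_csv(OUT / f"deg_{reference}_vs_{stage}.tsv", sep="\t", index_label="gene")
        genes = D.deg_set(table)
        deg_sets.append(genes)
        print(f"{reference} vs {stage}: {len(genes)} DEGs at |log2FC| > 1")

    intersection = D.multiway_intersection(deg_sets)
    pd.Series(sorted(intersection), name="gene").to_csv(
        OUT / "deg_intersection.tsv", sep="\t", index=False
    )
    print(f"DEGs shared by all {len(deg_sets)} comparisons: {len(intersection)}")

    sam = D.sam_permutation_fdr(
        expr, annotation, reference, annotation.stage_order[-1],
        delta=1.0, n_perm=100, seed=seed,
    )
    pd.DataFrame(
        {"d": sam.d, "expected": sam.expected,
         "significant": sam.d.index.isin(list(sam.significant))}
    ).to_csv(OUT / "sam.tsv", sep="\t", index_label="gene")
    print(
        f"SAM ({reference} vs {annotation.stage_order[-1]}, delta=1): "
        f"{len(sam.significant)} significant, FDR ~ {sam.fdr:.3f}, s0 = {sam.s0:.3f}"
    )


if __name__ == "__main__":
    main()
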