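# stagenet

Weighted gene co-expression network analysis with **stage-ordered
progression-module selection**, for expression studies whose samples span an
ordered disease course — the motivating design is pancreatic disease with
four stages (normal tissue, chronic pancreatitis, pancreatic cancer,
metastatic pancreatic cancer), nine samples per stage.

Most co-expression studies pick the module with the highest correlation to a
single trait. Here the stages are treated as ordered traits, and the modules
of interest are those whose eigengene–trait correlations *rise monotonically
from negative in normal tissue to positive in metastatic disease* — gene
networks gradually activated as the disease progresses.

## What it computes

* **Differential expression** — per-gene log2 fold change (expression is
  log2-scale, so FC is a mean difference) with the strict cutoff
  |log2FC| > 1, and the SAM (significance analysis of microarrays)
  moderated statistic d_i = (x̄_iB − x̄_iA)/(s_i + s0) with permutation-based
  expected order statistics, the Δ criterion and a median-based FDR
  estimate. DEG sets from several comparisons can be intersected.
* **Co-expression network** — Pearson correlation, unsigned soft-threshold
  adjacency a_ij = |r_ij|^β with β chosen by the scale-free topology fit
  (R² of the log–log connectivity regression), and the topological overlap
  matrix TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).
* **Modules** — average-linkage clustering of 1 − TOM with a static tree
  cut, minimum module size, eigengene-correlation merging, and a kME
  membership filter; labels follow the WGCNA colour palette by size, with
  unassigned genes "grey".
* **Module eigengenes and kME** — first principal component per module
  (unit norm, sign-aligned) and each gene's correlation with each eigengene.
* **Progression-module selection** — per-module correlations with the 0/1
  stage indicators; selected iff the stage-ordered sequence starts negative,
  ends positive, never drops by more than ε (default 0.05) between adjacent
  stages, and (by default) the correlation with the ordinal stage code
  0..3 is significant at α = 0.05.
* **Hub genes** — top-20 members of each selected module by kME, their
  overlap with the DEG intersection, a co-expression edge list (Cytoscape-
  ready TSV), and a log2(x+1) heatmap matrix with stage-ordered columns.
* **Synthetic data** — a planted-module generator (latent factor per module,
  monotone stage means for progression modules, shifted background genes as
  known DEGs) so every step is verifiable by parameter recovery.

## Worked example

```sh
python analysis/01_simulate.py        # default planted design, seed 0
python analysis/02_differential.py
python analysis/03_network_modules.py
python analysis/04_progression_hubs.py
python analysis/05_benchmarks.py
```

The default design plants four 50-gene modules (M1, M2 with a monotone
stage effect δ = 1; M3, M4 flat) over 200 background genes, 50 of which are
shifted by 1.5 log2 units in every diseased stage. The run prints:

```
normal vs pancreatitis: 114 DEGs at |log2FC| > 1
normal vs cancer: 150 DEGs at |log2FC| > 1
normal vs metastatic: 150 DEGs at |log2FC| > 1
DEGs shared by all 3 comparisons: 114
beta = 6: 3 modules, sizes {'turquoise': 150, 'blue': 50, 'brown': 50, 'grey': 150}
stage-ordered eigengene correlations:
           normal  pancreatitis  cancer  metastatic
turquoise   -0.90         -0.01    0.32        0.60
blue         0.08         -0.10    0.00        0.02
brown        0.01         -0.06    0.10       -0.05
selected progression modules: ['turquoise']
20 of 20 hub genes overlap the 114-gene DEG intersection
```

The two planted progression modules share the stage-mean ramp, so their
eigengenes correlate strongly and they merge into one detected module
(turquoise, together with the stage-shifted DEG cluster); its correlation
sequence −0.90 → −0.01 → 0.32 → 0.60 is exactly the planted monotone
negative-to-positive signature, while the flat modules (blue, brown) show
no trend and are not selected. The benchmark driver reports planted-module
recovery (mean adjusted Rand index 0.98), hub top-20 recovery (18.6/20),
selection sensitivity 1.00 with false-selection rate 0.00, and clean null
behaviour.

The same steps are available as a CLI (`stagenet simulate|qc|deg|sam|
network|traits|hubs|run-all`), e.g.

```sh
stagenet run-all --seed 2 --outdir out/
```

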