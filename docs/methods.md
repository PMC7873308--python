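# Methods

## Model and pipeline

The package analyses a gene × sample table of log2-scale expression values
from a design with K ordered disease stages (default K = 4: normal,
pancreatitis, cancer, metastatic; nine samples per stage, n = 36). Because
the input is log2-scale, a fold change is a group-mean difference; a flag on
loading can log2-transform raw-scale data instead. The pipeline is:

1. **QC** — average-linkage clustering of samples on 1 − Pearson
   correlation; leaf order and merge heights are exported for plotting.
2. **Differential expression** — log2FC of the reference (first) stage vs
   each later stage, DEGs at strict |log2FC| > 1 (strict because the cutoff
   is stated as an exclusive inequality); SAM on the extreme comparison.
3. **Network** — Pearson correlation; unsigned adjacency |r|^β; topological
   overlap; modules from average-linkage clustering of 1 − TOM.
4. **Progression selection** — eigengene correlations with 0/1 stage
   indicators and the ordinal stage code 0..K−1; monotone negative-to-
   positive selection rule.
5. **Hubs** — per selected module, the top-k members by kME; overlap with
   the multi-comparison DEG intersection; edge-list and heatmap exports.

## SAM statistic

d_i = (x̄_iB − x̄_iA)/(s_i + s0), where s_i = sqrt(a·(SS_A + SS_B)) with
a = (1/n_A + 1/n_B)/(n_A + n_B − 2). With s0 = 0, d is exactly the pooled
two-sample t statistic (verified against an independent t computation). The
fudge factor s0 is a quantile of {s_i} (default: median). This single-
quantile estimator replaces the original two-dimensional coefficient-of-
variation optimisation; it is documented, swappable via `s0_quantile`, and
sufficient for the rank-based use made of d here. Significance uses the
standard Δ criterion against expected order statistics averaged over label
permutations; all C(n, n_A) distinct assignments are enumerated when their
count does not exceed `n_perm`, making small problems seed-independent. The
FDR estimate is the median permuted count beyond the observed cut-points
divided by the observed significant count, clipped to [0, 1]. s0 is
recomputed per permutation with the same rule, so permuted statistics are
computed exactly as the observed one. With correlated genes (co-expression
modules are the object of study) the permutation FDR estimate can be
anti-conservative in single runs; the null benchmark therefore reports the
median over 20 runs.

## Scale-free fit and β

Connectivity k_i = Σ_{j≠i} a_ij is binned into 10 equal-width bins;
log10(frequency) is regressed on log10(mean k) over non-empty bins; the fit
index is R² × sign(−slope). The chosen β is the smallest candidate with
index ≥ 0.8, else the index-maximising β with a fallback flag. The default
analysis uses β = 6, the conventional unsigned-network default for this
sample size; the scan table is always written alongside. The scan benchmark
uses a generator configuration with heterogeneous module sizes
(100/60/40/25/15) over 300 noise genes, because a connectivity distribution
only shows a heavy tail when hub-rich modules of many sizes coexist with
many low-connectivity genes; equal-size blocks produce a bimodal k
distribution that no power makes scale-free (best index ≈ 0.75).

## Module detection

Average linkage on 1 − TOM, static cut at 0.995 × the highest merge height
(configurable absolute `cut_height`), size filter (default min 30), then
iterative merging of the closest module pair while any eigengene pair
correlates above 1 − `merge_height` (default 0.25). A static cut alone
absorbs noise genes into modules: at n = 36, a pure-noise gene reaches
|r| ≈ 0.3–0.5 with some module factor by chance, which after β = 6
amplification still yields enough topological overlap to attach below the
cut (≈ 10–20 noise genes per 50-gene module in simulation). Detection
therefore ends with a **membership filter**: genes whose kME to their own
module falls below `min_kme` (default 0.5) are reassigned to grey, and the
size filter is re-applied. The 0.5 default sits midway between the chance
kME of noise genes (|kME| ≲ 0.4 at n = 36) and the weakest genuine members
in the planted designs (kME ≈ 0.77 at loading 0.6, σ_e = 0.2). Ties in
label ordering are broken by gene input order, and module labels follow the
WGCNA colour palette in decreasing size order — the palette reproduces the
field's colour vocabulary without claiming to match any particular study's
assignment.

## Eigengenes and kME

Per module, member genes are z-scored across samples and the eigengene is
the first right-singular vector of the standardized block (unit Euclidean
norm), sign-flipped when negatively correlated with the module's mean
standardized profile; variance explained is the first squared singular
value over the total. kME is the Pearson correlation of each gene with each
eigengene. An independent eigendecomposition of the sample covariance
reproduces the eigengene to |r| = 1 within 1e−8 (tested).

## Progression-module selection

With stage-ordered correlations (r_1, …, r_K), a module is selected iff
r_1 < 0, r_K > 0, and r_{j+1} ≥ r_j − ε for every step. "Gradually
increasing" is qualitative, so the slack ε (default 0.05) absorbs
estimation noise and is exposed as a flag; the selected set is monotone in
ε (tested). Sign-and-shape constraints alone are weak at n = 36: a
pure-noise eigengene satisfies them with probability ≈ 0.086 at ε = 0.05
(Monte Carlo), which is far too permissive for a rule meant to single out a
handful of modules. The default selection therefore also requires the
module's correlation with the ordinal stage code (0, 1, …, K−1) to be
significant (two-sided t test, α = 0.05), which drops the null selection
probability to ≈ 0.014 while leaving genuine monotone modules (r_ord ≈ 0.9
in the planted design) untouched. `select_progression_modules` accepts
`ordinal=None` for the bare rule. One-hot p-values are reported but never
used for selection.

## Synthetic-data generator

Gene i in module m, sample s: x = baseline + loading_i · f_m(s) +
shift_i(stage(s)) + ε, with f_m(s) ~ N(μ_{m,stage(s)}, σ_f²) shared by the
module's genes within a sample (the latent factor the eigengene estimates),
ε ~ N(0, σ_e²) iid, and background genes pure noise. Progression modules
get the centred ramp μ_k = δ·(k − (K−1)/2) — for K = 4:
(−1.5δ, −0.5δ, 0.5δ, 1.5δ) — flat modules all-zero means. Planted DEGs are
background genes shifted by `deg_shift` in designated stages (default: all
diseased stages), so their expected log2FC vs normal equals the shift.
Defaults are the study conditions: four 50-gene modules (two progression),
200 background genes, n_per_stage = 9, δ = 1, σ_e = 0.2, σ_f = 0.4,
loadings uniform on [0.6, 1.0], baseline 8 log2 units (so 2^x − 1
back-transforms stay positive), 50 shifted genes at 1.5 log2 units.

What the generator does **not** emulate: microarray probe effects,
background subtraction, batch effects, heavy-tailed or heteroscedastic
noise, and correlated background structure. Passing recovery tests
demonstrates the pipeline recovers its own generative model's structure —
a necessary correctness check — not that it would recover modules in real
tissue data with those artefacts.

Note that planted DEG genes share a step pattern and are therefore
genuinely co-expressed; they legitimately form a module of their own (and,
having a stage-increasing eigengene, can merge with progression modules).
Benchmarks whose truth is the module partition or the absence of stage
structure set `n_shifted_degs = 0`.

## Benchmark designs and problem sizes

All benchmarks run on 400-gene (or smaller) designs so the full suite
completes in seconds; the construction is O(p²) in genes and the same code
paths run at any size.

* **Module recovery** — four independent-factor (flat) modules, σ_e/σ_f =
  0.25, five seeds; scored by adjusted Rand index against the planted
  partition (mean ≈ 0.98). Flat rather than progression modules, because
  two progression modules share the stage ramp, correlate ≈ 0.89 > the
  merge threshold 0.75, and merge by design — clustering accuracy is the
  quantity under test here, not merging.
* **Selection operating characteristics** — the default design (two
  progression + two flat modules), ten seeds; each planted module is
  matched to the detected module holding the majority of its genes, so the
  score is robust to the expected merging of the two progression modules.
* **Hub ranking** — one 30-gene module with loadings spanning [0.2, 1.0],
  σ_e = 0.1, k = 20. The wide span is an identifiability requirement, not a
  convenience: correlation-based ranks separate at rate Δz ≈ Δloading /
  loading on the Fisher scale, so with loadings on [0.6, 1.0] the top-20-
  of-50 boundary genes differ by ≪ the sampling noise of kME at n = 36 and
  no correct implementation could recover them; with the wide-span 30-gene
  module the top-20 set is well separated (mean overlap ≈ 18.6/20).
* **Nulls** — δ = 0 with no shifts for selection (no module selected in
  10/10 seeds); label permutation for SAM (median significant count 0 at
  the smallest FDR ≤ 0.05 delta over a Δ grid of 0.1–2.0).

## Numerical choices and degenerate inputs

Correlation and TOM matrices are explicitly symmetrised ((M + Mᵀ)/2)
because BLAS products are not bitwise symmetric; diagonals are set exactly.
Zero-variance genes are an error listing the offending ids (callers drop
them); a zero-variance group in SAM is allowed (s_i = 0 is caught by s0).
Degenerate connectivity (all equal) reports fit index 0 with a warning.
Sample order alignment between expression, traits and eigengenes is
enforced positionally. Pipeline sub-seeds derive from the run seed via a
fixed affine-CRC map and stay below 2³¹; identical configs give bitwise-
identical outputs (tested).

## Known limitations

* Static cut + kME filter is simpler than dynamic tree cutting; deeply
  nested or close-sized modules may be split or merged differently.
* The SAM FDR estimator ignores gene–gene correlation within a run.
* The ordinal trend filter assumes equally spaced stages; a monotone but
  saturating trend with a weak ordinal correlation could be missed at
  small n.
* Module counts and sizes from any particular tissue study are not
  reproduction targets: they depend on the data and on unreported
  clustering parameters; this package targets the method's properties,
  which are what the test suite and the acceptance script measure.
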