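# Methods

`dmfusion` implements a complete, desk-scale pipeline for discovering
gene-expression biomarkers of distant metastasis (DM) in carcinoma
cohorts and for classifying DM status from multimodal data: bulk
RNA-seq expression (TPM), H&E histopathology patches, and routine
clinical variables. This note documents the models, the defaults and
their rationale, the synthetic data the package is validated on, and
the known limitations.

## Expression preprocessing

Per-sample TPM tables are outer-joined on the gene universe; absent
entries and NaNs become 0. Values are transformed as `log10(x + 1)`.
The bare log10 is undefined at zero, and TPM tables are zero-rich; the
+1 pseudocount keeps zeros at zero and is monotone, so downstream
rankings are unaffected except at exact ties. Genes that are zero in
**strictly more than 80%** of samples are removed (a gene at exactly
80% is kept), then the top 10,000 genes by per-gene variance are
retained. Variance is the population variance (ddof = 0) of the
log-transformed values, with ties broken by gene identifier so the
filter is fully deterministic. The chain is idempotent on its own
output, and no gene filter ever changes the sample count.

## Frequency-ranked iterative random-forest selection

The selection signal is stability under refitting, not any single
model's importance. With `N` iterations (default 1000) and `top_k = K`
(default 100):

1. each iteration fits a fresh random forest (default 500 trees) to
   classify DM vs non-DM, seeded from the master seed by a counter
   scheme so iterations are independent but reproducible;
2. the K genes with the highest importances are recorded
   (ties broken by gene ID ascending);
3. after N iterations, genes are ranked by how many times they appeared
   in a top-K list (frequency), with mean importance over all N
   iterations and then gene ID as tie-breakers;
4. the top `n_select` (default 50) form the gene panel.

Between iterations only the forest's internal randomness (bootstrap
resampling and feature subsampling) varies; an optional
`subsample_fraction` additionally refits on stratified subsamples.
Importance is mean impurity decrease by default; permutation importance
is selectable (slower, less biased toward high-cardinality features —
immaterial here since all features are continuous expression values).
The per-iteration top-K lists are retained in `iteration_log`, so the
final tally can always be re-derived by brute-force recount; the test
suite does exactly that, and also checks the invariant
`sum(frequencies) == N * min(K, n_genes)`.

A univariate Welch-t ranker (`rank_genes_by_tstat`) is provided as a
desk-scale baseline for comparing multivariate selection against simple
differential expression; it is not a negative-binomial differential
expression test and is not meant to be one.

## Panel benchmarking and specificity experiments

Panels are evaluated with a linear-kernel SVM, KNN (k = 5) and a random
forest (500 trees) on the top-s genes for each s in the ladder
30, 25, 20, 15, 10, 5, 3, 2, 1. Two protocols are reported: a
stratified 75:25 hold-out, and stratified 5-fold cross-validation over
the full group, as mean ± SD of accuracy, F1 and AUROC. AUROC is
computed from continuous decision scores (SVM margin, class
probabilities otherwise), never from hard labels. Features are
standardized inside each training fold for the margin/distance models.
Fold assignments and the hold-out split are shared across models so
comparisons are paired.

Specificity of a signature is probed two ways: `cross_apply` evaluates
one group's panel on another group's cohort (genes missing from the
target are dropped; an empty intersection is an error), and
`union_panel` pools per-group panels (order-stable, first occurrence
wins) for evaluation at the combined budget. On cohorts whose
signature genes are disjoint by construction, the expected direction is
own-panel > cross-applied and own-panel > union — the acceptance suite
checks exactly this direction, not any particular AUROC value.

## Patch funnel

Slides are analyzed as 512×512 RGB patches. The funnel:

1. up to 500 random non-overlapping patches (rejection sampling of
   top-left corners, stopping after 10× the cap in failed proposals;
   a deterministic grid mode is the extraction alternative upstream);
2. patches with tissue fraction ≥ 0.80 survive; if more than 200 do, a
   uniform random subsample of 200 is taken under the stage seed;
3. the 60 patches with the highest cellularity survive, ties broken by
   origin in row-major order.

A pixel counts as background glass when its minimum channel is ≥ 200
and its channel spread is ≤ 30 — bright and unsaturated — which
separates blank glass from eosin-pink/hematoxylin-purple tissue; the
rule is configurable. Cellularity is pluggable; the default scorer
deconvolves the patch into H&E channels, thresholds the hematoxylin
channel (OD > 0.05) and counts connected components with area ≥ 20 px.
On rendered fixtures with non-overlapping nuclei the score equals the
true nucleus count; on real tissue it is a proxy, and any callable
`patch -> float` (e.g. a segmentation-network counter) can replace it.

## Macenko stain normalization

Optical density is `OD = -log10((I + 1) / 256)` per channel. Pixels
with all OD ≤ β = 0.15 are discarded as glass; at least 100 tissue
pixels are required, otherwise an `InsufficientTissueError` is raised
and the patch is excluded. The OD cloud is projected onto the plane of
its top two singular vectors, and the robust extreme directions at the
α = 1 and 99 angle percentiles become the stain vectors; the column
with the larger red-channel OD is labelled hematoxylin (hematoxylin
absorbs red most strongly). Columns are clipped to nonnegative and
normalized to unit length. Per-pixel concentrations are solved by
nonnegative least squares — for a 3×2 system the exact active-set
solution (unconstrained solve, then clamp-and-resolve) vectorizes over
all pixels. Normalization scales each stain's concentrations so the
source's 99th-percentile concentration matches the reference's, then
reconstructs RGB with the reference stain matrix, clipped to [0, 255].

Validation is by forward synthesis: a patch rendered from known stain
parameters (with hematoxylin-dominant, eosin-dominant and mixed pixel
populations, so the angle percentiles can reach the pure directions) is
re-normalized against those same parameters and must reconstruct within
2 mean absolute intensity levels; measured error is ~0.2 levels, and
re-normalizing an already-normalized patch moves pixels by ≤ 2 levels.

## Image features and aggregation

Labels exist per patient, not per patch (weak supervision), so patch
features are mean-pooled: the patient vector is the element-wise
arithmetic mean of its patch vectors. Any extractor honoring the
32-dimension contract can be plugged in — the interface matches a CNN
head whose last hidden layer has 32 units (reference head: global
average pooling, dropout 0.1/0.2/0.05, dense 512/32/1, Adam at 1e-4,
40 epochs; loading and fine-tuning such weights is outside this
package's scope). The default `Handcrafted32` extractor needs no
weights: 8-bin intensity histograms per RGB channel (24), per-channel
mean and SD (6), fraction of pixels above the hematoxylin OD threshold
(1), and mean Sobel edge magnitude (1). It is deterministic and
separates the synthetic cohort's cellularity classes (linear-probe
AUROC > 0.7), which is all the fusion experiments require of it.

## Clinical cleaning and late fusion

Four variables enter the clinical block: age, T stage, N stage, and
positive-node count. Missing age is imputed with the rounded mean age
of the patient's cancer type; missing/invalid stages and node counts
become 0; min-max normalization is applied to age and node count over
the whole cohort (cleaning is treated as a preprocessing step; model
standardization is still fit per training split). Encoding an invalid
N stage as 0 collides with genuine N0 — the rule is kept as stated and
the ambiguity documented. Stages enter as ordinals.

Fusion is late: blocks (genomic = log-TPM of the selected panel, image
= 32-dim patient vector, clinical = 4 variables) are concatenated
column-wise with provenance-carrying column names, then a single
classifier is fit. Evaluation is Monte-Carlo cross-validation: 5
independent stratified 80:20 resplits, shared across classifiers;
a split with a single-class test set is redrawn (≤ 10 retries).
Classifiers are a linear SVM and a single-hidden-layer MLP (32 units);
blocks are standardized per training split so a wide genomic block
cannot numerically swamp 4 clinical columns. `modality_report` runs
the six combinations — Clinical, Image, Genomic, Genomic+Image,
Clinical+Genomic, Genomic+Image+Clinical — and tabulates mean ± SD of
accuracy, F1 and AUROC per classifier.

## Synthetic cohort generator

The generator is first-class code: every downstream stage is validated
against its planted ground truth.

- **Expression.** Per-gene log10-mean ~ Uniform(−1, 3) and log10-SD ~
  Uniform(0.2, 0.6): a log-normal on the TPM scale spanning four orders
  of magnitude, which is what motivates the log transform. Each cancer
  type owns a disjoint set of planted genes (enforced under
  `specificity_mode`) whose log10 mean is shifted by `effect_size`
  (default 1.0) in that type's DM samples only. Zero inflation
  (default 0.10) replaces drawn values by 0 after the draw; NaN
  injection (default 0.01) follows as a distinct event, matching the
  treatment of NaN-replacement and true zeros as different phenomena.
- **Clinical.** Age ~ round(Normal(63, 9)) clipped to [40, 90] — the
  cohorts this emulates average 61–63 years; positive-node count ~
  Poisson(1.5 + clinical_effect·DM) with N stage derived from the node
  count by the usual 0 / 1–2 / 3–6 / >6 banding, so the clinical signal
  is label-linked but noisy. Missingness defaults: node count 20%
  (configurable per group up to the ~33% seen in bladder-cancer-like
  cohorts), age 5%, stage 5%.
- **Patches.** Tissue patches are a noisy eosin-pink field with dark
  elliptical nuclei at rejection-sampled positions (minimum center
  distance 2·radius, so blobs never merge and the rendered count is an
  unambiguous cellularity ground truth); glass patches are near-white.
  The rendered count is stored per patch. DM patients draw nucleus
  counts around density 45, non-DM around 30, with a per-patient
  lognormal multiplier (SD 0.35) and Poisson patch-level counts —
  without that heterogeneity the image block is a perfect predictor,
  which no histology cohort is; with it the image block is informative
  but imperfect, the profile the fusion experiments assume
  (genomic strong, image moderate, clinical weak).

One seed drives everything; the same config reproduces the cohort bit
for bit, pixels included. What the generator does **not** emulate:
real H&E texture, nucleus morphology or color variation between
scanners; slide pyramids; survival endpoints; any quantitative claim
about how DM changes primary-tumor morphology (the density shift is a
stand-in that makes the image pathway testable, not a biological
claim). Passing tests therefore demonstrate the pipeline's
correctness and calibration, not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script run a desk-scale profile chosen to
exercise every code path with comfortable statistical margins: cohorts
of 48 samples × 200 genes, selection at N = 30–50 iterations, K = 10,
forests of 100 trees, 5–20 seeded replicates per stochastic property;
funnel checks use a 310-patch synthetic slide and Macenko checks a
128×128 synthesized patch. Library defaults remain the full-scale
protocol (N = 1000, K = 100, top-50 panels, 500 trees, 10,000-gene
variance filter). Specificity experiments use effect size 0.7: at 1.0
the own-panel AUROC saturates at 1.0 and the own-vs-union comparison
degenerates into ties, whereas 0.7 lands own-panel AUROC in the
0.87–0.97 range typical of real DM cohorts, where the dilution effect
of pooled panels is measurable.

All randomness flows from one master seed through named, hashed
sub-streams (`dmfusion._seeds`), so stages are individually
reproducible and statistically independent. Classifier seeds are
reduced modulo 2³¹−1 for scikit-learn. Degenerate inputs are handled
explicitly: single-class labels raise; K > n_genes clamps with a
warning; zero-variance genes get t = 0; empty funnel output warns and
flags the patient; a patch without 100 OD pixels is excluded from
stain fitting with a logged error.

## Known limitations

- Impurity-based importance can dilute frequency ranks among strongly
  correlated genes (they share appearances); permutation importance
  mitigates but does not remove this.
- The default cellularity scorer counts connected components, so it
  undercounts overlapping nuclei on real tissue.
- Min-max clinical scaling uses the whole cohort, which leaks range
  information across CV splits; the effect is negligible for bounded
  ordinal-like variables but is documented here deliberately.
- The t-statistic baseline is not a substitute measurement of
  differential expression for publication purposes.
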