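# dmfusion

Distant metastasis (DM) — spread of a carcinoma from the primary site
to distant organs — drives most cancer mortality, yet it is often not
detectable at initial presentation and has no standard biomarkers.
`dmfusion` is a tested, reusable pipeline for (1) discovering
gene-expression biomarkers of DM from primary-tumor RNA-seq and (2)
classifying DM status from multimodal data: gene expression,
histopathology image features, and routine clinical variables. It is
aimed at computational-biology practitioners working with TCGA-style
cohorts (per-sample TPM tables, diagnostic H&E slides, clinical
tables), and every stage can be exercised end to end on a built-in
synthetic multimodal cohort with known ground truth — no downloads
required.

## The core algorithm

Gene selection is **frequency-ranked iterative random-forest
selection**. For a cohort X (samples × genes, log₁₀(TPM+1)) with
binary DM labels y:

1. for i = 1..N (default N = 1000): fit a random forest to (X, y) with
   a fresh sub-seed and record the K (default 100) genes with the
   highest importance;
2. rank genes by frequency — the number of top-K lists each gene
   appears in over the N iterations — breaking ties by mean importance,
   then gene ID;
3. the top n_select (default 50) genes form the panel.

The tally, not any single fit's importance, is the selection signal:
informative genes recur across refits while noise genes drift in and
out. The per-iteration lists are retained so the ranking can always be
re-derived by brute-force recount.

Around this sit: expression preprocessing (NaN→0, log₁₀(x+1), removal
of genes zero in >80% of samples, top-10,000 by variance); panel
benchmarking with SVM/KNN/RF over panel sizes 30…1 (stratified 75:25
hold-out + 5-fold CV of accuracy/F1/AUROC); cross-cancer specificity
experiments (panel overlap tables, cross-application, union panels); a
histology patch funnel (≤500 random non-overlapping 512×512 patches →
≤200 with tissue fraction ≥80% → top 60 by cellularity) with Macenko
stain normalization; 32-dim per-patient image features by mean pooling;
and late fusion of genomic + image + clinical blocks evaluated by
Monte-Carlo cross-validation (5 stratified 80:20 resplits) with SVM and
MLP classifiers. See `docs/methods.md` for the full model description.

## Worked example

Generate a 48-patient synthetic cohort with five planted DM genes, run
selection, and benchmark the panel:

```python
from dmfusion import (
    ImageConfig, SyntheticConfig, generate_cohort, preprocess,
    SelectionConfig, select_genes, PanelEvalConfig, evaluate_panel,
)

cfg = SyntheticConfig(
    groups=[("BLCA-like", 24, 24)],        # 24 DM + 24 non-DM patients
    n_genes=200,
    planted={"BLCA-like": [3, 50, 90, 140, 190]},
    effect_size=1.0,                        # log10-scale mean shift in DM
    image=ImageConfig(patches_per_patient=0),
    seed=11,
)
cohort = generate_cohort(cfg)
matrix, _ = preprocess(cohort.expression)

ranking = select_genes(matrix, SelectionConfig(
    n_iterations=50, top_k=10, n_select=10, trees_per_forest=100, seed=5))
print("top 10 by frequency:", ranking.top(10))
print("planted genes:      ", cohort.truth["BLCA-like"])

results = evaluate_panel(matrix, ranking.top(5),
                         PanelEvalConfig(panel_sizes=[5], seed=1))
cv = results[("svm", 5)].cv
print(f"SVM 5-fold AUROC: {cv.auroc:.3f} +- {cv.sd('auroc'):.3f}")
```

Output:

```
top 10 by frequency: ['G0090', 'G0140', 'G0190', 'G0003', 'G0023', 'G0068', 'G0050', 'G0128', 'G0022', 'G0121']
planted genes:       ['G0003', 'G0050', 'G0090', 'G0140', 'G0190']
SVM 5-fold AUROC: 0.974 +- 0.037
```

All five planted genes are recovered in the top ten frequency ranks,
and the recovered panel separates DM from non-DM nearly perfectly at
this effect size. The same workflow runs from the shell:

```bash
dm-pipeline synth generate --out cohort/ --group A:24:24 --seed 11
dm-pipeline genes select --expr cohort/expression.tsv \
    --labels cohort/clinical.tsv --n-iter 50 --top-k 10 --seed 5 \
    --out ranking.tsv
dm-pipeline run --config config.yaml     # full multi-stage pipeline
```

## Layout

```
src/dmfusion/
  synthdata.py    synthetic multimodal cohort generator (ground truth known)
  exprprep.py     TPM merging, log transform, prevalence/variance filters
  geneselect.py   frequency-ranked iterative RF selection + t-stat baseline
  panel_eval.py   SVM/KNN/RF panel benchmarking, overlap/cross/union experiments
  wsiprep.py      patch extraction, tissue/cellularity funnel, Macenko
  imgfeatures.py  32-dim patch features, patient-level mean aggregation
  fusion_eval.py  clinical cleaning, late fusion, Monte-Carlo CV
  pipeline.py     end-to-end orchestration under one master seed
  cli.py          `dm-pipeline` command-line interface
```
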