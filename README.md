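# methyldiag

Tissue-specific CpG-site screening and disease diagnosis from DNA methylation
beta values.

Aberrant, tissue-specific DNA methylation is a hallmark of age-related
disease: breast, kidney and lung cancers, and Alzheimer's and Parkinson's
disease all leave characteristic methylation signatures in the affected
tissue (and in accessible biofluids such as saliva and whole blood).
`methyldiag` implements a complete diagnostic pipeline over 450K-style beta
values β ∈ [0, 1] — the methylated fraction of each CpG site in each sample —
for researchers who want to screen epigenome-wide data down to a small
diagnostic panel and train a classifier on it.

## Method

**Stage 1 — tissue-specificity screen.** Using healthy samples only, each
site's beta values are discretized into equal-width bins on [0, 1] and
cross-tabulated against the tissue label. The contingency statistic

    χ² = Σ_cells (O − E)² / E,   df = (occupied bins − 1)(tissues − 1)

is referred to the upper tail of the χ² distribution; sites with
p < τ_p (default 0.01) are kept as tissue-specific.

**Stage 2 — disease-site ranking.** Within one tissue, an L2-regularized
logistic regression P(disease | x) = σ(β₀ + xᵀβ) is fitted on the
standardized candidate-site betas; sites are ranked by |β_j| descending and
the top k (default 400) form the tissue's diagnostic panel. Ranking by
magnitude keeps hypomethylated disease sites (fold change D_M/H_M < 1) as
well as hypermethylated ones.

**Diagnosis model.** The panel vector feeds a multi-head self-attention
Transformer encoder; its output H passes through a *dynamic residual*
(gated highway) layer

    T = H·W_fc + b_fc,  G = σ(H·W_gate + b_gate),  O = G⊙T + (1−G)⊙H,

and a softmax head gives P(healthy), P(disease). Setting
`use_dynamic_residual=False` gives the ablation baseline. The network and
its training loop (Adam, cross-entropy, early stopping) run in float64 on a
small in-repo reverse-mode autodiff engine — no deep-learning framework is
required — and are bit-deterministic for a fixed seed.

**Evaluation.** Seeded stratified k-fold cross-validation with
accuracy/recall/F1 (disease = positive class), pooled ROC curves and
concordance AUC, and conventional baselines (logistic regression, SVM,
random forest, XGBoost, k-NN) run on identical folds.

A synthetic-cohort generator plants tissue-specific and disease-specific
mean shifts in beta-distributed noise, with a ground-truth manifest, so the
whole pipeline is testable without any external download.

## Worked example

```sh
methyldiag simulate --out-dir demo --seed 7 --n-sites 2000 \
    --n-tissue-specific 200 --n-disease-specific 20
methyldiag screen tissue  --betas demo/betas.tsv --meta demo/metadata.tsv \
    --out demo/tissue_sites.tsv
methyldiag screen disease --betas demo/betas.tsv --meta demo/metadata.tsv \
    --tissue kidney --candidates demo/tissue_sites.tsv --top-k 400 \
    --out demo/kidney_sites.tsv
methyldiag summarize --betas demo/betas.tsv --meta demo/metadata.tsv \
    --tissue kidney --sites demo/kidney_sites.tsv --out demo/kidney_summary.tsv
methyldiag evaluate --betas demo/betas.tsv --meta demo/metadata.tsv \
    --tissue kidney --sites demo/kidney_sites.tsv --model lr --k 5 --seed 7 \
    --out demo/lr_metrics.json
```

prints

```
wrote 600 samples x 2000 sites to demo
215 of 2000 sites selected at tau_p=0.01
ranked 215 candidates; kept top 215
summarized 215 sites for kidney
lr on kidney: AUC 1.000, mean accuracy 1.000
```

The screen keeps 215 of 2,000 sites at τ_p = 0.01 — the 200 planted
tissue-specific sites plus a sprinkle of false positives near the nominal
1% rate. `demo/kidney_summary.tsv` lists per-site healthy/disease medians
and their ratio, e.g.

```
site_id     tissue  h_m    d_m    magnification  h_se    d_se
cg00001199  kidney  0.750  0.963  1.283          0.0079  0.0052
cg00001236  kidney  0.789  0.553  0.701          0.0114  0.0123
```

— one hypermethylated (fold change 1.28) and one hypomethylated (0.70)
disease site. Evaluating the Transformer on the same panel
(`--model transformer`) gives AUC 1.000 and mean accuracy 1.000 on this
strongly separable cohort. The full pipeline can also be driven from one
YAML config with `methyldiag run --config pipeline.yaml`.

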