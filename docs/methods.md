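# Methods

## Data model

A cohort is a samples × sites matrix of beta values (methylation fraction,
[0, 1], NaN = missing) plus per-sample metadata: a tissue label from a
declared vocabulary (default: brain, saliva, whole blood, kidney, lung,
breast) and a binary health status (0 healthy, 1 disease). The published
sources reuse one symbol for both labels; here they are always distinct
fields (`tissue`, `status`). Readers accept matrices in either orientation
(GEO series-matrix exports are sites × samples) and normalize status strings
("healthy"/"disease"/0/1). Missing cells are explicit (`NA`/empty → NaN),
never coerced to zero; how the original array cohorts handled missingness is
unstated, so the pairwise-drop policy below is this package's own choice.

## Stage 1: chi-square tissue-specificity screen

Restricted to healthy samples (disease effects must not register as tissue
specificity), each site is tested independently:

1. beta values are discretized into `n_bins` equal-width bins on [0, 1]
   (default 10; the value 1.0 belongs to the last bin);
2. the bins × tissues contingency table of counts O is formed, missing
   values dropped pairwise;
3. χ² = Σ (O − E)²/E over cells with E > 0, where E comes from row/column
   margins; df = (occupied bins − 1) × (tissues with data − 1), empty bins
   dropped;
4. p = 1 − F_χ²(χ², df); sites with p < τ_p (default 0.01) are selected,
   ordered by ascending p with lexicographic site-id tie-break.

The published formulation indexes the statistic's sum ambiguously (over the
site count, where a per-site test cannot sum over sites); it is implemented
here as the standard bins-of-one-site contingency test, and the statistic
agrees with `scipy.stats.chi2_contingency(correction=False)` exactly (the
scipy routine is used only as an independent oracle in tests). A site
observed in fewer than two tissues, or in one bin everywhere, is degenerate:
statistic 0, df 0, p = 1 — not an error in the screen.

**Calibration.** On null cohorts (6 tissues × 50 samples, 5,000 sites) the
empirical selection rate at τ_p = 0.01 is 0.004–0.009 across seeds: the
binned statistic is mildly conservative in the far tail because tail bins of
bounded, unimodal beta noise carry small expected counts. At α = 0.05 the
rate is 0.033–0.043. No multiple-testing correction is applied beyond the
fixed τ_p, matching the source procedure.

## Stage 2: per-tissue disease-site ranking

Within one tissue (both statuses required), candidate-site betas are
mean-imputed (within tissue), standardized to zero mean/unit variance, and
fitted with an L2-regularized logistic regression (scikit-learn, lbfgs,
C = 1.0, tol 1e-8). Regularization is necessary: the candidate set
(thousands of sites) typically exceeds the sample count, making an
unregularized fit ill-posed. Sites are ranked by |β_j| descending with
lexicographic tie-break; the top k (default 400) form the panel. The
literal published rule ranks by signed descending coefficient, which would
discard hypomethylated disease sites even though the published
disease/healthy median table contains fold changes below 1; magnitude
ranking is therefore the default, with `criterion="signed"` available for
the literal reading.

Per-site summaries report the healthy and disease medians H_M and D_M
(mean-of-middle-two for even n), the fold change ("magnification") D_M/H_M
(undefined, not infinite, when H_M = 0), and group standard errors. Whether
the published standard errors are of the mean or the median is unstated:
sd/√n (SE of the mean) is the default, a seeded bootstrap SE of the median
is available via `se_method="median"`.

## Diagnosis model

Input is the panel's length-d beta vector (d = 400 by default).

- **Token layout.** The published construction expands the vector in the
  channel dimension to a 1 × d sequence — one token of width d — under which
  self-attention over positions is degenerate (softmax over a single
  position). This literal layout is the default. A `token_layout="per-site"`
  alternative gives each site its own token (scalar embedded to `embed_dim`
  plus a learned positional embedding, mean-pooled after the encoder), under
  which cross-site attention is meaningful; in that mode the
  residual/classifier dimension is `embed_dim`, not d. Neither layout is
  asserted to be the original authors' intent.
- **Encoder.** Post-layer-norm Transformer encoder, L = 2 layers, h = 4
  heads (auto-reduced to the largest divisor of the width when d is not
  divisible), feed-forward width 2d with ReLU, dropout 0.1. No positional
  encoding in 1 × d mode (meaningless for one token).
- **Dynamic residual.** T = H·W_fc + b_fc; G = σ(H·W_gate + b_gate);
  O = G⊙T + (1−G)⊙H, elementwise. The sigmoid saturates to exactly 0/1 at
  extreme logits, so a closed gate returns H bit-exactly and the full model
  with a closed gate equals the no-residual baseline given shared weights.
  `use_dynamic_residual=False` removes the layer (O = H) for ablations.
- **Head.** Softmax over O·W_class + b_class; outputs sum to 1 within 1e-6.

The network runs in float64 on an in-repo reverse-mode autodiff engine
(`methyldiag.autograd`); every primitive and the assembled network are
verified against central finite differences. Training minimizes mean
cross-entropy with Adam (lr 3e-4, batch 32, up to 200 epochs, weight decay
0), with a stratified validation split (15%) and early stopping
(patience 20, min-delta 1e-4, best weights restored). lr 3e-4 was chosen
because the post-layer-norm stack is unstable at 1e-3 without warmup.
Optimizer, loss, schedule and epoch count are unstated in the source and are
this package's own defaults. One root seed drives initialization, batch
order, dropout and the validation split; identical data + config + seed give
identical weights on one platform.

## Synthetic cohorts

The generator is this package's own construction (the source works from
public array cohorts and states no simulation model). Each cell is drawn
from a beta distribution with per-site mean m and concentration
`dispersion` (default 30, i.e. sd ≈ 0.08 at m = 0.5), keeping values in
[0, 1] with realistic bounded, skewed noise; a matched-moment truncated
normal is available. Background sites share one mean (uniform on
[0.1, 0.9]) across tissues and statuses; planted tissue-specific sites get a
±0.25 mean offset in one target tissue; planted disease-specific sites
(a subset of the tissue-specific set) get an additional ±0.2 offset in
disease samples of their tissue, sign random per site so both hyper- and
hypomethylation occur, as in the published disease/healthy median table
(fold changes ≈ 0.6–11). Default cohort: 6 tissues × (50 healthy + 50
disease) × 2,000 sites. Means are clipped to [0.02, 0.98]. Site ids are
"cg"-prefixed zero-padded indices; ground truth records planted sets and
true means. Sub-streams for structure, noise and missingness are spawned
from the root seed in fixed order, so cohorts are bit-reproducible.

An `interaction_cohort` variant labels samples by the XOR of two planted
sites' low/high states (no marginal signal at either site) to probe
nonlinear capacity in the residual-layer ablation.

The generator emulates mean shifts and bounded noise only. Probe-level
artifacts, batch effects, cell-type composition, age covariates and
correlated neighboring probes of real 450K data are absent, so passing
recovery tests demonstrates correctness of the procedures under the stated
effect sizes — not expected performance on real cohorts (the published
real-data AUCs and independent-test accuracies require the original GEO
downloads and are out of scope here).

## Evaluation harness

Stratified k-fold splits (scikit-learn, shuffled, seeded) are shared across
all compared models so differences reflect the model, not the folds.
Accuracy, recall and F1 use disease as the positive class (F1 = 0 when
precision + recall = 0). ROC is a threshold sweep over unique scores; AUC is
the pairwise concordance probability with ties counted ½ (verified against
an O(n²) brute-force oracle). Baselines (LR, SVM, RF, XGBoost, k-NN) run at
library defaults with the fold seed; LR/SVM/k-NN are standardized in a
pipeline. Missing betas are mean-imputed per training fold. When models are
compared across site panels, panels are frozen before cross-validation
(site selection is not re-run per fold).

## Problem sizes used in tests and the acceptance script

Chosen once as the package's study conditions: null calibration at
6 × 50 × 5,000 sites; tissue recovery with 200 planted of 2,000 sites
(shift 0.25, 50 healthy per tissue); disease-ranking recovery with 20
planted among 2,000 candidates at 100 + 100 samples (shift 0.2); model
sanity on a 100 + 100 × 400-site cohort (shift 0.3, 5-fold, epochs 30,
batch 64); ablation on 10 XOR cohorts (100 + 100 × 20 sites, 3-fold,
epochs 60). On these conditions the residual model's mean CV AUC exceeds
the baseline's by a clear margin while neither fully solves XOR at this
training budget; the gap, not the absolute level, is the property of
interest.

## Known limitations

- The 1 × d token layout makes self-attention a fixed mixing; the encoder
  then acts as a (nonlinear) per-vector MLP with normalization. The
  per-site layout restores genuine attention at higher cost.
- The binned chi-square is conservative at stringent thresholds for
  concentrated beta distributions (sparse tail bins); bin count is
  configurable.
- Two rows of the published median table are internally inconsistent (the
  printed fold change does not equal D_M/H_M at printed precision); worked
  examples use the arithmetically consistent rows.
- No IDAT parsing, normalization, probe blacklisting, GEO client,
  enrichment analysis, or multi-class heads.
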