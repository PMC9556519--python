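# Methods

`hybridqc` implements the hybrid quality-control paradigm for large
diffusion-MRI cohorts: a small expert-rated gold standard is amplified
through calibrated community ratings and automated data-quality
metrics, the amplified labels train an image-based classifier, and the
consequences of QC screening are quantified downstream. Because the
real cohort requires large downloads, the package ships a synthetic
cohort generator that reproduces the statistical structure each stage
relies on; all tests and the acceptance script run on those synthetic
cohorts.

## Latent-quality cohort model

Every simulator is driven by a per-participant latent quality
`q ∈ [0, 1]`. `q` is Beta-distributed (default shape `(2.2, 1.3)`,
mildly pass-skewed, as most scans in pediatric cohorts pass QC) and
coupled to a uniform age on 5–21 years through a Gaussian copula. The
copula correlation is set from the target Pearson correlation `r` via
`ρ_z = 2 sin(πr/6)` (exact for uniform marginals; the Beta transform
attenuates a further ≲1 %). The default target `r = 0.31` reflects the
well-replicated direct association between age and data quality in
pediatric imaging (younger children move more). Sex and site are drawn
independently of `q`; the binary ground-truth label is `q ≥ 0.5`.

Everything downstream is a pure function of `(parameters, seed)`:

* **Automated metrics** — the 31-column data-quality table. Fourteen
  informative metrics are noisy monotone transforms of `q` with the
  empirically observed sign structure (neighboring-DWI correlation
  rises with quality; relative translation/rotation, framewise
  displacement, and outlier-slice counts fall; outlier slices are
  Poisson counts). The default noise scale (`noise_sd = 0.9` on the
  standardized latent) leaves the metrics clearly informative but not
  perfect, so that community ratings still add measurable signal on
  top of them. Acquisition descriptors (voxel sizes, grid dimensions,
  direction counts, max b-value) are constants, mirroring their zero
  importance in any fitted model.
* **Expert ratings** — each expert thresholds `q + bias_e + ε` at
  shared cutpoints (0.2, 0.4, 0.6, 0.8) onto the ordinal scale −2…+2.
  Rater differences enter only through the per-expert bias
  (`bias_sd = 0.05`) and i.i.d. noise (`noise_sd = 0.12`); the
  defaults put mean pairwise quadratic-weighted κ near 0.70 and ICC3k
  near 0.95, the regime reported for expert dMRI QC panels.
* **Community ratings** — binary pass/fail per (participant, rater,
  view). Raters see only slice subsets, so their error structure is
  asymmetric by construction: sensitivity is anchored high
  (Beta(12, 1.5) — a clean scan almost never looks bad in any slice)
  while specificity is lower and widely spread (Beta(3.5, 1.5) —
  artifacts are easy to miss), and an `optimism` parameter (default
  0.4) mixes every pass probability toward 1. This makes the
  community pass rate exceed the expert pass rate structurally, not
  just on average, and gives raters genuinely different reliabilities
  for the calibration model to weight.
* **Phantom volumes** — 4 channels (b=0, DEC-FA x/y/z) on a
  configurable grid (default 32³). Clean phantoms contain a smooth
  head-like b=0 ellipsoid and three tubes whose DEC-FA energy
  concentrates in the channel matching their orientation. Low quality
  adds an alternating-slice gain along the inferior–superior axis
  (the banding signature of motion) with depth `0.4·(1−q)`, and
  attenuates/blurs the DEC-FA channels. One parameter therefore
  controls the full severity continuum.
* **Bundle profiles** — 24 bundles × {FA, MD} × 100 nodes. Each
  (bundle, metric) has a fixed template (base level plus 1–3 Gaussian
  bumps seeded from the bundle name). Age scales the template *shape*
  logarithmically (FA bumps deepen, MD bumps flatten with log-age),
  sites contribute location/scale effects, and low quality shrinks
  each profile toward its own mean by `0.9·(1−q)` — flattening that
  destroys the age-informative shape while preserving the mean, which
  is exactly the mechanism by which QC screening can improve age
  prediction. A configurable fraction of (participant, bundle) pairs
  is dropped to exercise imputation.

What the generator does **not** emulate: real artifact physics
(ghosting, susceptibility distortion, eddy-current residuals), spatial
anatomy beyond blobs and tubes, scanner-specific metric distributions,
rater learning over time, and any correlation between sex/site and
quality. Passing tests therefore demonstrate that the pipeline's
machinery behaves correctly under the assumed statistical structure,
not that the trained models would transfer to real scans.

## Expert aggregation and reliability

Mean expert ratings are rescaled to [0, 1] via `(r + 2)/4`; 0.2-wide
bands recover the verbal categories and 0.5 is the pass threshold.
Pairwise agreement uses Cohen's κ with quadratic weights over the full
fixed 5-level scale (levels belong to the instrument, not the sample;
dropping unobserved levels would make κ sample-dependent). κ is
undefined when both coders are constant and identical; such cells
propagate as missing. Consistency ICCs come from the two-way ANOVA
mean squares — ICC3 `(MS_R − MS_E)/(MS_R + (k−1)MS_E)` for a single
coder, ICC3k `(MS_R − MS_E)/MS_R` for the k-coder mean — with
Shrout–Fleiss F-distribution confidence bounds at a configurable
level. A calibration model enters the ICC as an additional coder on
the continuous [0, 1] scale (no re-discretization; discretizing would
only discard information the ANOVA can use), while the κ matrix
discretizes model scores back to the ordinal scale since κ is defined
on categories.

## Label amplification

Gradient-boosted binary classifiers (XGBoost) are trained to predict
the binarized expert score from automated metrics ("q"), per-rater
community features ("f"), or both ("q+f"). Community ratings enter as
one column per rater holding that rater's mean rating per participant,
missing where unrated — the encoding that lets the trees weight
reliable raters individually; XGBoost's native missing-value routing
handles the sparsity. Training uses repeated stratified K-fold
cross-validation (3 splits × 2 repeats), a small randomized
hyperparameter search per fold (depth, learning rate, tree count,
subsampling; budget configurable — the search strategy is not the
scientific content), and combines the six fold models into a voting
ensemble weighted by held-out-fold ROC-AUC. Weights are used inside a
normalized weighted mean, so only their ratios matter. Out-of-fold
predictions are retained so the reported cross-validated AUC can be
recomputed independently.

Global feature importance is the mean absolute Shapley value per
feature, estimated by permutation sampling: coalition value is the
expected model output with coalition features pinned to the explained
row and the rest drawn from a background sample. The estimator
converges to exact Shapley values in the sampling limit (verified
against exact subset enumeration and the additive closed form in the
test suite); features never split on get exactly zero.

## Deep QC network

The image classifier consumes 4-channel volumes (b=0 + DEC-FA x/y/z),
optionally augmented with the standardized 31-metric vector routed
around the convolutional trunk. Four conv blocks (64, 64, 128, 256
filters; 3³ kernels, same padding, ReLU, 2³ max pooling, batch
normalization) feed a global average pool; pooled features (plus
metrics, when present) pass through batch norm, dense 512 and dense
128 with ReLU and 40 % dropout each, and a single sigmoid unit. With 4
imaging channels and 31 metrics this is exactly 1,438,783 trainable
parameters (batch-norm scale/shift included; moving statistics are
buffers). Global average pooling makes the count invariant to the
input extents, which are configurable (default 32³, each extent a
multiple of 16 to survive four pooling halvings). The imaging-only
variant keeps the post-pooling batch normalization.

The network runs on a compact numpy engine written for this package:
convolution as per-offset matrix products (with an im2col path for
few-channel inputs), explicit backward passes, Adam. The deciding
reason for explicit backward passes is integrated gradients, which
needs exact derivatives with respect to the *input*. Training follows
binary cross-entropy with Adam at 1e-4, halves the learning rate when
validation loss plateaus for more than two epochs, stops early when
validation loss fails to improve by more than 0.001 for twenty
consecutive epochs, and restores the best-validation weights.
Continuous amplified scores are binarized at 0.5 to serve as targets.
Per-epoch training metrics are the running minibatch aggregates
(Keras convention); validation metrics come from a full post-epoch
pass. A replicate driver trains one model per seed; replicate scores
combine by arithmetic mean of probabilities. Desk-scale defaults
(32³ phantoms, 200 training volumes, batch 8, ≤10 epochs) train in a
few minutes on one CPU; the phantom task is intentionally easy, so
the held-out AUC reached there overstates what the same architecture
achieves on real scans.

## Attribution

Integrated gradients attribute the sigmoid output (the pass
probability — the quantity whose sign convention the maps inherit) to
input voxels along the straight path from an all-zeros ("black")
baseline, including the metrics channel when present. The Riemann sum
uses midpoint evaluation `(k−½)/m`, which roughly halves the
completeness gap versus an endpoint rule at equal steps; the gap
`|Σ IG − (F(x) − F(b))|` is recorded on every map. Display masking
keeps voxels whose |attribution| strictly exceeds 98 % of the map's
maximum. One caveat discovered during validation: a trained network
scores the black baseline itself as a confident fail, so
`F(x) ≥ F(baseline)` for essentially every input and per-channel
attribution *sums* are nonnegative. The directional story — fail
evidence concentrating in the b=0 channel when banding is present —
survives contrastively: negative attribution mass concentrates in b=0
relative to the DEC-FA channels, and banding strips b=0 of the
pass-evidence it carries for clean phantoms. The tests assert exactly
that.

## Evaluation and site generalization

ROC-AUC uses the Mann–Whitney pairwise-concordance definition (ties
half), balanced accuracy the mean of sensitivity and specificity, and
the prediction threshold is fixed at 0.5 throughout. The leave-site-out
protocol holds out each 3T-site combination in turn (CBIC+CUNY→RU,
CBIC→RU+CUNY, RU+CUNY→CBIC, RU→CBIC+CUNY), training either the
metrics-calibration family (on expert labels; 20 replicates by
default) or the CNN family (on amplified labels; 8 replicates), and
reports accuracy, balanced accuracy, and ROC-AUC as mean ± sd over
replicates. CNN-family evaluation decomposes the held-out set into a
report set (scored against expert labels where they exist) and a test
set (scored against amplified labels).

## QC-cutoff sensitivity

Bundle-profile tables (4,800 features per complete participant) are
median-imputed and harmonized across sites. Two harmonizers are
provided: plain per-feature location-scale adjustment (transparent,
removes an injected shift exactly) and parametric empirical-Bayes
ComBat — standardization by design-based grand mean and pooled
residual variance, normal/inverse-gamma priors moment-matched across
features, and the standard fixed-point posterior iteration. The EB
variant reproduces the Bioconductor reference implementation to ~1e-5
on a frozen fixture (see the test suite).

The sweep keeps participants with `qc_score ≥ cutoff` for each cutoff
in 0…0.95 (step 0.05), fits a gradient-boosted regressor on log-age
(natural log; predictions back-transformed before scoring, so R² lives
on the age scale) under repeated K-fold cross-validation, and reports
mean R², a normal-approximation CI over fold scores, and retained-n.
Regressor hyperparameters are fixed defaults recorded in
`default_age_regressor` (shallow trees, strong column subsampling, 32
histogram bins — chosen once for the wide-and-short feature tables
this sweep produces). Cutoffs retaining fewer participants than folds
are reported unavailable (NaN), never silently dropped. The helper
`qc_score_from_quality` emulates a calibrated classifier's score
distribution (logit-sharpened, noisy, ceiling 0.955 — ensemble-averaged
probabilities rarely reach certainty), producing the bimodal shape
with ~8 % clear failures below the first cutoff and a thin top tail
that the sweep's rise-then-collapse behavior depends on.

## Problem sizes

Defaults used by the tests and the acceptance script, chosen as
desk-scale conditions: calibration cohorts of n = 600 with 6 experts
and 20 community raters (~200 ratings/participant); 200 + 50 phantoms
at 32³ for the deep-QC smoke training (≤10 epochs); sensitivity sweeps
on n = 300 with 5 folds × 2 repeats; site-generalization experiments
on n = 500 two-site cohorts with 3 replicates. Headline numbers
produced under these conditions are qualitative analogues of the
full-scale study's, not reproductions.

## Known limitations

* The NN engine is CPU-only, float32, small-batch; batch-norm
  statistics are noisy at batch 8, and there is no data augmentation.
* Parametric EB ComBat only (no non-parametric prior, no covariate
  preservation); harmonization assumes each site has ≥2 participants.
* The Shapley estimator is background-dependent, as all
  interventional Shapley estimates are; importances are comparable
  within a model, not across models.
* The synthetic phantom task is far easier than real QC; deep-QC
  accuracy on phantoms is a machinery check, not a performance claim.
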