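# Methods

## Problem and endpoints

The package predicts two dichotomized post-intervention outcomes for acute
ischemic stroke: inpatient length of stay, positive when strictly greater
than 8 days, and the 90-day modified Rankin Scale, positive when strictly
greater than 2.  Both thresholds are strict: a stay of exactly 8 days and
an mRS of exactly 2 are negative.  Death (mRS 6) remains in the
poor-outcome class.  Each outcome's cohort contains only subjects with that
outcome recorded, so the two cohorts overlap but differ in size; subjects
with an absent outcome are excluded from that outcome, never imputed.

## Cohort handling

One 80/20 stratified hold-out is drawn per outcome, followed by three
stratified shuffle splits of the remaining 80% into 80% training / 20%
validation.  The hold-out is identical across folds and untouched by every
training and selection step; the fold definition serializes to JSON
(`SplitPlan`) and its hash is stamped into every run record, so reuse of
identical folds across experiment arms is verifiable, and a leakage check
(`check_no_leakage`) asserts that no hold-out index ever appears in a
training or validation log.  Stratified shuffle folds may share training
subjects across folds; they are not a partition.

Tabular preprocessing fits on training rows only: continuous features are
mean-imputed and standardized with training statistics (a zero-variance
column gets SD 1 with a warning); binary indicators treat missing as false;
categorical features one-hot encode against schema-declared levels, with an
explicit "Missing" level where the schema declares one (thrombus location)
and all-zero encodings for absent or unseen categories.  Scanner
manufacturer and field strength are excluded from the modelling feature
set.  The schema is config-driven: the synthetic cohort uses a small
3-feature clinical block, and a real cohort's full feature list can be
dropped in without code changes.

Group comparisons between overlapping cohorts use two-sided permutation
tests (default n = 1000) with the add-one estimator
p = (1 + #{|t_perm| ≥ |t_obs|}) / (n_perm + 1); the statistic is an
absolute mean difference for continuous features and the total-variation
distance between level proportions for categorical ones.

## Architectures

All networks are built from a numpy layer library with hand-derived
reverse-mode gradients (`neurofuse.nn`); every layer's parameter and input
gradients are validated against central differences in the test suite.
Batch-norm layers keep running statistics (momentum 0.1) and are exactly
deterministic in inference mode.  Initialization is seeded; two builds from
one seed are bit-identical.

* **ResNet-10** — 7³ stem convolution (stride 2), batch norm, rectifier,
  3³ max-pool (stride 2); four stages of one basic residual block each,
  channel widths (64, 128, 256, 512) by default and strides (1, 2, 2, 2);
  global average pooling to the feature vector.  An optional
  squeeze-and-excite layer (reduction 16) follows the last residual stage.
* **Autoencoder** — encoder of three 3³ stride-2 conv blocks (channels
  8, 16, 32 by default) with batch norm and rectifier, flattened into a
  dense bottleneck of dimension 64 (the latent vector); decoder mirrors the
  encoder with transposed convolutions and a linear output layer.  Output
  padding per axis is derived from the recorded encoder shapes, so decoding
  reproduces the input grid exactly for any grid of at least 8 voxels per
  axis, not only powers of two.  The encoder is separable and reusable
  alone for embedding extraction.
* **Classifier** — a single dense layer from the concatenated enabled
  blocks (image features, EHR, IDF) to one logit; "single layer" is read
  literally, with no hidden layer.
* **DAFT block** — the pooled last-stage feature map is concatenated with
  the tabular vector, passed through a small bottleneck MLP, and emits a
  per-channel scale α and shift β applied as v′_c = α_c v_c + β_c.  The
  final dense layer is zero-initialized and α is offset by one, so the
  block is an exact identity at initialization; the transform is placed
  after the last residual stage, mirroring the SE placement.

The transposed convolution is computed as a per-kernel-offset scatter on
the input grid rather than by materializing the zero-stuffed upsampled
grid; this is algebraically identical and about thirty times faster at
32³ in this setting.

## Training harness

Arms are *clinical* (tabular only), *image* (ResNet trained end to end, or
autoencoder embeddings with a classifier), and *combined* (image features
plus EHR, optionally IDF); each arm runs with and without IDF, giving the
13-row experiment grid.  ResNet regimes are transfer learning (backbone
frozen, classifier trained), fine-tuning (all weights), and training from
scratch.  Learning-rate defaults follow the study conditions:
classifier-only training uses a constant 0.01; fine-tuning starts at 0.001
and scratch at 0.1, both with a scheduler.  Freezing is enforced at the
optimizer level (frozen parameters are never updated), and the
transfer-learning contract — backbone parameter hashes identical before and
after training — is asserted in tests.

Unstated settings were fixed once as the package's own choices: the
optimizer is Adam (adaptive moment estimation) with optional decoupled
weight decay; the scheduler is reduce-on-plateau on validation loss
(factor 0.1, patience 5); epochs default to 100 with early stopping
(patience 15) on validation AUPRC; batch sizes default to 8 volumes / 64
tabular rows; class imbalance is handled with a positive-class weight
n_neg/n_pos in the cross-entropy (configurable off).  The checkpoint with
the best validation AUPRC is restored before evaluation, and hold-out
metrics are computed once from it.  Among ResNet candidates, the selected
model maximizes mean validation AUPRC across the three folds, with ties
broken by lower SD and then by the fixed regime order TL, FT, FT+SE,
scratch, scratch+SE.

When the transfer-learning regime is requested without a user-supplied
pretrained checkpoint, a SYNTHETIC surrogate backbone is fitted first: the
backbone plus a regression head reproducing an 8³ trilinear thumbnail of
the masked input (an autoencoding-style task), after which the head is
discarded.  This stands in for an externally pretrained medical-imaging
backbone only in the sense of providing non-task-specific weights; it makes
no claim of comparable representation quality.

## Metrics

AUPRC is step-wise average precision (no trapezoidal interpolation), AUC is
the trapezoidal ROC area (equal to the Mann-Whitney statistic with ties
counted half); both are computed via scikit-learn behind the module surface
and verified against exhaustive brute-force pair-counting /
tie-group-precision oracles to 1e-12 on hundreds of random small instances.
Single-class inputs raise an error rather than silently returning 0.5.
Thresholded metrics (recall, specificity, F1) use a fixed operating point
of 0.5 by default — the operating threshold is genuinely unspecified
upstream, so it is a configurable argument.  Fold aggregation reports the
mean and the sample (n−1) SD over exactly the folds of one split plan;
population SD would understate spread over three folds.

## Synthetic lesion-phantom cohorts

The generator emulates the *structure* of a post-intervention stroke MRI
cohort, not MRI physics.  Each subject gets a centred ellipsoidal brain
(semi-axes 0.90–0.99 of the half-grid, covering 30–45% of the default
grid), constant base intensity 1.0 inside the brain plus Gaussian noise
(SD 0.05), exact zeros outside; one ellipsoidal hyperintense lesion
(contrast +1.0, semi-axes 2–6 voxels on the default 32³ grid with 8 mm³
voxels) implanted at an interior brain location and clipped to the brain
mask.  The recorded lesion-volume IDF is exactly voxel count × voxel
volume / 1000 on the native grid and is never recomputed after resampling.

Covariates mimic plausible admission marginals: age ~ Normal(62, 14), an
NIHSS-like severity ~ Normal(6.1, 6.6) truncated at 0, sex ~
Bernoulli(0.53), and a 4-level thrombus location including an explicit
Missing level.  Severity is coupled to lesion volume (+0.8 per cm³ around
the cohort mean) so the clinical block carries correlated signal, as it
plausibly would in practice; this correlation structure is a modelling
choice, not a claim about the real joint distribution.  Missingness is MCAR
at rate 0.05 on continuous clinical covariates only (the upstream
imputation scenario caps this below 20%).

Outcomes follow a logistic link on lesion volume and covariates with the
intercept bisected until the mean predicted probability matches the target
prevalence within 1e-4 (targets 0.1891 for LOS and 0.3850 for mRS).  The
default lesion-volume weights (2.0 per cm³ for LOS, 1.6 for mRS; 2.5 in
the lesion-only validation phantom) were calibrated once so the
*generating-truth* AUC sits near 0.85–0.93 at the default grid — the
regime where strong published models for these endpoints operate — and
were then frozen; a weaker effect leaves even perfect recovery
indistinguishable from noise at desk-scale cohort sizes.  Continuous
outcome values (LOS in days, mRS 0–6) are sampled consistently with the
binary label so the dichotomization stage is exercised end to end.
Written NIfTI files use a fixed gzip modification time, making outputs
byte-identical across runs with one config.

What phantoms do not show: real DWI contrast and artifacts, multifocal
strokes, registration error, scanner effects, informative missingness, or
the real joint distribution of clinical variables.  Passing phantom checks
demonstrates that the pipeline recovers signals it provably contains, not
that the real-data performance figures transfer.

## Validation studies and their desk-scale choices

The built-in studies (`neurofuse.benchmarks`) run 200-subject 32³ cohorts
with ResNet widths narrowed to (8, 16, 32, 64) and the autoencoder trained
for 30 epochs; these problem sizes keep a full run in minutes on one CPU.
Specific choices, each fixed once:

* *Planted-signal recovery* compares the combined arm (standardized
  autoencoder latents + EHR) against the clinical arm on a phantom whose
  outcome depends only on lesion volume, with IDF withheld.  One
  autoencoder is fitted per seed on the first fold's training subjects
  (the hold-out untouched); classifier heads train up to 300 epochs with
  decoupled weight decay 1e-2.  Embedding features are standardized with
  training-fold statistics, the same treatment all continuous features
  receive.  At ~130 training rows and 64 latent dimensions, an
  unregularized readout memorizes the training set, so the lesion-volume
  probe is a ridge regression with its penalty chosen by 5-fold
  cross-validation on training rows only.
* *Grad-CAM localization* trains a scratch ResNet at learning rate 3e-3
  (1e-3 stalls in a non-lesion-driven solution at this scale) and takes
  the saliency map at stage1, whose 8³ resolution is the finest stage map
  on a 32³ input — the last residual stage pools to a single cell there
  and is uniform after upsampling.  Heat is restricted to the brain mask
  before scoring: saliency outside a zero-masked input reflects
  convolution boundary offsets, not evidence, and the chance reference is
  the lesion's share of the brain.
* *Null calibration* uses a 400-subject cohort: at 200 subjects, chance
  cohort-wide feature–label associations survive the split and masquerade
  as signal.

## Grad-CAM

Channel weights are spatial means of the logit's gradient at the target
layer; heat is the rectified weighted activation sum, trilinearly upsampled
to the input grid and normalized to maximum 1 when nonzero.  Computation is
in inference mode and bit-reproducible, and scaling the classifier logit by
any positive constant leaves the normalized heat unchanged.  The
autoencoder-embedding classifier has no spatial map at the classifier and
is rejected explicitly.  Slice exports pick the lesion-centroid slice for
reproducibility.

## Numerical and degenerate-input conventions

Masks must be exactly binary (tolerance 1e-6 at load time); lesion masks
must lie inside brain masks.  Grids below 8 voxels per axis are rejected,
as are resampling upsample factors above 8 per axis.  The ResNet stem
requires at least 16 voxels per axis.  Zero-variance continuous features
standardize with SD 1 plus a warning.  F1 is 0 when precision + recall is
0; a heat map that is identically zero scores 0 localization.  Aggregation
over a single fold is an error.  All arrays are float64.

## Known limitations

No multiple imputation, feature selection, augmentation, hyperparameter
search, confidence intervals or calibration analysis; single-focus lesions
only; the surrogate pretrained backbone is synthetic; desk-scale network
widths and cohort sizes mean phantom metric values carry wide sampling
noise (the studies therefore test ordinal and calibration properties, not
point performance).
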