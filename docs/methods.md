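# Methods

## Problem and pipeline

`camrad` implements a radiomics-to-image deep-learning pipeline for
predicting a binary molecular label (the motivating application is MGMT
promoter methylation in diffuse glioma) from multi-modality MRI.  Per
patient the inputs are four co-registered volumes — T1WI, T2WI, T1CE and
an ADC map — with two nested regions of interest: the whole tumor (WT,
parenchyma plus edema, drawn on T2WI) and the tumor core (TC,
contrast-enhancing parenchyma, drawn on T1CE).  The stages are:

1. **Radiomics extraction** — 86 "original" features per (ROI, modality)
   pair: 18 first-order statistics, 14 GLDM, 22 GLCM, 16 GLRLM and 16
   GLSZM texture features; 8 pairs x 86 = 688 features per patient.
2. **Z-score normalization** of every column.
3. **Pseudo-image encoding** — the selected feature columns form an
   86 x m grid (m = #ROIs x #modalities, 1..8) which is resampled to the
   224 x 224 greyscale network input.
4. **Classification** — an 18-layer residual network whose average-pool
   and fully-connected head is replaced by a bilinear upsample of the
   7 x 7 x 512 conv5 output to 86 x m x 512 followed by a 1 x 1
   convolution to 86 x m x 2; the binary label is broadcast to all
   86 x m cells and the loss is mean per-cell cross-entropy.
5. **Evaluation** — stratified 5-fold cross-validation (80/20) per
   (ROI, modality-combination) model, 2 x 15 = 30 models in total, with
   an AUC/ACC/F1/SENS/SPEC/PPV/NPV/MCC panel.
6. **Importance** — the per-cell class-activation map (CAM) is aligned
   row-for-row with the feature grid; averaging over validation samples
   and grid columns scores each of the 86 features, and the top 10 are
   reported.

Because no patient cohort is distributed with the package, a synthetic
module generates (a) 3D phantoms with class-dependent lesion texture and
(b) feature tables with planted effects, so every stage is testable with
known ground truth.

## Radiomics definitions and conventions

* **Discretization**: fixed bin *count* (default 32), equal-width over
  the masked intensity range.  A fixed count makes synthetic tests
  scanner-scale-free; the bin count is configurable
  (`ExtractionSettings.n_bins`).
* **GLCM / GLRLM**: symmetric matrices for the 13 unique 3D directions,
  features computed per direction and averaged.  Directions that produce
  no voxel pairs (possible in very small regions) are excluded from the
  average.
* **GLSZM**: zones are 26-connected components of constant grey level.
* **GLDM**: distance-1 neighbourhood, dependence tolerance alpha = 0.
  The stored dependence size is (number of dependent neighbours + 1), so
  an isolated voxel has dependence 1 and the small-dependence emphases
  stay finite.
* **Grey-level values** in formulas are the integer bin values; the
  ``Ng`` appearing in the normalized inverse-difference features counts
  the distinct levels present in the region.
* **Degenerate regions**: a constant region has entropy 0, skewness and
  kurtosis 0, correlation 1; single-voxel regions produce finite values
  from the 1 x 1 matrices.  A mask must contain at least 27 voxels
  (a 3 x 3 x 3 core) or extraction refuses it.
* **GLCM panel**: the 22-feature set excludes the deprecated SumAverage
  and the matrix-correlation feature MCC from the 24 textbook GLCM
  features; the remaining 22 match the reference "original" set.
* **Feature order** (pseudo-image row semantics): feature-class blocks
  in the order first-order, GLDM, GLCM, GLRLM, GLSZM; alphabetical
  within a block.  This order is frozen in `camrad.features.names`.
* **Two-rater fusion**: masks whose symmetric difference divided by the
  union is below 5% are fused by voxelwise union; larger disagreement is
  flagged for third-rater adjudication.
* **Normalization**: Z-score statistics are fit on the *training rows of
  each fold* by default to avoid leakage; `CamNet(normalize="global")`
  reproduces the single-pass reading.  Population SD is used; columns
  constant on the fit rows become 0 with a logged warning.

## Network

The trunk is the canonical 18-layer residual architecture (7x7/2 stem,
3x3/2 max pool, four stages of two residual units with two 3x3
convolutions each, widths 64/128/256/512, batch norm after every
convolution, identity or 1x1 projection shortcuts) adapted to a single
input channel: 11,170,240 trunk parameters, plus 1,026 in the head.
Implementation is pure numpy (float32) with exact hand-derived backward
passes; convolutions run as one GEMM per kernel offset on contiguous
slice copies, which is the fastest single-core formulation we measured
(~40 GFLOP/s effective; ~0.28 s per sample forward+backward at 224x224).

Choices the architecture description leaves open:

* **Upsampling operator**: bilinear interpolation with the
  half-pixel-centre convention, expressed as two fixed interpolation
  matrices so the backward pass is their exact transpose.  The same
  convention is used for the 86 x m -> 224 x 224 pseudo-image encoding
  (nearest-neighbour available as an ablation switch).
* **Head convolution**: 1 x 1, initialized with He *fan-in* scaling.
  The canonical fan-out rule would give this 2-output convolution a
  weight std of 1.0 over 512 inputs and saturate the softmax at
  initialization (initial loss ~12 instead of ~0.7); every other
  convolution uses fan-out as usual (their scale is neutralized by the
  following batch norm).
* **Patient-level score**: the mean class-1 probability over all
  86 x m head cells — the natural scalar reduction consistent with the
  uniform broadcast labels; thresholded at 0.5 for the confusion panel.
* **Classic head**: `head="classic"` restores global average pooling +
  a 2-way linear layer for ablation comparisons.
* **Optimizer**: SGD, momentum 0.9, weight decay 4e-4 (applied to
  convolution weights, not to batch-norm parameters or biases), batch
  size 32, learning-rate grid {0.1, 0.01, 0.001}, epoch grid
  {200, 400, 600} — these are the `TrainConfig` defaults.  Training is
  deterministic given the config seed.  A NaN loss aborts with a
  suggestion to lower the learning rate.
* **Batch-norm recalibration**: at desk-scale epoch counts the
  exponentially averaged running statistics lag the trained weights
  badly enough to corrupt evaluation-mode predictions, so after training
  the running statistics are replaced by exactly pooled full-training-set
  statistics ("precise BN").  This also makes patient scores independent
  of inference batch composition.

## Cross-validation and metrics

`make_folds` builds a stratified k-fold plan (default k = 5); each
patient validates exactly once and fold train fractions are 80% within
one patient.  `split_cohort` reproduces the single 80/20 split
arithmetic (111 patients -> 89/22).  AUC uses the Mann-Whitney rank
formulation with ties counted 1/2, identical to the trapezoidal area
under the empirical ROC.

The headline AUC of a cross-validated model is the **mean of the
per-fold validation AUCs** (the natural companion of "average
accuracy", which is the mean per-fold validation accuracy).  Scores
from independently trained folds are not on a common calibration scale,
so the pooled-prediction AUC — kept as `CamNetResults.pooled_auc` — can
understate discrimination even when every fold separates perfectly.
Confusion-panel metrics are computed from the pooled predictions at
threshold 0.5; zero-denominator ratios are reported as 0 with a logged
warning.  Cohort comparison tables use Pearson's chi-squared without
continuity correction (a flag enables Yates) and Student's equal-
variance t-test.

Hyperparameter selection over the published 3 x 3 grid is supported by
looping `CamNet.fit` over `TrainConfig` replacements; the grid harness
(`run_model_grid`) trains one model per (ROI, modality combination) and
selects the best row by highest average accuracy with AUC as the
tie-break.

## CAM importance

`rank_features` aggregates the per-cell head output over validation
samples and grid columns into one score per feature row.  Three
statistics are available:

* `class_prob` — mean probability of a fixed class of interest;
* `true_class_prob` — mean probability assigned to each sample's own
  label;
* `margin` — mean signed log-odds, (2y-1) * log(p1/p0).

On a well-fitted model the per-cell probabilities saturate to the
sample's class at *every* cell (each head cell sees the whole image, and
the broadcast labels give every cell the same target), so the
probability statistics average to nearly flat profiles on a balanced
validation set.  The margin statistic ranks by the unsaturated log-odds
and is therefore the default for `CamNetResults.rank_features`.  Ties
are broken by the fixed feature order.

A structural property worth stating plainly: the activation map is an
upsampling of a 7 x 7 response, so the importance profile over the 86
rows is piecewise linear with about seven effective degrees of freedom.
A contiguous *band* of informative features is resolvable; scattered
single rows are not, and top-10 lists will tend to be contiguous blocks
of adjacent features.  The planted-signal experiments therefore plant a
contiguous 5-feature block, and real-data top-10 lists produced by this
mechanism should be read as implicating a feature neighbourhood rather
than 10 independent features.

## Synthetic cohorts

`SyntheticSpec` defaults emulate the reference cohort: 111 patients, 56
positive / 55 negative, four modalities, 64 x 64 x 32 voxel volumes with
ellipsoidal lesions of radius 8-14 voxels (the core at 0.55 of the
whole-tumor radii, so nesting holds by construction).  Lesion texture is
a smoothed Gaussian random field whose variance and correlation length
depend on the class label (label 1: sd 1.8, correlation length 1.6
voxels; label 0: sd 1.0 / 0.6), so the class signal is carried by
texture — visible to the radiomics stage, not just the classifier.
Feature cohorts are standard normal noise with a mean shift of
`effect_size` (Cohen's d, default 2.0) added to the chosen informative
cells for label-1 patients.  Per-patient random streams derive from
(seed, patient index), so cohorts are reproducible regardless of
generation order.

What the phantoms deliberately do not model: MRI physics, bias fields,
registration error, partial-volume effects, irregular lesion shapes, or
correlated noise between modalities.  Passing tests therefore
demonstrate the *mechanics* of the pipeline — extraction correctness,
learnability of planted texture/feature signal, chance-level behaviour
under permutation — not clinical performance on real gliomas.

## Desk-scale experiment sizes

The validation experiments in `camrad.experiments` are sized for a
single CPU:

* **Signal recovery**: n = 30 (15/15), 3-fold CV, learning rate 0.01
  (from the published grid), batch size 4, 10 epochs, three seeds.
  Batch 4 rather than 32 keeps several SGD updates per epoch on a
  ~20-patient training fold.  Pass criteria: in a majority of seeds the
  cross-validated AUC exceeds 0.9 and at least 4 of the 5 planted
  features appear in the CAM top-10.
* **Permuted control**: identical pipeline on label-permuted cohorts,
  4 epochs, two repeats; mean AUC must lie within 0.5 +/- 0.15.
* **Model grid**: n = 16, 2 folds, 1 epoch — a completeness and layout
  check of the 30-row comparison harness, not a performance benchmark.

With ~0.28 s per sample step these run in roughly 10, 3 and 4 minutes
respectively.  Epoch counts this small are meaningful only because of
the batch-norm recalibration described above.

## Known limitations

* The numpy network is single-threaded and desk-scale; the published
  200-600 epoch grids on real cohorts would take days at this speed.
* CAM importance has ~7-row resolution (see above); per-feature claims
  sharper than a band are not supported by the mechanism.
* The permuted-control band (±0.15) reflects the small cross-validated
  cohort; it is a sanity check, not a calibrated null distribution.
* Chi-squared cohort comparisons are asymptotic; with expected cell
  counts near zero (as in sparse tumor-type tables) exact tests would
  be preferable but are not implemented.
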