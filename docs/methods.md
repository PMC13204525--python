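# Methods

This note documents the models, parameters and design choices behind
`dpetfusion` — an end-to-end pipeline for predicting pathologic complete
response (pCR) to neoadjuvant chemotherapy from dedicated-breast-PET-like
volumes — and what the synthetic validation does and does not establish.

## Problem and data model

Each case is a 3D SUV-like intensity volume with a binary tumor mask, a
small clinical covariate record (age, cT, cN, grade, Ki-67, regimen,
SUVmax) and a binary endpoint (total pCR: response in both breast and
axilla). A primary cohort of 129 cases is split 70/30 with label
stratification into a training set (n = 90) and test set 1 (n = 39); an
independently generated 18-case block with higher prevalence plays the
role of a temporally separated test set 2. All fitting — feature
selection, hyperparameters, fusion weights, imputation statistics —
happens on training rows only; the test partitions pass exclusively
through frozen transforms (asserted by a label-poisoning test).

## Synthetic cohort generator

Real patient volumes are private, so the generator plants the structure
the analysis assumes and nothing more:

* **Geometry.** Ellipsoidal tumors with semi-axes drawn uniformly from
  5–9 mm on a 48³ grid at 1 mm isotropic spacing (the scanner's true
  reconstruction spacing is not publicly documented; spacing is a
  configurable parameter, not a claim about the device).
* **Uptake.** A high-uptake core with a radial falloff to a rim at a
  configurable core:rim contrast (default rim level 0.5), on a smoothed
  positive background. Per-case SUVmax is drawn from a truncated normal
  (mean 32.2, sd 9, clipped to 14–65) and imposed exactly by rescaling
  the in-mask uptake, so the recorded SUVmax is the masked maximum by
  construction.
* **Texture channel.** Gaussian-filtered white noise with class-specific
  correlation length (default 5.0 mm vs 2.5 mm, amplitude 0.28 of the
  core level) — a spatial-frequency signal aimed at handcrafted texture
  features.
* **Focal-geometry channel.** A class-specific number of Gaussian
  high-uptake foci (default 1 vs 3, per-focus amplitude 0.8, sigma
  2–3 mm) at random interior positions — a spatial-arrangement signal
  aimed at the convolutional branch.
* **Clinical covariates.** Drawn with weak class-conditional shifts
  (|log-odds| ≤ 0.4 on standardized covariates), so the clinical baseline
  is deliberately mediocre.

Three named conditions freeze the validation settings: `strong_texture`
(granularity 6 vs 2 mm at amplitude 0.35, no focal difference),
`complementary_signal` (granularity 5 vs 2.5 mm plus 1 vs 4 foci at
per-focus amplitude 0.8), and `null` (no class difference anywhere).
These were calibrated once while designing the generator, before the
acceptance suite was wired up, and are not tuned thereafter. The default
condition itself is calibrated so cohort-scale branch discrimination
lands in the regime the original analysis reports (AUCs roughly 0.6–0.85
at 90 training cases), which is what a realistic emulation should give.

What the generator does **not** emulate: PET physics (attenuation,
scatter, partial-volume effects, reconstruction artifacts), multifocal or
non-ellipsoidal lesions, scanner/protocol variation, or any realistic
correlation structure among clinical covariates. Passing recovery tests
therefore demonstrates that the *pipeline machinery* detects the kinds of
signal it claims to detect — not that the real-data effect sizes or AUCs
would be reproduced.

## Habitat segmentation

Habitats are uptake-defined. Intensities are Gaussian-smoothed (sigma
1 mm, physical units; the source analysis smooths but gives no value) and
the in-mask values are split by k-means with k = 2. In one dimension with
exact convergence, 2-means reduces to a threshold rule, so the partition
is found exactly by scanning every cut between consecutive sorted values
with prefix sums — there is no initialization sensitivity and no RNG. The
cluster with the higher centroid is the high-uptake habitat. The mean
silhouette of the assignment (computed exactly in O(n log n) with the
Manhattan metric) is reported as a quality diagnostic; k stays fixed at 2.
ROIs with negligible intensity spread or with a habitat smaller than
8 voxels are flagged degenerate and assigned entirely to the high-uptake
habitat; their habitat-level features are median-imputed from training
columns downstream.

A caveat recorded as a known limitation: the claim that order-preserving
intensity transforms leave the 2-means partition unchanged is false in
general (the SSE-optimal cut depends on distances, not ranks). What holds,
and what the tests assert, is that the partition is always a contiguous
threshold cut, and that the cut is stable under monotone transforms when
the two uptake populations are well separated.

## Radiomics branch

**Feature bank.** 1688 features per region: 14 3D shape descriptors
(mesh-based surface/volume/sphericity, PCA axis lengths, maximum
diameters) computed once on the original mask, plus 93 intensity/texture
features (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM,
IBSI-style definitions) on the original image and 17 derived images:
8 single-level stationary-wavelet sub-bands (`coif1`; stationary so
sub-bands keep the grid shape), Laplacian-of-Gaussian at sigma = 1–5 mm,
and 4 pointwise transforms (square, square root, logarithm, exponential)
of the min–max-normalized image. Defining the pointwise transforms on the
normalized image makes the *entire* bank invariant to adding a constant
to the input, which the test suite checks. Texture matrices aggregate all
unique directions (13 in 3D) and are computed on fixed-bin-count
discretization (32 bins) inside each region. Over the whole ROI and the
two habitats a case contributes 5064 named columns.

**Selection cascade.** (i) two-sided Mann–Whitney U filter at alpha 0.05
(normal approximation with tie correction); retained columns are z-scored
with training statistics; (ii) greedy mRMR keeping m = 30 features, with
mutual information estimated on 8 equal-frequency bins and the
difference criterion (relevance − mean redundancy), ties broken by column
order; (iii) L1-penalized logistic regression over a 40-point log-spaced
lambda grid with stratified 5-fold CV on binomial deviance. The lambda
rule is the one-standard-error rule (sparsest model within one SE of the
minimum deviance); plain minimization is available but over-selects noise
badly in recovery simulations. On null data, where the U filter may
retain almost nothing and the LASSO may shrink everything away, the
cascade falls back to the least-insignificant features so the pipeline
remains runnable; selection quality is then nominal by construction.

**Classifiers.** LR, random forest, XGBoost, k-NN and Gaussian naive
Bayes, each grid-searched by stratified 5-fold CV AUC and refit on the
full training set. The branch that feeds fusion is the classifier with
the best CV AUC (LR or GNB in practice on this generator). Out-of-fold
probabilities for the stacking meta-learner re-run the grid search inside
each fold, so no training case is ever scored by a model that saw it.

**Stability.** A bootstrap re-runs the whole cascade on resampled
training rows (single-class resamples are redrawn and counted) and
reports per-feature reselection frequencies.

## Deep branch

Tensorization crops the ROI with a 5-voxel margin, resamples trilinearly
to 64³ (mask nearest-neighbour) and z-scores within the crop (guarded
standard deviation; a constant crop becomes all zeros).

Because no deep-learning framework is available in the target
environment, the models run on a small reverse-mode autograd written for
this package (`dpetfusion.nn.autograd`): broadcast-aware arithmetic,
matmul, im2col 3D convolution, average pooling, batch/layer norm,
softmax attention, GELU and a stable BCE-with-logits loss. Every
non-trivial backward pass is verified against central finite differences
in the test suite.

* **resnet3d_small** — stem convolution (stride 2) + 8 residual blocks in
  4 stages (widths w, 2w, 4w, 4w with w = 8) + global average pooling +
  two fully connected layers. The stem is preceded by a 4× average
  pooling, so the residual stages operate at 16³: pretrained video or
  medical-imaging weights are out of scope here, and at CPU scale the
  width- and resolution-reduced network is what 120-case training can
  support. The pooling is algebraically hoisted out of the network and
  applied once per dataset as a pure speed optimization.
* **vit3d** — non-overlapping 16³ patches (64 tokens), linear embedding
  to 64 dimensions with learned position terms, 3 transformer layers
  (4 heads, MLP ratio 2), mean token pooling and a linear head. Patch
  size 16 is a default, chosen to give 64 tokens; it is configurable.

Training: Adam with decoupled weight decay (1e-3), learning rate 1e-3,
batch size 16, 12 epochs, BCE loss; no augmentation, no early stopping,
and no schedule. Architecture/configuration selection uses mean
out-of-fold AUC under stratified 5-fold CV inside the training set; the
winner is retrained on all training cases and its out-of-fold
probabilities are kept for stacking. Held-out partitions play no role in
any of this. Seeded runs are bitwise reproducible on one machine;
cross-platform BLAS differences may perturb probabilities at the 1e-3
level.

## ITH branch

On the axial slice with the largest in-mask area (ties to the lowest
index), every in-mask pixel receives a 104-dimensional vector computed on
its 3×3 mask-intersected window: 19 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM and 5 NGTDM features (8-bin in-window discretization,
border pixels use the valid part of their window) plus 10 shape
descriptors of the window's in-mask geometry. The composition is pinned
here; the source analysis reports only the total dimension. Pixels are
k-means-clustered on z-scored vectors, k chosen from {2..5} by silhouette
(fixed-k override available), and the cluster map yields

    ITH = 1 − Σ_i p_i · (largest 4-connected component of cluster i) /
                        (total area of cluster i),

with p_i the cluster area fractions. The score is 0 exactly when every
cluster is one connected component and increases as clusters fragment;
it operationalizes "cluster area, connectivity and spatial distribution"
as a single scalar, since the referenced formula is not reprinted in the
source. The production path computes the 104 features for all windows at
once (vectorized); a window-by-window reference implementation is kept
and the two must agree to float precision in the tests. A univariate
logistic model on the score provides the branch probability; its AUC and
the two-sided rank-test p-value are reported.

## Fusion

**Decision level.** Inputs are the two branches' out-of-fold training
probabilities, logit-transformed after clipping to [1e-6, 1−1e-6]. A
logistic meta-learner is tuned (C grid, stratified 5-fold CV AUC) on
training rows, then frozen and applied unchanged to the test partitions.
Out-of-fold inputs are this package's choice — refit probabilities would
be optimistically distorted; the refit variant exists behind a flag in
the underlying functions for comparison experiments.

**Feature level.** The selected radiomic features (z-scored with training
statistics) pass through a bias-free, zero-initialized linear projection
to the CNN's pooled-representation width and are added element-wise to
the pooled features before the classification head; the whole network is
retrained end-to-end under the deep branch's procedure. Zero
initialization makes the initial forward pass exactly the image-only
network, and the bias-free projection means zeroed radiomics inputs
reproduce the image-only pathway exactly at any point in training. The
projection uses a 10× learning-rate multiplier: a zero-initialized path
attached to an already-learning backbone otherwise starves (the image
path saturates the BCE before the projection grows), which in the
complementarity study left fused performance measurably below the better
branch; the multiplier is the standard new-head remedy.

## Evaluation suite

* AUC: Mann–Whitney pair counting, ties 1/2 (equals the trapezoidal ROC
  area; checked to 1e-12).
* Fixed-cutoff metrics at 0.5: SEN, SPE, ACC, PPV, NPV with integer cell
  accounting; undefined ratios are flagged, not silently dropped.
* Bootstrap 95% CIs: class-stratified case resampling, percentile
  intervals, B = 2000 by default (the source states neither B nor the
  interval type); degenerate resamples are redrawn and counted, and a
  metric undefined on >10% of resamples raises.
* PR curves with step-interpolated average precision.
* Decision-curve analysis: NB(p_t) = TP/n − FP/n · p_t/(1−p_t) against
  treat-all and treat-none; beneficial intervals are maximal runs of
  strict superiority over both references and the longest run is the
  reported "final continuous" range.
* Hanley–McNeil: Q1 = A/(2−A), Q2 = 2A²/(1+A),
  V = [A(1−A) + (n1−1)(Q1−A²) + (n0−1)(Q2−A²)]/(n1·n0); power for the
  two-sided test of A = 0.5 uses the null-variance critical value and the
  alternative variance under a normal approximation. Published power
  percentages are not asserted anywhere: the printed values cannot be
  reproduced without knowing which variance entered the critical value,
  so the implementation exposes the pinned variant and reports what it
  computes.
* Confusion-matrix reconstruction: given two-decimal printed SEN/SPE and
  the class counts, enumerate all integer (TP, TN) whose ratios round
  (half away from zero) to the printed values; report the unique solution
  or flag ambiguity, and derive ACC/PPV/NPV at two decimals.
* Clinical baseline: z-scored continuous covariates, one-hot categorical
  covariates over their declared vocabularies (a stage level absent from
  90 training cases must still encode at test time; genuinely unknown
  values raise), logistic regression grid over regularization type and
  strength, elastic-net ratio, solver and class weighting.

## Problem sizes and numerical choices

Simulation studies (signal recovery, fusion complementarity, null
control) use a compact 3-image extraction profile (original, wavelet-HHH,
LoG sigma 2 mm; 16 bins) and 3-fold internal CV; the cohort-scale
analysis and the acceptance script use the full 18-image/32-bin bank and
the 5-fold protocol. Recovery conditions: strong texture at 320 cases
(120 training / 200 held out, 3 seeds), complementarity at 120 training /
300 test cases (3 seeds), null at 100 training / 400 test cases. These
sizes are the package's validation design. Tie-breaks are deterministic
everywhere (first-maximum argmax, column order, lowest slice index); all
randomized stages consume explicit seeds fanned out from one pipeline
seed via `SeedSequence`.

## Known limitations

* Synthetic realism is deliberately schematic (see above); reported
  synthetic AUCs characterize the pipeline, not breast-PET biology.
* The compact CNN/ViT are far smaller than their namesakes; conclusions
  about architecture rankings at scale do not transfer.
* The ITH formula is this package's operationalization of a cited but
  unreprinted score; biological comparability is not claimed.
* Shape descriptors use voxel/mesh approximations (marching cubes on the
  binary mask); very small regions fall back to voxel-count surrogates.
* The per-pixel 2D bank and the 3D bank share definitions but not code
  paths; their agreement is enforced by tests only at the window scale.
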