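# Methods

## Problem and scope

Screening mammograms (craniocaudal view, 224×224 8-bit) show the lesion —
calcification or mass, benign or malignant — as the brightest structure in
the breast, with dense tissue only a few grey levels below it and bright
acquisition artefacts (border frames, text markers, a near-vertical line at
the breast edge) elsewhere in the frame.  The package implements the full
chain from raw image to four-class prediction: artefact removal,
enhancement, augmentation, dynamic-threshold seeded region growing, a
16-descriptor lesion feature vector, and an accuracy-thresholded stacking
ensemble.  Base-classifier internals are delegated to scikit-learn and
XGBoost; the segmentation rule, the selection/stacking logic, the
confusion-matrix metrics and the synthetic phantoms are authored here.

## Synthetic phantoms

Real mammograms cannot ship with the package, so every stage is exercised on
a deterministic phantom: a half-ellipse breast flush with the left edge
(base intensity 120), Gaussian-blurred noise texture (σ = 8 intensity units,
blur σ = 3 px) emulating dense tissue, a uniform lesion disk at intensity
250 (the artefact-free maximum, radius 12 by default), and optional
artefacts — a 255 border frame (3 px), 2–4 bright rectangles in the corner
opposite the breast, and a 2-px near-vertical 255 line touching the breast's
right extent.  A validity check enforces the modelling assumptions: the
lesion must exceed the tissue base by more than 3σ of texture and lie fully
inside the breast.  The class-labelled dataset generator encodes class in
lesion radius (BC 5, MC 8, BM 11, MM 15 px at 224², scaled with image size)
with jittered placement — calcifications smaller than masses, malignant
larger than benign, which gives the feature table a genuine geometric class
signal.

What the phantoms do *not* model: anatomical texture statistics, pectoral
muscle, multi-lesion images, spiculated or blurred lesion margins, detector
noise.  Passing the phantom suite therefore demonstrates that the pipeline's
mechanics (artefact suppression, threshold logic, growth, descriptors,
model plumbing) are correct, not that its accuracy transfers to clinical
data.

A second generator emits a purely numeric 4-class feature table: informative
columns are class-conditional Gaussians whose class means sit
`class_separation` within-class standard deviations apart (feature *j*
marks class *j* mod 4), noise columns are class-independent standard
normals, class priors exactly uniform.  `class_separation=0` is chance
level; `6` is linearly separable — the two calibration points used by the
tests.

## Preprocessing

Stage order is fixed: border mask → binarise → largest component → apply
breast mask → vertical-line removal → gamma → CLAHE.

* **Border mask** zeroes all pixels within 5 px (default) of any edge;
  idempotent by construction.
* **Binarisation** defaults to Otsu with a fixed-threshold override; on
  integer images the mask is `img > t_otsu` (implemented as `>= t+1` to keep
  the documented `>=` convention exact).  A constant image falls back to the
  fixed threshold with a logged warning.
* **Largest component** uses 8-connectivity and fills interior holes; area
  ties break toward the component holding the row-major-smallest pixel, so
  results are deterministic.
* **Line removal**: Canny (hysteresis 50/150, σ = 1) then a probabilistic
  Hough transform restricted to normals within ±10° of horizontal (lines
  within 10° of vertical), vote threshold 50, minimum segment length 30 px;
  accepted segments are overdrawn in black at width 5.  The Hough angular
  resolution defaults to π/180; the coarser π/50 sometimes quoted for this
  configuration is selectable but looks like a transcription slip and is not
  presumed.
* **Gamma** is applied on [0, 1]-normalised intensities with gain 1
  (`V_out = V_in^2` at the default γ = 2.0), making the map bit-depth
  independent; note γ > 1 darkens mid-tones on normalised data.
* **CLAHE** exposes `clip_limit` in the OpenCV convention (histogram bins
  clipped at `clip_limit·tile_area/256`, default 1.0, 8×8 tiles) and maps it
  internally to scikit-image's normalised convention (÷ 256 at 256 bins).

## Quality metrics

MSE is the mean squared pixel difference (normaliser `1/(m·n)`, the only
reading consistent with a per-pixel error); RMSE = √MSE; PSNR =
20·log₁₀(MAX/RMSE) with a documented `inf` sentinel for identical images;
SSIM is the standard Gaussian-weighted 11×11, σ = 1.5 form with stabilisers
c₁ = (0.01·MAX)², c₂ = (0.03·MAX)².  The widely quoted acceptability band
for 8-bit PSNR is 30–50 dB; on phantoms the enhancement step scores lower
(≈ 16 dB) because γ = 2.0 strongly darkens the mid-grey synthetic breast —
a property of the phantom's intensity design, not a pipeline defect.
Published quality tables for this configuration on real data are internally
consistent between MSE and RMSE (√16.38 ≈ 4.05 vs 4.04 printed) but their
PSNR column is not reproducible from the printed MSE via the formula at
MAX = 255 (29.99 dB vs 36.67 printed for that pair); the formula is
implemented literally.

## Augmentation

Exactly seven variants per image — hflip, vflip, hvflip, rot+30, rot+30 +
hflip, rot−30, rot−30 + hflip — so a labelled set grows 8× with provenance
records.  Flips are exact pixel permutations (histogram-preserving,
involutive; hvflip ≡ 180° rotation bit-exactly).  Rotations keep the
original canvas, interpolate bilinearly and fill with black to match the
mammogram background; a ±30° round trip reproduces interior pixels within
≤ 2 intensity levels on smooth images.

## Dynamic-threshold region growing

Per image: `b` = maximum intensity, near band `[b−δ, b)` with δ = 10 of 255
(robust to isolated hot pixels, unlike "second distinct histogram level"),
`count_max` = pixels at `b`.  Rule: threshold `b` when `count_max ≥
min_region` (default 10 px), else `b−δ` — the brightest level alone is then
too sparse to cover the lesion body.  Diagnostics record both counts and
which branch fired so alternative rules can be compared offline.  The seed
is the rounded (floor(x+0.5)) centroid of the brightest set, snapped to the
nearest above-threshold pixel (Euclidean, row-major tie-break) when disjoint
bright blobs put the centroid on dark background.  Growth is the seed's
connected component of `img ≥ threshold` (default 8-connectivity — lesion
boundaries touch diagonally), computed by connected-component labelling and
verified in tests against an independent brute-force flood fill.  Only the
seed's component is grown: a single-lesion assumption.  Lowering the
threshold can only enlarge the region (monotonicity property test).

## Features

Sixteen descriptors; conventions chosen where the field is ambiguous and all
stated in the module docstring: equivalent diameter is the same-area circle
√(4A/π) (a same-perimeter variant P/π exists as an option); extent is
area/bounding-box (the area/convex-hull reading would duplicate solidity);
entropies in bits; kurtosis non-excess; GLCM at distance 1, angle 0°, 64
levels, symmetric, restricted to pixel pairs fully inside the mask.  The
perimeter uses the 4-direction Crofton estimator: the marching-squares
contour walk overestimates a discretised r = 32 disk's perimeter by ≈ 6.6 %
(circularity 0.88 instead of ≈ 0.98), while Crofton is within 1.1 %; the
contour variant stays selectable.  Convex area is the pixel count of the
hull of pixel centres without the half-pixel offset, a superset of the mask
that keeps a discretised disk's solidity at ≈ 1 instead of deflating it by
≈ 2.4 %.  Degenerate regions are defined, not errors: single-pixel masks
report std/skewness/kurtosis 0, point/line masks fall back to filled area
for the hull.  Min-max normalisation is fit on training rows only; held-out
rows may leave [0, 1] and are deliberately not clipped.  Intensity
statistics are computed on the pipeline's enhanced ROI image (the image the
classifier consumes), not the raw input.

## Ensemble and model study

The bank holds eleven classifiers with library defaults and a fixed seed —
published hyper-parameters do not exist for this configuration, and
documented defaults are reproducible.  SVC is RBF-kernel, SVM linear-kernel
(both probability-calibrated); SGD trains a logistic model so every member
exposes class probabilities for stacking.  Selection is *strictly greater*
than the accuracy threshold, preserving bank order; the canonical worked
example feeds the published benchmark accuracy column through the rule
(5/3/2 members at 90/93/95).  Stacking feeds cross-validated class
probabilities (default 10-fold, clamped to the smallest class count) to a
logistic-regression meta-learner.  Evaluation: accuracy = trace/total;
multiclass MCC in the covariance form (reduces to the binary TP/FP/TN/FN
expression at 2×2, cross-checked in tests against an independent
implementation); F1 macro-averaged one-vs-rest; AUC macro one-vs-rest —
single-number multiclass summaries require an averaging convention and
macro is the stated choice.

Feature selection: random-forest impurity importance ≥ threshold;
univariate top-k ANOVA-F; |Pearson r| of feature vs class label ≥ threshold
(a feature-feature redundancy filter would be the alternative reading; the
label-correlation form is implemented); PCA top-n components fit on train
only; greedy forward wrapper stopping when the cross-validated accuracy gain
falls below a tolerance.  The K-fold sweep uses twelve fold counts
{3, 4, 5, 7, 10, 12, 15, 18, 20, 22, 25, 30} (the count and range are
prescribed, the individual values are a documented choice), stratified and
shuffled at a fixed seed; K = n rows degrades to leave-one-out, K above the
smallest class count is an error.

## Problem sizes and determinism

Test and acceptance runs use sizes chosen to exercise every code path while
staying lightweight: 20 phantoms for lesion recovery, 100 random 16×16
images for the flood-fill audit, 160-row separable tables (40 per class)
for the stacked-classifier and K-fold studies, and a 4×6-phantom end-to-end
pipeline run.  Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical (inputs, config, seed) reproduce
bit-identical images, tables and reports, and the pipeline manifest records
content hashes to verify it.

## Known limitations

Single-lesion assumption; no pectoral-muscle handling (CC view largely
avoids it); phantom realism as discussed above; classifier hyper-parameters
untuned by design; the accuracy-threshold selection inside the sklearn
estimator uses internal cross-validation on the training data, whereas the
module-level workflow selects on a held-out split — both are exposed.
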