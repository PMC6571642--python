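# Methods

This note documents the models, conventions, parameter choices and known
limitations of `nystagrid`. It is written for a maintainer or reviewer who
wants to know *why* the pipeline is built the way it is, not just what each
function does.

## Problem setting

Benign paroxysmal positional vertigo (BPPV) is diagnosed by provoking
nystagmus with positional maneuvers and reading its three-dimensional
pattern: the excited semicircular canal determines the combination of
horizontal, vertical and torsional beating. The pipeline quantifies
nystagmus from infrared eye videos, condenses a ten-test examination into a
3×10 "grid image" of signed per-axis amplitudes, and classifies the grid
into one of eight canal diagnoses (right/left posterior, right/left
geotropic lateral, right/left ageotropic lateral, right/left anterior).

## Pupil tracking

Each frame is processed in a fixed order: circle Hough transform on Canny
edges as a gate (no plausible circular dark region ⇒ blink), threshold
binarization, boundary extraction of the dark region selected by the Hough
circle, ellipse fit to the boundary. The ellipse center is the eye
position; the first valid frame is the reference.

Numerical choices:

* **Binarization threshold** — Otsu's method on the frame histogram,
  clamped to ≤ 100 gray levels. Otsu adapts to contrast; the clamp prevents
  the threshold from drifting into the iris on low-contrast frames.
* **Blink rule** — two stages: an absolute Hough-accumulator floor (0.2)
  per frame, and a clip-level rule flagging frames whose score falls below
  half the clip median. The relative rule catches partial lid closures that
  still produce a weak circle.
* **Gap handling** — invalid runs of ≤ 5 frames are bridged by linear
  interpolation of position before velocities are differenced; longer runs
  split the trace into segments and no velocity ever spans a split.
* **Degenerate fits** — if the ellipse estimation fails (too few boundary
  points, collinearity) the detector falls back to the darkness-weighted
  center of gravity of the pupil region, which agrees with the ellipse
  center to well under a pixel on clean frames.
* **Units** — positions stay in pixels; there is no pixel-to-degree
  calibration stage, so all downstream velocity thresholds are in px/s.
  `axis_direction` returns 0 on an exactly zero velocity sum (read as "no
  nystagmus on this axis").

## Torsion

An iris annulus (inner radius 1.15 × pupil semi-major axis, outer 1.8 ×, 8
radial samples) is unwrapped to polar coordinates at 1°/bin over two
lateral 90° arcs centered on the horizontal meridian; the lateral arcs
avoid the eyelid-occluded upper and lower iris. Rotation between
consecutive frames is the shift maximizing normalized cross-correlation of
the angular gray-level profile, searched over ±15°, evaluated on
overlapping 30-bin patches (stride 15) whose votes are combined by median,
and refined to sub-bin precision by parabolic interpolation through the
correlation peak. A patch only votes when its peak correlation reaches
0.2; if no patch qualifies the pair is invalid and the cumulative angle is
carried forward.

The default reference is the *previous* frame (incremental matching). This
tracks slow texture change but accumulates drift; a first-frame reference
mode exists for comparison and is immune to drift but limited to rotations
inside the search window. Two summary statistics are provided: the mean
signed increment × frame rate (mean torsional velocity, the default) and
the mean absolute increment × frame rate ("mean sample distance"), which
is retained because it is outlier-sensitive in an instructive way —
alternating beat noise inflates it while canceling in the signed mean.

Sign convention: positive torsion is counterclockwise in the displayed
image (the patient's clockwise, since the camera faces the eye).

## Feature grid

Per positional test, each axis is summarized by its mean **slow-phase
velocity**: transient (frame-to-frame) velocities whose magnitude exceeds
2 × the 75th percentile of |v| are labeled fast resetting phases and
removed; the mean of the remainder is the summary. For a constant-velocity
trace nothing is removed; for a sawtooth the resets are far above the
cutoff and drop out. The per-axis direction is the sign of this summary —
for ideal jerk nystagmus the raw velocity sum is near zero (slow and fast
phases cancel), so the slow-phase mean is the stable signed quantity.

Clinical sign conventions: horizontal + = rightward; vertical + = upbeat
(negative image-y); torsional + = counterclockwise in the image.

The **normality short-circuit** stops the pipeline before classification
when every |overall velocity| is strictly below its axis threshold across
all tests (defaults 5 px/s horizontal and vertical, 2 °/s torsional; a
value exactly at the threshold counts as abnormal).

Encoding: velocities are converted to a dimensionless amplitude scale
(0.1 px/s and 0.01 °/s per unit, so the ±1000 amplitude cap spans
±100 px/s and ±10 °/s — comfortably covering clinically observed
slow-phase velocities), clamped to ±1000, and mapped affinely to 8 bits:
`cell = 128 + round(127·a/1000)`, so 0 → 128 (neutral, also the fill for
missing tests), +1000 → 255, −1000 → 1. The quantization step is
1000/127 ≈ 7.9 amplitude units per gray level; `decode_grid` inverts the
map to within half a step and `build∘decode∘build` is exactly idempotent.

The ten-test column order is a package convention (the battery is named
generically in the clinical literature without a canonical ordering):
bow, lean, lying-down, supine roll right/left, straight head-hanging,
Dix–Hallpike right/left, return-to-sitting right/left. It is a single
constant (`TEST_ORDER`) so an alternative enumeration is a one-line change.

## Synthetic data

**Grid sampler.** Each class template assigns (mean, SD) Gaussians to the
cells its canal activates: posterior canal → torsional + upbeat in the
affected side's Dix–Hallpike column; geotropic lateral canal → horizontal
beats toward the lower ear in both roll columns, stronger on the affected
side; ageotropic lateral canal → beats toward the upper ear, stronger when
rolling toward the unaffected side (the standard laterality rules);
anterior canal → torsional + downbeat in head-hanging, echoed in the
Dix–Hallpike column. Defaults: active mean 400 (affected) / 200
(contralateral), SD 80, background SD 20. These put active cells well
clear of neutral after 8-bit encoding while leaving enough overlap that
classification is a real learning task rather than a lookup. Datasets are
exactly class-balanced (incidence 1/8 per class in every split); training
and validation consume disjoint random streams spawned from one seed, and
per-class counts are explicit arguments — no split ratio is ever inferred.

**Video renderer.** A dark anti-aliased pupil ellipse over a striated iris
annulus (random angular harmonics, rotating with the torsion schedule)
over a light sclera, with additive Gaussian pixel noise and optional
near-uniform blink frames. Nystagmus is modeled as a sawtooth: slow drift
at the specified slow-phase velocity with an instantaneous reset each beat
period, which makes the slow-phase ground truth exact at frame resolution.
The renderer deliberately omits eyelids, corneal reflections, defocus,
head motion and camera distortion; passing tracking tests on rendered
clips therefore demonstrates the estimator's correctness on its model
assumptions, not robustness to real-world recording artifacts. Iris
texture granularity and frame geometry are spec parameters so that the
resolution-dependence of torsion estimation can be probed rather than
fixed.

## Classifier

The network is `conv_depth` blocks of [3×3 convolution (edge padding) →
batch normalization → ReLU] over the 3×10 single-channel grid, channel
width starting at `base_neurons` and doubling per block (capped at 512),
then a fully connected softmax over the 8 classes. Defaults: depth 3, base
32, batch 128, Adam at 1e−3, ≤ 50 epochs, early stopping on validation
loss with patience 5 (best weights restored). Inputs are normalized to
(v − 128)/128 so neutral is exactly zero. The raw 3×10 matrix is the
input; an upscaled block rendering exists for viewing but carries no extra
information. The network, backpropagation and optimizer are implemented
directly on NumPy arrays — at this input size a full deep-learning runtime
adds dependency weight without adding capability, and the from-scratch
implementation keeps initialization, shuffling and updates exactly
reproducible from one integer seed.

`rule_classify` implements the canal rules deterministically on decoded
amplitudes (a cell is active when |amplitude| > 50; competing canal
patterns are resolved by largest total active amplitude; no pattern →
"indeterminate"). On noiseless template grids it recovers all eight
classes, which makes it the independent oracle for the trained network.
Normality is handled upstream by the short-circuit, not as a ninth class.

## Evaluation

One-vs-rest per-class precision, sensitivity, specificity, FPR and
accuracy; F-beta with β = 1; micro-averages from pooled TP/FP/TN/FN and
macro-averages as unweighted means (for single-label predictions micro
precision = micro sensitivity = accuracy, an identity the tests assert on
random matrices). The no-information rate is the majority-class frequency
and anchors a one-tailed exact binomial test on the number of correct
predictions. ROC curves use the exact threshold set (sorted unique scores
plus ±∞ sentinels) with trapezoid areas, which equals pairwise
concordance with ties counted ½. Cross-validation is stratified k-fold
(fold assignment a pure function of the seed) with mean ± t(0.975, k−1) ·
SD/√k confidence intervals — the t distribution rather than a normal
approximation because k = 10 folds is small-sample. Zero-denominator
metrics return 0 with a logged warning so a degenerate fold never aborts a
cross-validation run.

A constant, `CLINICAL_VALIDATION_TABLE`, holds the published per-class
validation means of the clinical study whose methodology this package
re-implements (1005 patients, 10-fold cross-validated); it is reference
input for arithmetic self-checks — recomputing F1 from precision and
sensitivity, macro-averaging the columns, summing the class sizes — all of
which the metrics engine reproduces to the printed precision.

## Problem sizes

The test suite and the acceptance script size their computations to run
comfortably on one CPU: tracking checks use 30–75-frame clips at 160×200
px; the full-scale dataset check generates 90,000 grids (a 3×10 grid is 30
bytes, so this is seconds of work); classifier checks train on 400 grids
per class with a depth-3/base-32 network and validate on 150 per class,
with a smaller depth-2 network for the label-shuffling control. These
sizes were chosen as the smallest at which the measured quantities are
stable across seeds.

## Known limitations

* No pixel-to-degree calibration; thresholds are device-dependent.
* Torsion drift accumulates in incremental mode; the clinical study this
  re-implements reports torsion as its weakest axis for related reasons
  (iris resolution, repeated-texture ambiguity, template-matching error
  accumulation).
* The renderer's simplicity means synthetic validation bounds real-world
  performance from above.
* Single-canal BPPV only; multi-canal disease and non-BPPV vestibular
  disorders are out of scope, as is any claim about the clinical video
  performance of the original study, whose patient videos are not
  available.
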