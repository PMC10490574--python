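# Methods

This note documents the models, operational definitions, parameter choices
and known limitations of the `pfb` pipeline, in the order the stages run.

## Problem setting

Subjects are labelled from DEXA T-scores: healthy iff T > −0.9, unhealthy
otherwise (the boundary value −0.9 itself is unhealthy). Labels are 0 =
healthy, 1 = unhealthy. The study cohort this package models contains 284
subjects (185 healthy, 99 unhealthy) scanned under seven different TR/TE/
flip-angle protocols; the per-protocol referred/healthy/unhealthy counts are
recorded in `pfb.phantom.PROTOCOLS` and drive the phantom generator's
protocol sampling.

## Synthetic phantoms

The generator draws a femur-like bright region on a darker background:

* **head** — a disk of radius `head_radius_px`;
* **neck** — a thick segment of width `neck_width_px` leaving the shaft top
  at the neck–shaft angle toward superior-medial; its length defaults to
  2.2 × head radius;
* **shaft** — a vertical rectangle of width `shaft_width_px` spanning rows
  0.48–0.92 of the canvas at column 0.62 (canonical left orientation; a
  right-side phantom is the exact horizontal mirror).

Intensities are i.i.d. Gaussian inside the bone (`bone_mean_intensity`,
`bone_intensity_sd`), constant outside (`background_mean`), scaled by a
protocol-dependent global gain, clipped at 0, then a fraction
`salt_pepper_fraction` of pixels is replaced by 0 or the image maximum.

Class conditions (defaults of `spec_for_subject`): healthy femurs have head
radius 26 px, neck width 22 px, shaft width 20 px, neck–shaft angle 130°,
bone mean 150, SD 10; fully separated unhealthy femurs have 23 px, 15 px,
17 px, 122°, 120, 18 — thinner neck and head, straighter angle, lower
marrow signal, higher intensity variance, which is the direction real
bone-density loss moves these quantities. A `separation` parameter in
[0, 1] linearly interpolates the unhealthy condition from the healthy
baseline, so separation 0 yields two identically distributed classes (the
chance-level control) and 1 the fully separated condition. Per-subject
jitter: 4% multiplicative SD on geometry, ±2° on the angle, ±4 on the bone
mean. Background is 30, salt-and-pepper fraction 0.02, canvas 256×256 by
default (tests and the acceptance script use 96–128 px canvases to keep
runtimes small; all features are scale-equivariant so this only changes
resolution, not structure).

What the phantoms do **not** emulate: soft-tissue anatomy around the femur
(real slices contain pelvis, muscle and marrow heterogeneity), partial-volume
and bias-field effects, spatially correlated texture, and inter-subject pose
variation beyond mirroring. Passing phantom tests therefore demonstrates
that the pipeline's machinery is correct and parameter-recoverable, not that
its accuracy transfers to clinical scans.

### Noise injection

`add_gaussian_noise` adds zero-mean white Gaussian noise with variance
σ² = P / 10^(SNR/10), where P is the mean squared intensity of the whole
image (configurable to in-mask power). The output is clipped at 0 by
default, which truncates the noise distribution once σ approaches the
background level; at SNR ≤ 0 dB the clipped field's realized variance is
therefore below the target. The calibration contract (realized SNR within
0.5 dB) refers to the injected field and is verified with `clip=False`,
which returns a plain array since negative intensities cannot live in the
image carrier.

### Minority augmentation

`augment_minority` equalizes class counts by appending jittered copies of
minority-class images: uniform rotations in ±40° and uniform shifts up to
20% of each image dimension (the conventional "0.2" fraction; a literal
0.2% would be sub-pixel and do nothing). Originals are never modified.
Inside cross-validation the `augment` option balances **training rows
only** — never test folds — to avoid leakage; because only the feature
table exists at that point, balancing there is seeded minority
oversampling rather than image-space rotation. Image-space augmentation is
available to pipelines that re-extract features per fold.

## Segmentation

Images are median-filtered (5×5, reflected edges) to remove salt-and-pepper
noise. Two methods then compete:

* **Region growing bounded by Canny edges.** Canny hysteresis thresholds
  are the 70th/90th percentiles of the gradient magnitude restricted to the
  *active* population (above 5% of the maximum) — computing percentiles over
  the whole image would let a large flat background drag both thresholds to
  the noise floor and turn bone texture into edges. The 4-connected flood
  region containing the seed is taken on the complement of the 3×3-dilated
  edge map, dilated back two steps (the flood stops a couple of pixels
  inside the edge band), closed with a 5-px disk and hole-filled. A region
  reaching more than half the image border is a flood-out and fails.
  Seeds come from the strongest Hough circle with radius in 6–20% of the
  smaller image dimension (the femoral-head scale at this framing), falling
  back to the row/column intensity-projection argmax.
* **Active contour.** A region-based level set (morphological Chan-Vese,
  200 iterations, smoothing 1) evolved from an initial circle; the
  component overlapping the initialization is kept and hole-filled. A
  constant image or a < 10-px result is a failure. This variant suits the
  bright-bone/dark-background contrast and is deterministic.

With ground truth available the higher-DSC mask wins. Without it, a
plausibility screen accepts single-component masks with area 2–40% of the
image and solidity ≥ 0.55, preferring region growing on ties. The solidity
floor is deliberately low: the head+neck+shaft silhouette is L-shaped and
its solidity on correct masks is ≈ 0.6, so a compactness threshold tuned
for blob-like organs would reject every correct result. If both methods
fail, a manually delineated mask file may stand in.

## Geometric features

All geometry is measured on the canonical mask: right femurs mirrored,
cropped to the bounding box plus a 5-px frame. Coordinates are 0-based
(row, col), x = columns, y = rows. The twelve quantities are only sketched
pictorially in the source material; the operational definitions below are
this package's reconstruction, chosen to be scale-equivariant and
parameter-recoverable on phantoms:

* **Head** — largest inscribed circle: center = argmax of the Euclidean
  distance transform (EDT), W₀ = twice the EDT there.
* **Neck bottleneck** — along the widest path from the head center to the
  shaft centroid (minimum-cost route through 1/(EDT+0.5)), consider points
  outside the head disk and farther than 1.2 shaft half-widths from the
  shaft axis line; the bottleneck is the middle of the plateau of
  near-minimal EDT values there. W₁ = twice the EDT at the bottleneck,
  L₁ = its distance from the head center, W₂ = twice the EDT at the
  midpoint of the head→bottleneck segment. The plateau-middle rule keeps
  the location stable under rescaling; the shaft-distance exclusion stops
  the search from sliding into a shaft narrower than the neck. (Using the
  whole-mask centroid to define the neck axis was tried first and rejected:
  the centroid is dragged down the shaft and biases the angle by ~20°.)
* **Shaft** — principal axis of the inferior third of the mask, oriented
  distally. L₂ = extent of the whole mask along this axis; W₃/W₄ = twice
  the EDT at the proximal/distal third points of the shaft region's span.
* **θ** — angle between the bottleneck→head direction and the distal shaft
  axis, reported on the obtuse side (the anatomical neck–shaft convention,
  ~120–140° on normal femurs). A disk-like mask (centroid within 3 px of
  the head center and inscribed radius ≥ 0.9 of the equivalent radius) has
  no neck or shaft: it is flagged degenerate with θ = 90° and all widths
  equal to W₀.

On 30 jittered phantoms these definitions recover W₀ within 2 px, θ within
5° and correlate with the generator's neck width at r > 0.99. Lengths are
scale-equivariant to within 2% or 2 px (pixel discretization dominates at
small bases); the crop-frame offset (5 px) must be subtracted from
coordinates before comparing across scales.

## Boundary curves

The crop's occupied rows are split into three equal bands; C1-0/C1-1/C1-2
record, per row of the top/middle/bottom band, the distance from the left
crop edge to the first bone pixel. C2-0 records, per column of the left
half, the distance from the top edge down to the bone; C4-0, per column of
the right half, the distance from the bottom edge up. Rows/columns missing
the bone are dropped; fewer than 8 raw samples is an error; every curve is
linearly resampled to length 64 so crops of different sizes are comparable.
The band/direction assignment is fixed in `pfb.curves` and can be swapped
without touching downstream code.

Ramp descriptors: *average ramp* is the OLS slope of value against index —
chosen because the ramp-removed signal subtracts it as a trend and an OLS
slope is the unique choice that leaves a zero-slope residual; *first-to-last
ramp* uses the literal endpoints; the *ramp-removed signal* is value −
slope·index (subtracting a scalar, as a literal reading might suggest,
would not remove a slope at all). Statistics use the population (biased)
convention: moment1/moment2 are the first/second central moments (moment1
is identically ~0 and kept for table fidelity; moment2 equals the
population variance), kurtosis is excess kurtosis, and "elongation" —
named in prose but absent from the feature table — is treated as a synonym
for kurtosis. Zero-variance curves report skew/kurtosis 0 with a
degenerate flag. The curve whose statistics are computed on the raw signal
(C1-2, 8 statistics) versus the ramp-removed signal (the other four, 10
statistics each) follows the published feature table row by row.

## Texture features

First-order statistics (mean — a marrow-fat/BMD surrogate —, population
variance, skew) are computed over in-mask intensities only. The
box-counting fractal dimension uses boxes of size {2, 4, 8, 16, 32}
(capped at a quarter of the point-set extent, at least three scales) and
returns the negative OLS slope of log N(s) vs log s; it is computed on the
**boundary** pixel set by default, since boundary complexity is what
separates the classes, with a full-mask option. The GLCM quantizes in-mask
intensities to 32 levels, accumulates symmetric co-occurrences at distance
1 over angles {0°, 45°, 90°, 135°} with out-of-mask pixels excluded via a
sentinel level, normalizes, and reports contrast, correlation, energy and
homogeneity — the canonical Haralick quartet (the source material never
names its four GLCM statistics; this quartet matches the common MATLAB
tooling). A constant region returns (0, 1, 1, 1) with a degenerate flag.

## Feature vector

The 68 primaries are ordered: 12 geometric, 10 C1-1, 8 C1-2, 10 C1-0, 10
C2-0, 10 C4-0, 3 intensity, 1 fractal, 4 GLCM. Squares then cubes follow,
so index i+68 is always (feature i)² and i+136 is (feature i)³ — this
fixed block layout is what selection-map images index into. Any non-finite
primary aborts assembly naming the feature. Standardization (z-scoring
with train-fold means/SDs, zero-SD columns mapped to 0) is applied inside
every CV fold; it is not part of the source pipeline's description but
kernel methods are scale-sensitive and would otherwise be dominated by the
cubed features' dynamic range.

## Genetic algorithm

Chromosomes are boolean vectors over the feature columns; fitness is
Cost = 1/(Accuracy + 1/NOF) with Accuracy the pooled 10-fold CV accuracy
**as a fraction** — with percentages the 1/NOF term would be negligible
and the cardinality pressure the cost is designed to exert would vanish.
Defaults follow the published run sizes (population 100, up to 500
iterations); operators are standard choices, all configurable: tournament
selection of size 3, uniform crossover with probability 0.8, per-bit
mutation at rate 1/L, elitism of 1 (making the best-cost history monotone
non-increasing), empty chromosomes repaired by switching one random bit
on. Fold assignment is frozen per run so all chromosomes face the same
folds, and evaluations are cached by bit pattern — evaluation dominates
runtime. The per-iteration best chromosome is recorded, giving the
feature-index × iteration selection map.

## Classifiers and evaluation

Stratified 10-fold CV (plain shuffled partition, with a warning, when a
class has fewer members than folds). The pooled-over-folds confusion
matrix — not per-fold averaging — is the only convention under which the
published per-classifier tables total 284 subjects. Accuracy =
100·(TH+TU)/total; F1 is the macro average of the healthy-as-positive and
unhealthy-as-positive views, which reproduces all six published F1 values
from their printed confusion counts to 2 decimals (the F1 convention was
otherwise unstated). Hyperparameters are fixed defaults, exposed in the
spec objects: SVM C = 1 (poly degree 3), Gini tree of unlimited depth,
L2 logistic regression. "RBF" and "Gaussian" SVMs are one kernel form with
two kernel-scale policies — the 1/(d·var) heuristic versus a
median-pairwise-distance bandwidth — reconstructing a MATLAB kernel-scale
distinction with no other obvious reading.

The noise harness degrades **test** images at each requested SNR before
feature extraction while training stays on clean features, reporting
accuracy per SNR plus the clean reference. The class-average-difference
map canonicalizes every image with its mask, resamples to a common frame,
and subtracts the healthy from the unhealthy mean image.

## Problem sizes

Default test and acceptance runs use phantom canvases of 96–128 px,
cohorts of 15–100 subjects per class, 4–10 folds, and GA runs of
population 30 × 50 generations on a 21-feature planted benchmark; these
sizes were chosen as the smallest at which the statistical bands under
test (chance-level nulls, ≥ 8/10 GA recovery, 2-px/5° recovery) are
comfortably resolved.

## Known limitations

* The operational definitions of the geometric quantities and curve
  regions are reconstructions of pictorial sources; a different but
  self-consistent relabeling (e.g., among W₁–W₄) would rename features
  without changing pipeline mechanics.
* The headline clinical accuracy of the source study is not reproducible
  without its scans; the package pins the reproducible arithmetic
  (metrics, counts) exactly and the pipeline behaviour by phantom
  properties instead.
* Segmentation is tuned for a single bright bone on a darker background;
  multi-bone scenes, 3-D volumes and vendor-specific DICOM tags are out of
  scope.
* GA selections are seed-dependent (different runs may pick different,
  equally cheap feature sets); stability is measured by the selection map,
  not enforced.
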