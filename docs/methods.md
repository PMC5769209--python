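# Methods

This note records the models, parameter choices and numerical conventions
behind `nemaphen`, and what the synthetic-data tests do and do not
demonstrate about real microscope data.

## Input model and the contrast gate

A plate acquisition is a set of equally shaped 2-D channels on a common
[0, 1] intensity scale with a mandatory bright-field channel.  Integer
TIFF/PNG data are normalized by the full dtype range; RGB pages are
grayscaled by the BT.601 luminance weights.  Physical pixel pitch comes
from one of three named presets (10X objective → 0.45 µm/px, 4X → 1.14,
2X → 5.14) or is given explicitly; square pixels are assumed throughout
(area uses height × width, length and widths use a single pitch).

The admission statistic is the standard deviation of the normalized
grayscale bright-field image, computed on the **raw** image before any
detection-time stretching.  Images scoring below 0.04 are refused with a
diagnostic naming the measured value; well-prepared agarose plates
typically score 0.06–0.15.  The alternative — scoring after automatic
contrast adjustment — would make the gate depend on the stretch
percentiles and accept arbitrarily flat images, so it was rejected.

For detection only, a working copy of the bright-field channel receives a
linear 1st–99th percentile stretch.  Raw intensities are preserved in all
crops: every fluorescence quantity is measured on unstretched data.

## Segmentation

Binarization is local-mean adaptive thresholding with two free
parameters: a pixel is foreground iff its intensity is below
`(1 − threshold) × mean` over the `neighborhood × neighborhood` window
(replicate-padded borders, uniform-filter implementation).  Defaults per
preset scale with resolution (medium: 101 px window, threshold 0.10).
Polarity is fixed to dark-foreground with a config flag for inverted
optics.  A Gaussian-weighted local mean would be a drop-in alternative;
the box mean was chosen for exactness and speed.

Cleaning removes 8-connected components below `min_object_area`, removes
components touching the image edge (unlikely to be whole worms), fills
interior holes, and applies a 3×3 majority filter iterated to a fixed
point; the whole pass is itself iterated to a fixed point, which makes
`clean_mask` idempotent by construction.  Connectivity is 8-connected
everywhere, and worm numbering follows bounding-box origin scan order
(row, then column) so repeated runs join reproducibly.

The size gate keeps components whose area lies within `area_range`
(default 0.3–3.0) times the **median** component area of the same image.
The median anchor makes the gate self-calibrating per plate without an
absolute size prior.

Crops are padded by one background pixel, other worms' pixels are zeroed
out of each crop's mask, and bounding boxes are 0-based, half-open,
row-major.

## Morphometry

The midline is obtained by morphological thinning.  If the skeleton has
branch points, a 15×15 median filter is applied to a *temporary copy* of
the mask and the copy re-thinned, up to five attempts; the original mask
is never modified, so area and width measurements are unaffected.  A
skeleton is *continuous* when it has exactly two endpoints and no branch
points — a self-touching (looped) worm thins to a cycle and is therefore
never continuous, surfacing through the QC flags rather than a dedicated
geometric test.

* **Area** = foreground pixel count × pixel area.  (MATLAB's `bwarea`
  weighted count is a known variant; the raw count was chosen because it
  makes thickness × length ≡ area an exact identity.)
* **Length** = skeleton pixel count × pixel pitch.  The pixel-count
  metric undercounts diagonal runs by up to √2; an optional Euclidean
  variant sums chain distances along a 5-point moving-average-smoothed
  path (the smoothing removes thinning staircase jitter, which would
  otherwise inflate the chain length by ~7 %).
* **Cross-sections**: the local tangent is the principal axis of the
  skeleton pixels within ±5 arc steps (robust to skeleton jaggedness,
  including vertical runs); the normal is walked in both directions at
  0.25 px steps with nearest-pixel lookup, and the width is the total
  traversed distance, which spans the half-pixel boundaries of the
  outermost mask pixels.
* **Midwidth** = cross-section at the arc midpoint × pixel pitch.
* **End diameter profile**: D1 is the widest cross-section between 10 px
  and 10 % of the length from the end; if the argmax sits exactly on the
  10 % boundary (a still-thickening profile) D1 is re-read at 2.5 % of
  the length.  D2 is the narrowest cross-section from 20 px past D1's
  location to 20 % of the length.  The 10/20-px offsets are absolute
  (resolution-dependent) and configurable; worms whose skeleton is too
  short for the windows are flagged rather than measured.  The ratio
  D1/D2 exceeds 1 only for bulb-then-taper (male-like) tail ends.
* **Head/tail assignment** combines two cues as a weighted two-vote
  score: the brighter end votes head (weight ∝ normalized brightness
  difference), and the end with the larger D1/D2 votes tail.  The
  diameter vote weighs the *excess of each ratio above 1*: for two
  smooth ends both excesses are ~0 and the vote abstains, because ratio
  differences between smooth ends are measurement noise and would
  otherwise outvote the genuine brightness cue (and bias against
  hermaphrodite tails, whose ends are both smooth).  Ties fall back to
  brightness, then deterministically to end A.  End brightness is the
  mean raw bright-field intensity over mask pixels within 10 px
  (configurable) of the end pixel.

A Sobel edge map is computed and stored with each crop for visual parity
with common viewers; no feature depends on it.

## Fluorescence

Peak detection: a candidate pixel must reach `threshold_frac` of the crop
maximum and match the maximum of its `neighborhood` square (plateau tops
qualify); candidates outside the worm mask are discarded, and greedy
suppression in descending intensity order (ties by row, then column)
enforces one peak per neighborhood square.  The threshold is relative to
the per-crop maximum; a plate-level reference is available by
configuration.

Background is estimated per crop as the mean intensity of non-mask
pixels — the only background available after cropping, and robust to
plate-level illumination gradients.  With area `A`:

    CTWF = (mean_worm − mean_bg) · A
    RID  = sum_worm − mean_bg · A

These are algebraically identical when computed over the same region and
background; both are reported, positive for worms brighter than their
background, and the identity is asserted in the tests to 1e-9 relative
tolerance.

Puncta are the connected components of `fl ≥ threshold_frac × max(worm)`
inside the mask that contain at least one accepted peak; per-punctum
pixel areas and the mean size as a percentage of worm area are reported
(log transformation is left to the analysis layer).

## Quality control

Within a batch, area and length are standardized (sample SD); |z| > 1.5
flags a worm for review.  More than two debranching attempts, or a
skeleton still branched/looped after five, also flag.  Batches smaller
than three worms get no outlier flags (z-scores are meaningless) and a
logged warning.  Flags never alter feature values; filtering happens only
at export with `--drop-flagged`, and the run summary reports the
fraction of objects surviving QC.

### WormNet

The mask classifier is a small convolutional network implemented directly
in NumPy: three 3×3 convolution blocks (16/32/64 filters by default, each
with batch normalization, ReLU and 2×2 max pooling) and a fully connected
two-way softmax head.  The scaled-down corpus used by the tests and the
acceptance script runs a lighter 8/16/32 stack, which trains four times
faster and generalizes equally well at that corpus size.  Masks are centred on a zero canvas sized at the
65th percentile of the training batch's mask sizes (per axis; larger
masks are cropped centrally), rescaled to the fixed 64×128 input and
re-binarized at 0.5; the pad size is stored with the model so later
classification preprocesses identically.

Training uses stochastic gradient descent with momentum 0.9, L2
regularization 1e-4, mini-batch 256, learning rate 0.005, reshuffling
every epoch, with an 85/15 stratified split.  Because the synthetic
corpus used here (1,000 masks) is small, the training split is augmented
with horizontal and vertical mirror copies — mirrored masks are equally
valid or faulty — and 14 epochs suffice on that corpus; the default of
50 epochs matches the recipe for larger corpora.  All hyperparameters
and the layer plan are configuration, so users can retrain on their own
labelled masks.  The repository ships no trained weights (they are a
binary artifact); `nemaphen qc --train` reproduces the model from the
synthetic corpus in minutes.

A global-average-pooling head variant is available
(`NetSpec(global_pool=True)`) but is not the default: with the fixed
learning rate of 0.005 it converges far too slowly to be useful.

## Analysis layer

The SVM route standardizes features (fit on training rows only — test
rows never touch the scaler or the fit), cross-validates on the training
split and reports held-out accuracy plus per-class true-positive rates.
Rows with missing selected features are dropped, not imputed, consistent
with the review-then-exclude QC workflow.

PCA scoring optionally unit-variance scales the features (constant
features are dropped with a warning) and fixes each component's sign so
its first-feature loading is non-negative; the PC1 coordinate is the
continuous phenotype score, with `--flip-score` to negate it.  t-SNE
embeds after a PCA pre-reduction retaining components covering ≥ 95 % of
variance (capped at 10); rows must exceed 3 × perplexity.

The learning-curve harness draws a fixed held-out test set (100 rows per
class) first, then for each training size fits on random subsets over 10
seeds and reports the median accuracy on that same test set.

## Synthetic data: what it does and does not emulate

Worms are rendered by sweeping a disk of radius w(s)/2 along a random
smooth midline (bounded-curvature random walk, self-contact rejected),
which gives analytic oracles: arc length, width profile, head position,
puncta locations.  Two parameter poles encode sexual dimorphism —
hermaphrodite-like (340 px long, 14 px wide, centre bulge, smooth
tapers, brighter head) and male-like (270 px, 11 px, bulb-then-sharp-
taper tail, darker tail) — and a coefficient λ ∈ [0, 1] interpolates all
parameters for intersex phenotypes.  Worm lengths were chosen so the
absolute 10/20-px diameter windows exist for every class (skeletons
must exceed ~200 px), mirroring how real adults span many hundreds of
pixels at these magnifications.  The default plate (20 worms on a
1000×1000 background at level 0.90, worms at ~0.35, noise σ 0.012)
lands the contrast statistic inside the accepted 0.06–0.15 band.

Bright-field head-vs-tail brightness is painted explicitly as a linear
gradient along the body; real optics (depth, translucency, diffraction)
are not simulated.  Fluorescence channels are flat in-worm baselines
times a per-condition scale factor plus well-separated Gaussian puncta
over a dim background; no bleaching, spectral overlap or 3-D structure.
Faulty objects for QC training are self-touching loops, compact ellipse
blobs, crossing (merged) worm pairs and fragmented worms.

Passing tests on this generator therefore demonstrates the correctness
of the measurement and analysis machinery against known truth — not
robustness to focus drift, uneven illumination, touching worms or
debris morphologies beyond the modelled ones.  The statistical fixtures
for the analysis layer are Gaussian feature tables with a known pooled-SD
class separation (Bayes error in closed form), used where image content
is irrelevant: a 4-SD fixture for classifier recovery, a 0-SD fixture
for the chance-level control, and a deliberately data-limited fixture
(64 weak features, 3-SD total separation) for the learning curve so the
curve is still rising at every grid point instead of sitting on a
saturated plateau where median noise would mask the trend.

## Numerical conventions and degenerate inputs

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical plates, tables and models.
* Missing features are NaN/empty CSV fields, never silent zeros.
* Empty masks, single-class training labels, over-large thresholding
  neighborhoods, perplexities beyond n/3 and mask-filled crops raise
  validation errors with actionable messages.
* z-scores use the sample standard deviation (ddof = 1); peak-intensity
  SD uses the population convention and is 0 for a single peak.
* The problem sizes used by the test suite and the acceptance script
  (20-worm plates, 1,000-mask QC corpus, 14 training epochs, 280-worm
  gradient populations) were chosen as the smallest sizes at which each
  property is statistically stable.

## Known limitations

* Touching or overlapping worms are excluded/flagged, not untangled.
* The pixel-count length metric undercounts diagonally oriented worms;
  use the Euclidean option when absolute lengths matter.
* Per-crop background estimation biases CTWF slightly if a neighbouring
  worm's fluorescence bleeds into the crop margin.
* The shipped QC classifier quality depends on the synthetic corpus;
  real deployments should retrain on their own reviewed masks.
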