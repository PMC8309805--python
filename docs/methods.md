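# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not show.

## Phantom model

A phantom is `background + spots + noise`, clipped to [0, 1].

**Background.** Parenchymal texture is modeled as white noise smoothed by a
Gaussian kernel (`texture_scale_mm`, default 2 mm) and rescaled to a fixed
standard deviation (`texture_amplitude`, default 0.04) around
`background_level` (default 0.35). A flat background would make detection
trivial; a smoothed noise field gives the detector and classifier a
low-frequency structure to reject. It does not reproduce the anatomy of
real parenchyma (ducts, vessels, pectoral muscle, skin line) — see
Limitations.

**Spots.** Each microcalcification is a radially decaying bright disk: a
Gaussian profile whose full width at half maximum equals the nominal
diameter, truncated at the nominal radius (so the support is exactly one
diameter wide and the edge value is half the peak). Peak amplitude is
`spot_contrast` (default 0.5 of dynamic range). Diameters are drawn
uniformly from `diameter_range_mm`, default 0.2–0.5 mm within the
physiological 0.1–0.7 mm span; specs whose smallest spot radius falls
below half a pixel are rejected as sub-resolution. Overlapping profiles
combine by maximum, so every annotated center remains a local maximum on
noise-free renders.

**Archetypes.** The four clinical spot arrangements are parameterized as:
clustered = uniform in a disk of radius 5 mm; segmental = uniform along a
random 15 mm segment with 0.5 mm jitter; regional = uniform in a 20 mm
disk (clamped to the field); diffuse = uniform over the whole field.
Centers are drawn with a minimum separation of 1 mm by rejection sampling
and rounded to the pixel grid. The class label is a pure function of the
archetype: clustered/segmental → malignant, regional/diffuse/none →
benign. Generated cohorts cycle benign images through regional/diffuse and
malignant ones through clustered/segmental, so both classes contain spots
and differ only in arrangement; per-image seeds and spot counts
(uniform within ±4 of the base count, floor 3) derive deterministically
from the dataset seed.

## Preprocessing

Images are floating point on [0, 1] in memory; PNG I/O is at 8 or 16 bit.
DICOM ingestion preserves the stored integer pixel array exactly (no
window/level) and appends the patient header to a cumulative CSV; only
monochrome photometric interpretations are accepted. Resizing is bilinear
with half-pixel sample centers. The resize goes directly to the target
frame without padding, even when the aspect ratio changes. The weighted
grayscale conversion defaults to the BT.601 luma weights
(0.299, 0.587, 0.114), overridable; the summation order is fixed
(r, then g, then b) so results are bit-reproducible.

## Augmentation

Offline inflation produces, per source image: the original plus rotations
by 45°, 90°, 180° and 360°. The 360° copy duplicates the original and is
kept deliberately so one source yields exactly five outputs. Rotation
expands the canvas to the rotated bounding box (no corner cropping,
background fill 0, bilinear interpolation, positive = counterclockwise as
displayed) and resizes back to the target frame. Flips exist but are off
by default offline; the on-the-fly trainer augmentation (rotation ≤ 20°,
shift/shear ≤ 10%, flips) is available behind a flag and off by default.

## Candidate detection

The detector is classical: white top-hat with a disk structuring element
of radius 0.45 mm (slightly larger than the largest 0.7 mm MC, so whole
spots survive), a relative threshold at mean + 3·sd of the filtered image
(`k_sigma` configurable), 8-connected component labeling, and the
equivalent-circle diameter in mm via the pixel spacing. Candidates outside
0.1–0.5 mm are discarded: larger deposits are coarse calcifications, not
MC targets. On noise-free phantoms with spots inside the window the
detector attains full recall with centroids within 1 px and diameters
within 1 px-equivalent; diameters measured near the upper window edge can
exceed it by the ~half-pixel discretization bias, so spots at exactly
0.5 mm may be filtered — the filter is applied literally.

## Networks and training engine

Both architectures are three pooled blocks of 3×3 stride-1 same-padded
convolutions (filters 32 | 64, 64 | 128, 128, 128, each followed by batch
normalization, ReLU activations, 2×2 max-pooling after each block), then
flatten, dropout 0.5, a 256-unit dense layer and a 2-way softmax. The
FC-DSCNN uses depthwise-separable convolutions (depthwise 3×3 per channel,
pointwise 1×1 mixing; `9C + CF` weights), the DCNN standard `9CF`
convolutions — identical shape traces, ~8× fewer convolutional parameters
for the separable stage at full size.

The engine is plain float64 NumPy with analytic backpropagation,
verified against central differences in the tests. Numerical choices:

- He-initialized weights (per-stage fan-in for the separable layers);
  zero biases.
- Batch normalization: epsilon 1e-3, EMA momentum 0.9 for running
  statistics, which are seeded from the first training batch — with the
  short runs used here an EMA started at (0, 1) would still be biased
  toward its initialization at evaluation time.
- Max-pooling floor-divides spatial dims (odd trailing rows/columns are
  dropped); tied maxima share the gradient equally.
- Dropout is inverted (train-time scaling), identity at inference.
- The softmax is fused into the loss (log-sum-exp stabilized); the loss is
  sparse categorical cross-entropy over integer labels with optional
  per-sample weights.
- AdaGrad in its classic form: zero-initialized squared-gradient
  accumulator, update `w -= lr · g / (sqrt(acc) + 1e-7)`.

Training defaults follow the study configuration: batch 32, learning rate
0.001 decayed ×0.1 every 5 epochs, 20 epochs, dropout 0.5, seed 42,
stratified 60/20/20 split (5-fold CV available; the protocol ambiguity
between the two is left to the caller). The published "class weight
[−1, 1]" setting is not interpretable as literal loss weights; the
effective policy is inverse-frequency class weighting normalized to mean 1,
which is what a loss-based imbalance correction does. Non-finite losses
abort with the epoch index.

## Metrics

Malignant (label 1) is the positive class. Sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/total, precision TP/(TP+FP),
F1 harmonic mean, FPi = FP/N with N the number of evaluated images
(imagewise, not ROI-wise). Recall shares the sensitivity formula and is
reported as the same number. AUC is the trapezoidal area under the ROC
built by sweeping the threshold over unique scores; tied scores collapse
into one ROC step, which equals the Mann–Whitney pair count with half
credit for ties (asserted to 1e-12 in tests, and cross-checked against
scikit-learn). Individual metric functions raise an explicit
undefined-metric error on zero denominators; the aggregate report records
NaN for undefined columns instead of silently zeroing them.

## Scaled-down experiment

Full-size training (240×320 inputs, thousands of images) is out of desk
range, so the end-to-end experiment runs a 24×32-input variant of the
FC-DSCNN (flatten length 1536) on 400 phantoms, stratified 60/20/20,
20 epochs — about a minute on one CPU.

Phantoms for this experiment are rendered directly on the 24×32 network
grid at 0.7 mm/px (a 17×22 mm field) with 0.7 mm spots, i.e. each MC is
about one pixel. Rendering at the working resolution is deliberate: at
this miniature scale any resampling smears one-pixel specks into the
background texture and erases the arrangement cue (anti-aliased
downsampling of higher-resolution renders was measurably
uninformative), whereas the clinical-scale pipeline keeps rendering and
classification resolutions separate. Under these conditions the network
separates the malignant (clustered/segmental) from benign
(regional/diffuse) arrangements with validation sensitivity ≈ 1.0 and
AUC ≈ 0.99 at seed 42 (sensitivity 0.88–1.0 across other seeds), and the
tests assert ≥ 0.9 for both.

## What the synthetic experiments do not show

- Phantoms contain no masses, architectural distortion, anatomy, or
  scanner physics; passing tests demonstrate the pipeline's mechanics and
  the networks' capacity to learn spot-arrangement classes, not clinical
  performance on real mammograms.
- The spot model is rotationally symmetric with a fixed profile; real MC
  morphology (pleomorphism, branching) is absent, so morphology-driven
  discrimination is untested.
- The scaled-down input (24×32) and cohort (400 images) are far below the
  full-size configuration; absolute metric values do not transfer.

## Known limitations

- The detector assumes bright-on-dark MCs and a single pixel spacing per
  image; anisotropic spacing is unsupported.
- Candidate diameters are biased upward by about half a pixel near the
  filter's upper edge (see above).
- The training engine is single-threaded NumPy: adequate at the scaled
  input, impractical at 240×320.
- `resize_image` rescales the physical pixel spacing by the width ratio
  only; anisotropic resizes lose exact physical calibration.
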