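# Methods

## Overview

`croppainter` implements trait-to-image crop visualization: given a
vector of phenotypic traits measured on a segmented plant image, a
conditional generative adversarial network synthesizes a plant image
whose own measured traits match the input. The package covers the full
loop — trait extraction, dataset preparation, adversarial training,
generation, and evaluation of both visual fidelity and trait-prediction
accuracy — plus a procedural silhouette generator that supplies seeded
training data at desk scale.

## Phenotypic traits

Eighteen traits describe one plant silhouette (RGB image + binary
foreground mask):

* **Texture** (intensity histogram of the grayscale foreground,
  rescaled to [0, 1]): mean `M`, standard deviation `SE`, smoothness
  `S = 1 − 1/(1+σ²)`, third central moment `MU3`, uniformity
  `U = Σp²`, entropy `E = −Σ p log₂ p` (bits). The histogram uses 256
  equal-width bins; each occupied bin is represented by the mean of
  the intensities assigned to it, so `M` equals the exact pixel mean
  and `SE` is within one bin width of the exact standard deviation.
  Statistics are computed over foreground pixels only — on a black
  background the whole-canvas histogram would be dominated by the
  background spike.
* **Morphology**: projected area `TPA` (pixel count), bounding
  rectangle height `H` and width `W`, box area `CBA = H·W`, box ratio
  `TBR = TPA/CBA`, hull ratio `THR = TPA/hull area` (hull area is the
  pixel count of the filled convex hull), perimeter `P` (foreground
  pixels with a 4-connected background neighbour; the image border
  counts as background), `PAR = P/TPA`, and the box-counting fractal
  dimension `FDIC`: the mask is cropped to its bounding box, padded to
  the next power-of-two square, and `FDIC` is the least-squares slope
  of `log N(s)` against `log(1/s)` over box sizes `s = 1, 2, 4, …,
  side/2`. A bounding box smaller than 4 px yields `FDIC = 0` by
  convention (the fit is degenerate).
* **Color**: green projected area `GPA` (foreground pixels with hue in
  [60°, 180°)), yellow projected area `YPA` (hue in [20°, 60°)), both
  requiring HSV saturation and value ≥ 0.15, and `YTR =
  TPA/max(YPA, 1)`. Hue windows are half-open so boundary hues are
  unambiguous; the `max(YPA, 1)` guard keeps `YTR` finite for crops
  with no yellow tissue. The saturation/value floors and windows are
  configurable; the defaults were fixed before any model training and
  are part of this package's trait contract.

Two schemas exist: the full 18-trait schema, and a 16-trait schema
that drops `YPA`/`YTR` for crops whose images contain essentially no
yellow (e.g. whole rice or maize plants at the seedling stage). The
trait order is fixed and serialized with every dataset and checkpoint.

## Dataset preparation

Each plant is cropped to the minimal bounding rectangle of its mask
and centered (floor offsets, for determinism) on a square canvas of
side `M` = the dataset-wide maximum bounding-box side, then resized to
the model resolution (bilinear for RGB, nearest for the mask so it
stays binary). Traits are extracted **after** the resize, so trait
scales are consistent with the pixels the model sees at any
resolution; this also makes trait↔image consistency directly testable.
The train/test split is a seeded uniform shuffle. Trait conditioning
uses min-max normalization to [0, 1] fitted on the training split
only; test-time values are clamped into [0, 1] so unseen extremes
cannot leave the trained condition domain, and a constant trait maps
to 0.

## Model

The generator is a tree of up to three stages emitting images at 64,
128 and 256 px. Stage 1 concatenates a Gaussian noise vector `z` with
the normalized trait vector `c`, applies a fully connected block
(linear + batchnorm + ReLU) to a 4×4 feature map, then four upsampling
blocks (nearest 2× upsample + 3×3 conv + batchnorm + ReLU) to the
hidden feature `h₁` at 64×64, and a 3×3 conv + tanh head for the stage
image. Stage k > 1 tiles `c` spatially, concatenates it with `h_{k−1}`
along channels, and applies a joint conv + batchnorm block, two
residual blocks, and one upsampling block to produce `h_k` and its
image at doubled resolution. Channel widths halve per upsampling, from
`8·base_channels` at 4×4.

The condition enters by plain channel concatenation — there is no
stochastic re-embedding of the condition vector, so the traits reach
the generator unperturbed. `z` models the many-images-per-trait-vector
ambiguity; `z_dim = 0` is allowed and yields a deterministic
trait-to-image mapping.

Each stage's discriminator downsamples with stride-2 4×4 convolutions
(LeakyReLU 0.2; batchnorm except on the first block) to a 4×4 map and
emits two logits: an unconditional real/fake score, and a conditional
trait-match score from the map concatenated with the tiled condition.
The discriminator loss per stage is binary cross-entropy:
uncond(real→1, fake→0) + cond(real,c→1; fake,c→0) plus a
mismatched-pair term (real image, wrong traits → 0) with weight
`w_mis` (default 1) — without negatives the trait-match head would be
untrainable. The generator loss per stage is uncond(fake→1) +
cond(fake,c→1).

Training uses Adam with lr 2e-4, β₁ 0.5, β₂ 0.999, ε 1e-8,
alternating one discriminator step over all stages and one generator
step per batch. All computation runs on a compact NumPy
neural-network backend (`croppainter.nn`): im2col convolutions with
hand-written backward passes, verified against finite differences in
the test suite. Batch-norm uses batch statistics in training and
running averages at generation time.

## Synthetic plants

The procedural renderer draws a vertical stem with alternating side
branches, two levels deep, as raster strokes without anti-aliasing:
the mask is exactly binary, equals the set of non-black pixels, and
pixel counts are integer-exact. Each segment is colored green
(hue ≈ 120°) or yellow (hue ≈ 40°) by a per-segment Bernoulli draw
with probability `yellow_fraction`, with uniform hue jitter and
saturation/value well above the color-trait floors. Default sampling
ranges (canvas 96 px; 2–9 branches; stem height 0.45–0.95 of the
canvas; stroke width 1–3 px; branch length 0.2–0.5; yellow fraction
0–0.5; hue jitter up to 12°) were chosen so that a 100-image dataset
varies every one of the 18 traits, keeping min-max normalization
well-posed.

What the generator does **not** emulate: photographic texture,
lighting, occlusion, soil/background clutter, species-specific
morphology, and segmentation error. Passing tests on this data shows
the pipeline's machinery is correct and that conditional learning
works at desk scale; it does not certify accuracy on real
phenotyping-platform images.

## Evaluation

* **SSIM** in its global-statistics form — one mean, variance and
  covariance per image pair (channel-averaged grayscale), constants
  `c₁ = (0.01·255)²`, `c₂ = (0.03·255)²`. A sliding-window variant is
  deliberately not the default; the global form is the package's
  reference formula.
* **FID**: `|μ_a − μ_b|² + tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2})` between
  Gaussian fits of image features. The matrix square root uses
  symmetric eigendecomposition with negative eigenvalues (numerical
  noise) clipped at zero. The feature extractor is pluggable; the
  default "pixel" extractor (8×8 area-averaged grayscale, 64
  features) is deterministic and dependency-free, so FID values are
  comparable only within one extractor — they are not on the scale of
  FIDs computed with a pretrained deep embedding.
* **Trait prediction accuracy**: traits are re-extracted from each
  generated image and compared with the input traits — per-trait
  Pearson correlation over the test set, and per-image cosine
  similarity. Cosine similarity is computed on min-max-normalized
  traits: raw traits span four orders of magnitude (areas vs ratios),
  which would pin the raw cosine near 1 regardless of quality.
* **Virtual-image segmentation**: generated images have no ground-truth
  mask, so the mask is recovered by thresholding (any channel >
  10/255) followed by removal of connected components smaller than
  16 px. GAN outputs carry isolated near-black speckle that
  contributes negligible area but, left in place, saturates the
  bounding-box traits (H, W, CBA) at the full canvas. The 16-px floor
  is far below the footprint of any real plant part at 64 px
  resolution. Trait rows whose recovered mask is empty are excluded
  from the correlation and cosine summaries.

## Desk-scale defaults and problem sizes

The package's own experiments (test suite and the acceptance script)
run a single-stage 64×64 model with `base_channels` 8 and `z_dim` 8 on
500 synthetic plants for 60 epochs, batch 16 — sizes chosen so a full
train-and-evaluate cycle completes in minutes on one CPU core while
still demonstrating conditional learning (size-trait correlations well
above chance). The full-scale preset (three stages to 256 px,
`base_channels` 32, `z_dim` 100, 600 epochs) uses the same code paths.

## Numerical choices and degenerate inputs

* Histogram statistics: empty foreground is an error; intensities
  outside [0, 1] are an error (the extractor clips the grayscale
  conversion before calling).
* `FDIC`: bounding boxes smaller than 4 px (after power-of-two
  padding) return 0 rather than fitting a slope through fewer than
  two points.
* Min-max normalization: `max = min` maps to 0; inverse transform is
  exact on in-range values to 1e-9.
* FID: covariance eigenvalues below zero are clipped; the sqrt of a
  rank-deficient covariance amplifies float noise, so equality
  assertions on FID use relative, not absolute, tolerance.
* Training aborts with a diagnostic on non-finite losses; the loss
  log records every batch.
* Determinism: every random choice (rendering, splitting, weight
  initialization, noise, batch order) flows from an explicit seed;
  reruns are bit-identical on the same platform and BLAS.

## Known limitations

* Maximum output resolution is 256×256 (three stages).
* The desk-scale GAN demonstrates coarse conditional control (size
  and area traits); faithful reproduction of all 18 traits requires
  datasets and training budgets far beyond desk scale.
* Adversarial training at this scale has high run-to-run variance:
  across training seeds the mean size-trait correlation of a
  desk-preset run can range from roughly 0.35 to 0.6. The packaged
  experiments therefore fix every seed; conclusions about real data
  should be drawn from paper-scale runs, not the desk preset.
* Absolute FID values from the pixel extractor are not comparable to
  published FIDs based on pretrained deep features.
* Segmentation of real photographs is out of scope; masks are inputs.
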