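# Methods

## The model

The network is a 15-layer hierarchical convolutional network (HCNN) that
mimics the ventral visual stream: a feature-extraction stack of 8
convolutional layers interleaved with 5 non-overlapping 2×2 max-pooling
layers, then a classification head (global average pooling over the final
768 feature maps, a fully connected layer, softmax over 1000 categories).
The layer table is

| layer | type | maps | spatial | kernel |
|---|---|---|---|---|
| 0 | input | 3 | 224 | – |
| 1 | conv | 32 | 224 | 9 |
| 2 | max-pool | 32 | 224 | 2 |
| 3 | conv | 48 | 112 | 9 |
| 4 | max-pool | 48 | 112 | 2 |
| 5 | conv | 96 | 56 | 7 |
| 6 | max-pool | 96 | 56 | 2 |
| 7 | conv | 192 | 28 | 5 |
| 8 | max-pool | 192 | 28 | 2 |
| 9 | conv | 384 | 14 | 5 |
| 10 | max-pool | 384 | 14 | 2 |
| 11–13 | conv | 768 | 7 | 5 |
| 14 | global avg-pool | 768 | 7 | 7 |
| 15 | softmax | 1000 | 1 | 1 |

Spatial sizes are listed at each layer's input; convolutions use stride 1
with zero padding that preserves spatial size (the only reading under which
the chain telescopes 224→112→56→28→14→7 and the final feature layer holds
768·7·7 = 37,632 units).  Each convolutional stage applies convolution
(with bias) → batch normalization → rectification f(x) = max(x, 0).
Weights and biases are Xavier-uniform / fan-based uniform initialized from
a seed; two builds from the same seed are bit-identical.

**Lateral inhibition.**  Local response normalization

  b^i_{x,y} = a^i_{x,y} / (k + α·Σ_j max(0, a^j_{x,y})²)^β,

with the sum over feature maps j = max(0, i−n/2) … min(N−1, i+n/2) and
constants k = 2, α = 10⁻⁴, β = 0.75, n = 15, models competition between
units sharing a receptive field.  Two choices here were genuinely open:

* The displayed formula omits the exponent on the denominator; we apply
  `denominator^β`, following the formulation the constants come from.
* *Placement.*  The constants originate from the AlexNet architecture,
  which normalizes only its first two convolutional stages, and that is the
  default here (`lrn_layers=(1, 3)`).  Applying the constant-k divisive
  step after all 8 stages damps activations by ≈1.68× per stage, so deep-
  layer stimulus signal drowns under the bias terms of an untrained network
  and the untrained selectivity statistics leave the regime reported for
  this class of models (we measured ~2% selective with all-stage LRN under
  evaluation-mode normalization versus ~17% with first-two-stage LRN).
  The placement is configurable per layer.

**Batch normalization.**  Evaluation mode (stored running statistics) is
used during all stimulus presentation.  For an untrained network the
freshly initialized statistics make BN the identity; responses to blank
displays are then nonzero through the convolution biases.
`calibrate_batch_norm` optionally estimates per-map statistics from a
stimulus sample (streamed layer-by-layer) for ensemble standardization;
training mode uses batch statistics and updates running estimates with
momentum 0.1 (ε = 10⁻⁵), common defaults the protocol leaves unspecified.

**Response noise.**  Multiplicative Gaussian noise (μ = 1, σ = 0.15) is
drawn independently per unit and per presentation and applied to every
convolutional stage's output, then clipped at zero.  It makes the
deterministic network's response to the constant empty-set display vary
across presentations; it is never applied during training.

**Training.**  The object-recognition pathway (cross-entropy, mini-batch
SGD with momentum; defaults epochs = 10, batch = 256, lr = 0.1,
momentum = 0.9) is implemented with analytic backpropagation through every
stage (conv, batch norm, ReLU, LRN, max-pool, average-pool, softmax) and is
verified against central finite differences in the test suite.  Training to
the reference ImageNet accuracy is a GPU-scale undertaking and is outside
the desk-scale analyses, all of which run on untrained networks.

All forward computation is NumPy: convolutions run as im2col + BLAS matrix
products, or — for layers with spatial maps ≥ 56 px — as real-FFT products
with cached kernel spectra (equal to the direct path within float32
rounding; verified in tests).  A full 600-stimulus presentation of the
224×224 network takes ≈2.5 min on one CPU core.

## Stimuli

600 grayscale 224×224 images per screen: numerosities 0–4 × 3 sets × 40
images.  Items are bright on a dark background, rendered by analytic
per-pixel inclusion tests (no anti-aliasing), placed fully inside the image
with ≥ 2 px between item boundaries, so 8-connected component counting
recovers the numerosity exactly.  An audit oracle re-measures every
constraint from the rendered pixels.

* **standard** — discs with radii drawn from U(12, 24) px; the *average*
  radius (18 px) is constant across numerosities while single dots vary.
* **control1** — total item area fixed at 1200 px² (per-dot areas are
  random shares, factors U(0.7, 1.3) normalized; disc radii are calibrated
  so the rasterized pixel count meets each dot's target); mean pairwise
  center distance held in [90, 100] px (density control); image-mean
  luminance held at 0.20 for *every* numerosity, including 0, by raising
  the uniform background (≈0.18 with 1200 px² of foreground; exactly 0.20
  for the empty display).  A luminance step at numerosity 0 would leak a
  zero-vs-nonzero cue inside the very set meant to equate luminance, so
  the raised background applies to the empty display too.
* **control2** — shapes drawn uniformly from {circle, rectangle, ellipse,
  triangle}, each area-matched to a disc with radius drawn as in the
  standard set; for numerosity > 2 the convex hull of item centers is a
  triangle (3 items at the vertices of a random non-degenerate triangle,
  any further items strictly inside it).

Numerosity 0 is an item-free image of the set's background.  Rejection
sampling is capped at 10,000 attempts; for reduced image sizes (test
variants) all geometric constants scale with size/224.  What the generator
does *not* emulate: natural-image backgrounds, color, occlusion, or
luminance gradients — conclusions from these displays concern the
abstract-numerosity regime the controls define, not natural scenes.

## Selectivity screen

A unit is numerosity selective when a balanced two-factor fixed-effects
ANOVA (numerosity × stimulus set, with interaction) on its 600 responses
gives p < 0.01 for the numerosity main effect and p ≥ 0.01 for both the set
effect and the interaction.  Constant-response (dead-ReLU) units have an
undefined F and are excluded from the ANOVA but retained in the 37,632-unit
denominator.  Tuning curves are mean responses per numerosity (per set and
pooled); preferred numerosity is the pooled argmax with ties broken toward
the smaller numerosity; normalized curves are min-max scaled per unit.
Population curves normalize per unit first, then average within
preferred-numerosity groups (the alternative order is available behind a
switch).

The untrained repetition study repeats — with fresh weights, fresh
stimuli, fresh noise per repetition — and reports across-repetition means
and standard errors of the selective fraction, the zero-preferring share,
the preferred-numerosity histogram, and the response variability.

**Response variability** is the average standard error of normalized
responses: each unit's single-presentation responses are normalized by its
pooled tuning-curve range, the standard error over the 40 presentations of
each (numerosity, set) cell is taken, and values are averaged over cells
and units.  Across-unit definitions (SD or SEM of normalized curves within
preferred-numerosity groups) cannot reproduce the magnitude this statistic
is reported at for untrained networks — with thousands of units per group
the across-unit SEM is < 0.01 — so the per-unit trial-wise reading is
used; `group_curve_spread` exposes the across-unit spread separately.

## Tuning characterization

Gaussian fits (amplitude, center, width, baseline) are least-squares with
deterministic initialization (amplitude = range, center = argmax, width =
half the axis span, baseline = min) and bounded center/width (center within
one span of the sampled range, width in [0.05, 10] spans) because monotone
curves otherwise drive the optimizer down an unbounded center–width ridge.
r² = 1 − SS_res/SS_tot on the fitted axis; non-convergent fits carry an
r² = −∞ sentinel and are dropped pairwise from comparisons.  The
logarithmic axis is x' = log₂(x+1), which keeps numerosity 0 at a finite
position and compresses spacing with magnitude; the transform is
configurable since the convention for plotting 0 on a log axis is not
standardized.  Wilcoxon signed-rank tests are two-sided, exact for n ≤ 25,
normal approximation otherwise; identical paired samples return p = 1.

## Behavioral decoding

*Matching*: per trial, two freshly generated displays; features are the
concatenation sample‖test of the selective units' noisy responses; classes
(same/different) are balanced 50/50 with numerosity pairs uniform over the
grid.  The classifier is an SVM with RBF kernel and C = 1: same/different
over a concatenated population code is a similarity judgment that a linear
separator cannot express (a planted one-hot code caps near 60% with a
linear kernel), so the maximum-margin family's standard nonlinear kernel
is used.  Performance tuning functions tabulate P("same") per
(sample, test) numerosity over the test trials, aggregated over
repetitions (default 50) of data generation, training and testing.

*Categorization*: a linear one-vs-one multi-class SVM labels single
displays with their numerosity from selective-unit activity, trained on
half the correct-trial images and tested on the held-out half or on
error-trial images.  *Silencing* zeroes the designated units' activity at
test time only; conditions are intact, all zero-tuned units, an equal
number of random nonzero-tuned units, and all units tuned to a given
countable numerosity, compared by paired Wilcoxon tests on per-class
true-positive rates across random-split repetitions.

## Problem sizes and reproducibility

The untrained-network statistics are computed at 3 repetitions (the
reference protocol used 100) with the full 600-stimulus screen per
repetition; behavioral smoke runs use the reduced architecture and small
trial counts, with the full-scale parameters as configuration defaults.
Every random stage (weights, stimuli, noise, trials, classifier splits) is
seeded from one global seed via `numpy.random.SeedSequence` spawning, so
any results bundle is regenerable from its embedded config; identical
seeds give bit-identical activation matrices on one platform.

## Known limitations

* The trained-network results (10.47% selective, 20% zero-preferring, 80%
  matching accuracy, and the trained-regime correlations) require ImageNet
  training and are not desk-reproducible; the training pathway exists and
  is tested on small fixtures only.
* Under this reimplementation the untrained zero-preferring share
  stabilizes near 20–25% and the response variability near 0.23–0.24,
  below the reference values (32.6%, 0.35).  Both statistics are sensitive
  to implementation details the protocol leaves open (normalization
  handling, LRN placement, bias initialization); the configurations we
  explored move them jointly with the selective fraction, and the default
  configuration is the one that reproduces the selective fraction
  (~15–17%) and the extremity-skewed histogram.
* The ANOVA assumes homoscedastic, roughly normal responses; rectified,
  noise-multiplied activations violate this mildly.  The same screen is
  standard for real neurons, and the planted-code tests bound its practical
  error-rate behavior.
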