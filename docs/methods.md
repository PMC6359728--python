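# Methods

## Model and assumptions

`spraymsm` classifies sets of aerial image frames into spray / non-spray
categories with the mutual subspace method. The underlying assumption is
that the appearance of one ground category, after reduction to a 64-element
pattern vector, occupies (approximately) a low-dimensional linear subspace
of ℝ⁶⁴, and that different categories occupy measurably different
subspaces. This holds when within-class variation is dominated by smooth
appearance changes (noise, small viewpoint drift) around a stable class
appearance; it degrades under strong nonlinear variation (large viewpoint
changes, mixed canopies, illumination swings), which is the method's main
practical limitation.

Class subspaces are fitted by eigen-decomposition of the **uncentered**
autocorrelation matrix C = (1/n) Σ xxᵀ (the classic CLAFIC convention).
Mean-centering before the decomposition is available via `centered=True`
and is recorded in fitted models; the two conventions give different
subspaces (the uncentered one always contains a direction close to the mean
pattern) but, in our synthetic conditions, nearly identical decisions. The
package asserts neither as canonical: uncentered is the default, centering
is a configuration flag.

Similarities are reported uniformly on the cos²θ scale — for a single
pattern the squared projection of the normalized vector onto the class
subspace, for a pattern set the squared largest canonical cosine (optionally
the mean of the top-t squared cosines). cos²θ is a strictly monotone
function of the canonical angle on [0, π/2], so classification decisions are
unaffected by the choice of scale; the uniform scale makes single-pattern
and set-based scores directly comparable.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| pattern size | 8×8 (k = 64) | working resolution of all similarity computations |
| grayscale weights | BT.601 (0.299, 0.587, 0.114) | the common JPEG/video luma convention |
| resize | exact area averaging | oracle-checkable; block means for integer factors |
| sampling interval | 20 | one frame kept in 20 for online streams |
| window size w | 4 | frames per online query subspace |
| window stride | 1 | overlapping consecutive windows |
| dimension rule | contribution τ = 0.95 | smallest d with Σ_{i≤d} λᵢ / Σ λᵢ ≥ τ; fixed-d override |
| centering | off | uncentered autocorrelation (see above) |

Frame subsampling keeps the first frame then every s-th by position, so two
passes with intervals a and b equal one pass with interval a·b. Pixel
values stay on the 0–255 scale throughout; the angle similarities are scale
invariant, so no normalization is applied.

The offline protocol splits each recorded sequence into a first
(training) and last (testing) half; for odd lengths the default puts the
smaller half in training (floor-first), with a ceil-first option. Offline
test frames are scored per image by the single-pattern angle by default
because per-image decisions produce per-image confusion counts; a
`set_size` option groups consecutive test frames into sets scored by the
set-based similarity instead, with every frame inheriting its set's
decision. Ties on similarity go to the earliest category in model order and
are logged.

## Synthetic scenes: what they emulate, and what not

The generator emulates the statistical structure the classifier exploits,
not the photometry of real fields. One sequence = a fixed 8×8 class
template (upsampled to the frame size, default 64×64) + per-pixel Gaussian
noise with standard deviation `within_class_sd` (default 0.05 on the [0,1]
intensity scale) evolving as a stationary AR(1) process with lag-1
correlation `temporal_corr` (default 0.6), quantized to 8-bit RGB.
Sequences default to 200 frames — the scale of one subsampled field video.
"Noise" segments (takeoff/landing, field entry/exit) are uniform random
pixels, maximally unlike either template. Everything is bit-reproducible
from an integer seed; datasets derive per-sequence seeds as master seed +
sequence index.

Not emulated: geometric distortion, motion parallax, illumination
gradients, mixed or complex canopies, compression artifacts. Passing tests
on these scenes therefore demonstrate the correctness of the pipeline and
the self-consistency of the method — they do not predict field accuracy on
real UAV video.

Two canonical conditions are exposed by `default_two_class_params`:

* **separable** — crop-row template (alternating 0.25/0.75 columns) vs
  uniform bare-soil template (0.5); the template distance is an order of
  magnitude above the appearance noise, so offline accuracy is expected at
  100% and online window accuracy ≥ 99% away from segment boundaries.
* **zero-separation** — both classes share one template, so any classifier
  can only perform at chance. This condition switches temporal correlation
  off so per-image decisions are approximately independent and comparable
  to a binomial reference around 50%. Even so, the two fitted subspaces
  differ through their noise directions, which adds a small shared bias to
  all decisions of one run; across seeds the accuracy therefore scatters
  slightly more than a pure binomial would.

## Numerical choices

* Canonical cosines are singular values of B_Pᵀ B_Q, clipped to [0, 1].
  Angles recovered through `arccos` of a cosine lose accuracy below ≈1e-8
  rad (cosine saturates at 1 in double precision); tests that need tiny
  angles measure them through the sine via the projection residual
  (I − B_PB_Pᵀ)B_Q instead.
* Eigenvalues below 1e-12 × λ_max count as zero for rank decisions. A
  requested dimension above the numerical rank is clamped to the rank with
  a `RuntimeWarning`. Subspaces spanned by tied eigenvalues are defined
  only up to rotation within the tied block; every similarity the package
  reports is invariant to that rotation.
* A query set of n patterns spans at most n dimensions, so a fixed
  dimension rule is capped at n for online windows (a window of w identical
  frames yields a rank-1 query subspace and is handled normally).
* A single test vector cannot span a query subspace; `classify_set` falls
  back to the single-pattern angle similarity and logs the fallback.
* Reported accuracies are kept at full precision internally and rounded
  half-up to one decimal for display; location summaries report both the
  unweighted mean of per-location accuracies and the pooled accuracy over
  summed counts, which generally differ.

## Problem sizes

The synthetic study conditions use 200 frames per class at 64×64 pixels
(≈0.5 s to generate and preprocess per class), 100 random subspace pairs
for the oracle-agreement checks, and 60 samples for planted-subspace
recovery. The full test suite runs in under a minute on one CPU; the
reproduction script in about 15 s.

## Known limitations

* The per-window timing recorded by the online classifier is wall-clock of
  the similarity computation only and is hardware-dependent; it is
  informational, never an assertion.
* Reference accuracy on real UAV video cannot be validated here (no field
  video is distributed with the package); the bundled field-study
  confusion counts validate only the evaluation arithmetic.
* Kernel and constrained variants of the subspace comparison are out of
  scope, as are flight control, spray actuation and any photorealistic
  scene modelling.
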