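# Methods

`lungtex` quantifies the fine-grained speckle texture that propagation-based,
edge-enhanced (phase-contrast) X-ray projection imaging reveals inside the
lung, and asks two questions of it: *where is lung?* (binary window
segmentation) and *how expanded is it?* (classification of the ventilation
pressure used as a discrete surrogate of expansion state). Because the
in-vivo images the method was developed on are not redistributable, the
package ships a synthetic phantom generator that reproduces the statistical
structure the analysis depends on, so every stage is testable end to end
with no external data.

## The texture pipeline

**Standardization.** Contrast varies strongly across subjects, so each
16-bit image is clipped at its 0.01th and 99.9th intensity percentiles and
then histogram-matched to a single template. Matching is an *exact*
rank-based specification: pixels are stably sorted (ties broken by raster
order) and each rank is assigned the template quantile at its rank
fraction, with each histogram bin represented by its lower edge. This makes
the mapping monotone in rank, makes matching an integer image to its own
unit-bin histogram the identity, and makes the operation idempotent —
properties an interpolated CDF mapping does not guarantee, which is why we
do not use `skimage.exposure.match_histograms` here.

**Feature modes.** Four rasters are derived from the standardized image,
each computed once over the whole frame and then windowed:

- *identity* — the image affinely rescaled from the cohort-common
  intensity range to [0, 1];
- *skeleton* — local Otsu binarization (32-px square neighborhood,
  8-bit quantization) thinned to single-pixel-width structures. Windows
  whose local 8-bit range is ≤ 1 are suppressed before thinning: a flat
  neighborhood has no meaningful Otsu split, and binarizing its
  quantization noise would fabricate structure;
- *gradient* — Euclidean norm of the central-difference first
  derivatives, borders edge-replicated;
- *Laplacian* — 5-point Laplacian after a σ = 1 px Gaussian blur.

**Window statistics.** Statistics are taken over 32 × 32-px windows at
stride 16 (a 1984² frame carries 123² = 15129 windows; the 512² phantom
default carries 31² = 961). Each mode contributes a location/dispersion
pair: median/IQR for identity and Laplacian (robust to rib shadows; the
Laplacian window *median* is the statistic whose cohort mean tracks
pressure), mean/SD for skeleton (mean = sparsity of local structure) and
gradient (an extensive heterogeneity measure). Quantiles use linear
interpolation; SD is the population form.

**Spectral and orientation predictors.** Three more predictors complete
the 11 per window:

- *power_sum* — the window's DC-centred Fourier power spectrum is weighted
  by a difference-of-Gaussians annulus (σ_low = 2, σ_high = 8 in
  frequency-bin units, clamped at ≥ 0, DC zeroed) and
  Σ log(1 + weighted power) recorded. The log is stabilized as log1p so a
  constant window scores exactly 0; no taper is applied to the patch.
- *orientation* and *horizontality* — a bank of zero-mean oriented line
  detectors (12 angles over [0°, 180°), 9 px long, Gaussian cross-profile
  σ = 1.5) is convolved with the Laplacian raster; per window, the summed
  squared response per angle is normalized into an orientation
  distribution (angles mod 180°). *Orientation* is its mode (ties to the
  smallest angle); *horizontality* is h = 2·P(−45° < θ ≤ 45°) − 1, with
  bins straddling ±45° counted fractionally, so h = +1/−1/0 for purely
  horizontal/vertical/unoriented texture. A window with total response
  energy below 1e−18 is treated as unoriented (uniform distribution):
  the kernels are zero-mean only to float rounding, and a constant patch
  must not be normalized into a spurious distribution. The cited
  directional-filtering literature targets retinal vessels; its kernel
  sizes do not transfer verbatim, so the bank parameters here are package
  defaults, all configurable.

In the table builder the directional responses are computed by whole-image
convolution and then window-summed, consistent with the other modes (the
patch-level `orientation_pdf` exists as the reference semantics for a
single window; near window borders it sees reflected padding where the
global path sees true neighboring content).

## Classification

Windows are labeled by a 95% purity rule: a window enters training only if
at least 95% of its pixels carry one region label. Lung exemplars are the
lung union minus heart and diaphragm overlap; not-lung exemplars come from
outside the rib cage and from a mediastinal spine band. Ambiguous windows
are excluded from training but can still be scored. Class counts are then
balanced exactly by seeded downsampling to the minority class, and every
predictor is transformed to z-scores *per mouse* (population SD;
zero-variance columns map to 0) — the standardization never crosses mouse
boundaries, so a held-out mouse is standardized purely from its own
windows and no validation information leaks into training.

The classifier is a 128-tree random forest with standard classification
defaults (√p features per split, unlimited depth), seeded for
reproducibility. Validation is leave-one-mouse-out: one fold per mouse,
balancing done within each fold's training split, accuracy =
confusion-matrix trace over total, summarized as mean ± SE (sd/√n_folds)
across folds. For the segmentation task one experiment is run per
(pressure, held-out mouse) — 32 experiments for an 8-mouse, 4-pressure
cohort. For the pressure task a single 4-class classifier is
cross-validated the same way; per-fold row-normalized confusion matrices
are averaged into ensemble confusion probabilities, and an image-level
pressure call is the plurality vote of its window predictions (ties broken
toward the lowest pressure, for determinism).

Misclassification geography is summarized by the distance from each
misclassified window centre to the nearest known-lung window centre,
against a size-matched null drawn uniformly from all window centres
(seeded); boundary-hugging errors give a median well below the null's.

## Regional analyses

A predicted lung-window mask can optionally be cleaned by filling enclosed
holes and removing 4-connected regions smaller than a minimum size
(4-connectivity on the window lattice, because strided windows overlap and
8-connectivity over-merges). Right-lung window locations are partitioned
into k = 3 regions by plain k-means on (row, col) with 10 seeded restarts,
relabeled upper/middle/lower by mean row; coordinates are not rescaled
before clustering (the lattice is isotropic). Horizontality is summarized
per region by five-number summaries. The independence of orientation from
brightness is checked with Kendall's τ-b (tie-adjusted, since windowed
medians of quantized images tie often) between horizontality and the
identity-mode window median; τ is left undefined (error) for constant
columns.

## The phantom: what it emulates, and what it does not

The generator renders, at any square size (512 px default, 1984 px
supported, geometry scaling with the frame):

- **Lung speckle.** A band-limited Gaussian field is squared and centred —
  a positively skewed texture whose windowed Laplacian median is
  consistently signed and scales linearly with amplitude. Pressure enters
  through a strictly increasing amplitude map (defaults 1.0/1.45/2.1/3.0
  for 6/8/10/12 cmH₂O, a ~3× swing chosen to mirror the reported ~200%
  texture-statistic change against < 20% intensity change) and a mildly
  increasing band centre (0.100–0.124 cycles/px). A symmetric field would
  have window median ≈ 0 at every gain; the skew is what makes the
  monotone texture–pressure link hold by construction.
- **Orientation gradient.** Within the right lung an isotropic and a
  vertically oriented field are blended with a weight ramping from 0 at
  the apex to 1 at the base (linear anisotropy profile, configurable), so
  basal texture is vertical and apical texture isotropic.
- **Anatomy.** Elliptical rib cage and lungs (lungs strictly inside the
  cage), a dark blurred heart disc overlapping the medial left lung, a
  diaphragm dome, and a mediastinal spine band. Ribs are *multiplicative*
  attenuation stripes: lung texture passes through them uninterrupted,
  which is the central observation the classifier exploits — additive ribs
  would erase it.
- **Nuisance structure.** Smooth background field, low-frequency body
  clutter across the whole frame (without it the exterior is so smooth
  that segmentation saturates near 1.0 even with no lung texture, and the
  accuracy-vs-gain link disappears), additive sensor noise (σ = 200),
  and per-mouse brightness offset, lung-size jitter, and lognormal
  texture-amplitude jitter (σ = 0.15). The amplitude jitter is what makes
  held-out-mouse pressure classification genuinely hard: neighbouring
  pressures overlap across mice, producing confusion probabilities graded
  by |Δpressure| rather than a saturated identity matrix.

Everything is driven by `numpy` `SeedSequence` spawning, so identical
specs give bit-identical images and cohorts.

The phantom is a statistical emulation, not a physical one: no Fresnel
propagation, attenuation physics, cardiac motion, or real anatomy. A green
phantom test establishes that the *pipeline* recovers the statistical
structure it was built to detect (monotone texture–pressure link,
orientation gradients, boundary-concentrated errors); it does not
establish in-vivo accuracy figures, which depend on real anatomy and are
out of reach without the original images.

## Numerical choices and degenerate inputs

- Quantile convention: linear interpolation throughout (matches the
  sort-based oracles in the tests).
- Constant image: empty skeleton, zero gradient/Laplacian/power, uniform
  orientation distribution, horizontality 0.
- Percentile clipping of a constant image is the identity; histogram
  matching to a single-bin template maps everything to that bin.
- Balancing requires ≥ 2 non-empty classes; training requires ≥ 2 classes;
  cross-validation requires ≥ 2 mice; a fold whose training split lacks a
  class is skipped with a warning.
- Vote ties → lowest pressure; orientation-mode ties → smallest angle;
  k-means regions relabeled by mean row with a stable sort.

## Limitations

- Reported in-vivo accuracies cannot be reproduced here; phantom
  accuracies are properties of the stated synthetic world.
- The directional-filter parameterization is a package default, not a
  value fixed by the source method description.
- The per-mouse manual ROI adjustment performed on real data has no
  algorithmic counterpart; phantoms emit per-pressure ground-truth masks
  instead.
- Window labeling treats the window lattice, not pixels, as the unit of
  evaluation; pixel-level segmentation is out of scope.
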