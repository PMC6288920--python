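# Methods

This note records the models implemented in `octavd`, the defaults and why
they were chosen, the numerical details that affect results, and what the
synthetic validation does and does not establish.

## Synthetic phantoms

`generate_vessel_network` renders each vessel as a constant-curvature arc:
random start point (inside the central 80% of the frame), random heading,
curvature magnitude drawn from `curvature_range` with random sign, and arc
length capped at 80% of the full circle so no vessel closes on itself.
Constant-curvature centerlines were chosen because they exercise the
curvature parameter `k` of the ridge detector directly. The cross-sectional
profile is Gaussian with σ = half-width / √(2·ln 2), so the intensity at one
half-width off the centerline is exactly half the peak; the ground-truth
mask is the set of pixels within the half-width of the centerline, which
therefore coincides with the half-maximum level set on noise-free phantoms
(a property the tests exploit as an oracle). Distances from pixels to the
centerline are resolved exactly within a local window around densely
sampled arc points (0.25 px spacing); overlapping vessels combine by
maximum intensity.

Defaults: 304 px grid (the native en-face export size for 3 × 3 mm scans),
22 vessels of half-width 1–3 px and curvature up to 0.02 /px, peak
intensity 180, additive Gaussian background noise with SD 10 clipped at
zero. With these settings the truth-mask area fraction lands near 0.2,
the vessel-density scale of healthy macular segments. The noise model is
additive Gaussian rather than multiplicative speckle — the simplest model
sufficient to stress thresholding — and the phantoms make no attempt at
realistic vascular trees (no branching, no fractal statistics), OCT
speckle physics, or decorrelation statistics. Passing phantom tests
therefore demonstrates the geometry and statistics of the pipeline, not
performance on real OCTA contrast.

Motion artifacts are single-pixel-tall, fully saturated full-width rows
(a `band_height` parameter widens them); rows are chosen pseudo-randomly
subject to pairwise non-adjacency so each line is a distinct artifact.

`generate_paired_scans` draws a true density per subject from
Normal(mean, between-subject SD) and adds independent Normal(0, σw) errors
to each of the two observations. Observed values are truncated to [0, 1];
truncation (rather than resampling) slightly biases results when the mean
sits within ~2 SD of either bound, which is negligible at the default
operating point (mean 0.22, SDs 0.05/0.02). Defaults — 47 subjects, mean
0.22, σw = 0.02 — put simulations at the scale of a two-scan repeatability
study of healthy eyes.

## De-striping filter

The bandpass is built in the frequency domain from the transfer functions
of spatial Gaussians: `H(f) = exp(−2π²σ_high²|f|²) − exp(−2π²σ_low²|f|²)`
with defaults σ_high = 1.5 px (suppresses pixel noise) and σ_low = 40 px
(removes slow illumination and the DC term). These bracket the 1–10 px
vessel scales of a 304-px-class grid. An isotropic bandpass cannot remove
full-width horizontal stripes, whose energy sits at near-zero horizontal
frequency across all vertical frequencies, so a Gaussian notch
`1 − exp(−f_x²/2w²)` with w = 1 cycle/image multiplies the transfer
function when `bandpass.stripe_notch` is enabled (default). A single
saturated row has *all* of its AC energy at f_x = 0 and is annihilated.

Boundary handling is periodic by default — stripes span the full width, so
wraparound cannot split or alias them — with mirror padding available via
`bandpass.boundary: symmetric` for images whose content would otherwise
leak across edges.

## White-line counting and QC

"White line" is operationalised as a row that is bright (row mean above
the global mean by `qc.z_thresh` = 3 global SDs) and uniform across the
width (within-row coefficient of variation ≤ `qc.max_row_cv` = 0.2).
Maximal runs of consecutive flagged rows count once, so a thick band is a
single line. For a pure-noise image the largest of ~300 row means sits a
few row-standard-errors above the global mean — far below three global
SDs — so false positives are essentially impossible at the default
threshold.

A segment image is discarded when it has more than two white lines or a
recorded signal-strength index below `qc.ssi_min` = 40 (strict
thresholds: 2 lines pass, SSI 40 passes). Images without an SSI pass that
gate, since the index is device metadata synthetic inputs lack. Discards
are per segment: other segments of the same scan remain usable. No
further "image clarity" gate is implemented — no numeric rule exists for
one.

## SCIRD ridge detection

The kernel on the unrotated frame derives from the curved-support
Gaussian `G(x₁,x₂) = exp(−x₁²/2σ₁²)·exp(−(x₂+k·x₁²)²/2σ₂²)`: the kernel
is `−∂²G/∂x₂² = ((σ₂²−u²)/σ₂⁴)·G` with `u = x₂+k·x₁²`, coordinates
rotated by θ, then normalised to zero mean and unit L2 norm. The negation
makes bright ridges on dark background correlate positively. The default
bank is σ₁ ∈ {4, 6, 8}, σ₂ ∈ {1, 1.5, 2, 3}, k ∈ {±0.1, ±0.05, 0}, 12
orientations evenly spaced on [0, π), kernels 49 px square — 720 kernels
covering capillary-to-arteriole widths and bend radii down to 10 px.

Correlations use mirror-symmetric boundary extension and are computed by
FFT convolution of the padded image; the backend contract (tested) is
agreement with direct spatial correlation to 1e-6 relative.

**Scale weighting.** With unit-L2 kernels the centerline response of a
matched straight ridge grows roughly with the square root of its width
(the inner product gains amplitude with the overlap area), which measured
at 36% variation across half-widths 1–3 px — a poor basis for a single
threshold across vessel calibers. `scird_response` therefore weights each
kernel's correlation by `1/√(σ₁σ₂)` before taking the per-pixel maximum
(`scird.scale_norm: area`; `none` restores raw correlations). In the
continuous limit this weight makes the matched-filter response
width-independent; measured variation across the same widths drops to
11%. The weight also cancels the σ₁ dependence for straight ridges, so
elongation scales compete only on curvature matching.

**Binarization.** The threshold rule is deliberately exposed rather than
hidden: `fixed` (response > value) or the default `percentile`, which
keeps exactly `⌈p·N⌉` top-response pixels with ties broken by row-major
order. The default `scird.threshold_param` = 0.25 sits at the density
scale of the denser healthy segments. Note the structural consequence:
with a percentile threshold the whole-frame density *equals* the
threshold parameter, so absolute segment densities are a property of the
configuration, not the image; quadrant densities, ratios and all
test-retest statistics remain informative. Detection quality is tracked
by a regression floor on phantoms — Dice ≥ 0.70 against the truth mask
with the percentile set at the truth density (measured ≈ 0.82–0.84).

## Regions

The disc ellipse is the axis-aligned ellipse inscribed in the annotated
bounding box (center = box midpoint, semi-axes = half the side lengths).
Quadrants are cut by the diagonal and anti-diagonal through the analysis
center: image center for macular scans (304² → (151.5, 151.5)), ellipse
center for disc scans. The pixel frame is 0-based with pixel centers at
integer coordinates and y increasing downward, so the top sector is
anatomically superior.

Tie rule: pixels exactly on the anti-diagonal join the vertical sector of
their ray (superior above the center, inferior below); pixels on the
diagonal join the horizontal sector of their ray; a pixel at the exact
center joins superior. The per-ray split matters: for an even-sized grid
with a half-integer center, both full pixel diagonals lie on the dividing
lines (200 tie pixels on a 100² grid), and the balanced rule is what
yields exactly equal quadrant counts (4 × 2500). Assigning whole lines to
single sectors would skew the counts by 2%. Exact tiling (quadrant counts
summing to the segment count) is asserted on every region construction,
not only in tests.

For disc scans the region over which densities are computed is
configurable (`region.disc_interior`): the default `include` uses the
whole frame, matching the macular convention; `exclude_inside_ellipse`
and `only_inside_ellipse` expose the alternative readings. The
nasal/temporal orientation is likewise configurable
(`region.od_nasal_side`, default `right` for OD, mirrored for OS),
because en-face exports are not guaranteed un-mirrored. Macular quadrants
use the full square frame.

## Repeatability statistics

With two replicates per subject and dᵢ the per-subject difference,
`Sw = √(Σdᵢ²/2n)` — the Bland–Altman within-subject SD, identical to the
square root of the one-way within-subject mean square (both routes are
tested). The repeatability coefficient is `1.96·√2·Sw` exactly; the CV
divides Sw by the overall mean of both scans' values (not scan 1 only).
The default 95% CI for Sw is the normal approximation
`Sw·(1 ∓ 1.96/√(2n))`, the standard companion of this estimator at
m = 2 replicates (n degrees of freedom); an exact χ²(n) interval is
available via `repeatability.ci_method: chi2`. CV and repeatability CIs
are the linear transforms of the Sw bounds. Simulated coverage of the
default interval at n = 47 is ~95–97%.

Degenerate paired t-tests (all differences identically zero) report mean
0, interval (0, 0), p = 1 with a `degenerate` flag; a nonzero constant
difference is flagged with p = 0 rather than an undefined statistic.
Groups with fewer than two complete pairs are emitted as
`available = False` rows, never dropped silently; incomplete pairs are
excluded with a logged warning, and an audit line reconciles input pairs
with report rows. No multiple-testing correction is applied across
regions by default, matching the analysis the report mirrors.

One arithmetic caveat worth recording: published repeatability tables of
this kind sometimes print Sw and `1.96·√2·Sw` rounded independently, so a
printed coefficient can disagree with the printed Sw at the last digit
(e.g. Sw 0.078 → 0.216, not 0.217; Sw 0.028 → 0.078, not 0.076). This
package always computes the coefficient from the unrounded Sw.

## Problem sizes and determinism

Phantom validation runs on the native 304² grid with the full 720-kernel
bank (a few seconds per image); end-to-end pipeline tests use reduced
grids (64–96 px) and banks, which exercise identical code paths.
Parameter-recovery checks use 200 simulated 47-subject studies. Every
stochastic component takes an explicit seed, generators are bit-reproducible
under a fixed seed, and pipeline outputs are byte-identical across reruns
(manifest timestamps aside).

## Known limitations

* Phantoms are geometric stand-ins: no speckle statistics, projection
  artifacts, layer-segmentation errors, or vascular-tree topology. Results
  on phantoms bound the pipeline's correctness, not its clinical accuracy.
* Absolute densities under the default percentile threshold reflect the
  configured percentile (see above); comparisons against externally
  reported absolute densities require a fixed-threshold calibration that
  only real images could supply.
* The white-line detector assumes artifacts are bright and span the full
  width; partial-width or dark motion artifacts are out of scope.
* Disc annotations are trusted as given; no automatic disc segmentation,
  and no peripapillary annulus regions.
* Repeatability analysis covers within-visit, intra-observer test–retest
  only; no ICC, no inter-visit or inter-observer designs.
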