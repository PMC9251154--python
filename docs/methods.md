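# Methods

This note documents the models, numerical choices and limitations of
the `stereoloc` pipeline in the order data flows through it.

## Coordinate conventions

Images are indexed 0-based as `(row, col)` addressing pixel centers; a
circle is `(a, b, r)` with `a` the row and `b` the column of the
center, in pixels.  Lines use the normal form
`rho = x cos(theta) + y sin(theta)` with `x = col`, `y = row`,
`theta` in `[0, pi)`.  Physical coordinates are pixel indices times the
per-axis spacing in millimetres.  These conventions are used by every
module without exception.

## Synthetic phantoms

The phantom generator emulates what matters to mark-point detection in
a stereotactic positioning scan — bright fiducial markers and rods over
a smooth background, with MR-like noise — and nothing else.  Markers
are rendered either as annuli (rings) of configurable thickness, the
default because ring fiducials are what edge-based circle detection
votes on, or as filled discs; both with ~1 px linear anti-aliasing so
sub-pixel center placement is meaningful.  The background is a constant
plus an optional smooth intensity plane.  Noise is additive Gaussian by
default, with a Rician option (the magnitude statistics of complex MR
data).  Default amplitudes put markers ~120 intensity units over a
background of 20 on a 0–255-like scale.

Volumes stack identical in-plane geometry over slices, mimicking frame
rods perpendicular to the scan plane; true AC/PC positions can be
recorded in the truth sidecar for targeting tests.

What the phantom does **not** model: brain anatomy, bias fields,
partial-volume effects, pulse-sequence physics, motion or susceptibility
artefacts.  Passing tests therefore demonstrate correctness of the
geometry and estimation chain, not robustness to every artefact of real
scanner data.

The outcome-cohort generator draws integer preoperative UPDRS scores
uniformly in [30, 80] (a typical moderate-to-advanced motor range) and
chooses each postoperative score so the improvement rate lands inside
the requested category's band, with bands kept ≥ 5 percentage points
clear of the classification cut-offs so rounding can never flip a
category.  Requested per-category counts are reproduced exactly.

## Wavelet denoising

A separable 2-D DWT realizes the dilated/translated wavelet family
`psi_ab(t) = |a|^{-1/2} psi((t-b)/a)` discretely.  Defaults: `db4`,
3 levels, symmetric padding, soft thresholding of all detail subbands
at the universal threshold `sigma_hat * sqrt(2 ln N)`, with
`sigma_hat = MAD(finest diagonal subband) / 0.6745`.  A
`threshold_scale` of 0 gives perfect reconstruction (relative error
below 1e-8, in practice ~1e-16).  The SNR metric is
`10 log10(sum(ref^2) / sum((img - ref)^2))` dB against a noiseless
reference, with `inf` as the zero-residual sentinel.

A caveat found while validating: a strong marker edge survives
hysteresis edge detection even at heavy noise (sigma ≈ 20), so
denoising does not necessarily increase the *count* of edge pixels on
the marker — what it reliably improves is edge *precision* (the
fraction of edge pixels that belong to the marker), which is what the
Hough stages care about.  The edge-detection tests assert exactly that.

## Edge detection

Canny-style: Gaussian-gradient magnitude, non-maximum suppression,
hysteresis with absolute thresholds (defaults low 5, high 15 on a
0–255 intensity scale, smoothing sigma 1.5 px).  Constant images give
empty maps.  The binary map and the gradient magnitudes are both kept;
refinement uses the intensities, not the edges.

## Hough detection

**Lines.**  Each edge pixel casts exactly one vote per theta bin at the
rho bin `floor(rho/delta + 0.5)`.  Defaults: 180 theta bins (1 degree),
1 px rho resolution.  Peaks: greedy non-maximum suppression over bins,
candidates ordered by votes descending with ties broken by ascending
(theta, rho) bin index — fully deterministic.

**Circles.**  The 3-D accumulator `A(a, b, r)` is filled by midpoint-
circle rasterization of the center locus: for each edge pixel and each
integer radius, one vote per bin of the Bresenham/midpoint circle of
that radius around the pixel, out-of-image centers discarded.  Integer
geometry makes the accumulator exactly reproducible by a brute-force
per-pixel loop, which the tests exploit (with skimage's independent
rasterizer as the oracle).  Peak ranking divides raw votes by the ideal
perimeter bin count of the radius, otherwise larger circles always
out-vote smaller ones; suppression is Chebyshev over all three axes;
exact ties break lexicographically on (a, b, r).

**Sub-pixel refinement.**  Three iterations of an intensity-weighted
centroid over the annulus band `|d - r| <= window` (default 3 px),
re-estimating both the center and the band radius each pass.  The
radius re-estimation matters: a coarse detection may sit on one edge
ring of a thick marker, and a fixed band then truncates asymmetrically.
Background is the 10th percentile of the local window — a low quantile
rather than the median because a large filled marker can occupy more
than half the window.  The refined center is capped at 1.5 px from the
coarse one (a larger excursion indicates a bad detection, and the
coarse center is kept); a window clipped by the image border is
flagged.

**Ring vs disc markers and the radius.**  A ring marker of thickness t
produces two concentric edge circles at `r ± t/2`, so the Hough radius
of a ring is offset by the half-thickness *by construction*; its center
is unaffected.  The recovery studies therefore use filled-disc markers,
whose single boundary coincides with the true radius, as the condition
under which "radius within one bin" is a meaningful claim.  With the
default batch conditions (128 px slices, r ∈ [6, 20] px, Gaussian noise
sigma ∈ [0, 10], denoise → edges → accumulate → peaks → refine) the
measured recovery is 97–99 of 100 slices within 1 px center and 1 bin
radius, mean center error ~0.3 px.

## Matching

`group_collinear` hypothesises the line through every point pair,
collects inliers within the tolerance, refits by total least squares
and re-selects once; maximal groups of ≥ 3 are kept, largest first.  A
point may sit in several groups (crossing rods).  All-identical points
are rejected as degenerate.

`match_marks` tries the template anchor pair against every ordered
detection pair; each hypothesis induces a similarity transform
(rotation + isotropic scale + translation — scale because detections
may be in px while templates are in mm; reflection excluded), under
which remaining labels are assigned one-to-one by
minimum-total-distance (Hungarian algorithm).  The hypothesis keeping
the most labels within tolerance wins, ties broken by total residual
and then detection indices.  Fewer than 3 consistent labels raises a
matching error naming the best residual found.  Matched labels are
reported anchors first, then by template order.  The exhaustive
hypothesis search is O(n² · assignment) — appropriate for the ≤ ~20
detections of a frame scan, not for large point clouds.

## Registration and targeting

The rigid fit is the SVD orthogonal Procrustes solution with the
determinant sign corrected to exclude reflections; no scale, because a
stereotactic frame is rigid and unscaled residuals are interpretable in
mm.  Rank-deficient (collinear/coincident) configurations are rejected
with an explicit error.  Noiseless recovery is exact to ~1e-13 mm RMS;
with 0.2 mm isotropic jitter on 8 points the mean FRE is ~0.29 mm
(the fit absorbs part of the noise, so FRE < FLE).

The AC-PC frame puts the origin at the commissure midpoint, Y along
PC→AC, Z the midsagittal component orthogonal to Y, X = Y × Z
(right-handed, X toward the patient's right).  The construction is
invariant under global rigid motion of its three defining points.
Targets take a lateral magnitude and a side; left-side targets carry
negative x internally.  The subthalamic protocol window —
|X| ∈ [10, 13], Y ∈ [−2, −1], Z ∈ [−6, −2] mm — is checked with
inclusive bounds, the usual reading of printed clinical ranges.

Error metrics follow the standard fiducial-registration vocabulary:
FLE per mark (detected vs true position, scaled to mm), FRE (RMS
residual of the fit), TRE (transformed target vs its true frame-space
position).

## Outcome statistics

Improvement rate `100·(pre − post)/pre` percent; undefined for
`pre ≤ 0` and negative when symptoms worsen.  Classification bounds are
inclusive: markedly effective at ≥ 50 %, improved at ≥ 20 %, else
ineffective.  These cut-offs are not universal in the literature and
are therefore configurable; they are also mirrored by the cohort
generator's sampling bands.

The group comparison uses the Pearson chi-square without continuity
correction (df = (rows−1)(cols−1)); expected counts below 5 produce a
warning rather than a silent switch of test, and a zero expected count
is an error advising category merging.  For the 40/40 two-arm table
with counts 37/1/2 vs 35/2/3 the statistic is 0.589 (df 2, p ≈ 0.745)
— the table rows are too similar to be significant by this test, and
the implementation reports what it computes.  The paired t-test is the
textbook statistic on the per-patient differences with a two-sided p;
zero difference variance is an error.  Under a simulated null its
type-I rate at alpha = 0.05 sits near 0.05 (measured over 1000
replicates).

## Problem sizes and determinism

The standard study conditions used by the test suite and the
acceptance script: 100 single-marker 128 px slices for recovery; 64 px
edge maps for exact brute-force accumulator comparison; 8-point
templates with 100 noiseless motions and 50 jittered replicates for
registration; 20 seeds per noise level for denoising; 1000 replicates
for the t-test null.  These sizes give stable statistics while keeping
a full run in seconds.  Every stochastic step is driven by an explicit
integer seed through `numpy.random.default_rng`; equal inputs give
bit-identical outputs, and all peak searches have documented
deterministic tie-breaks.

## Known limitations

* Circle radii are integer-valued in the accumulator; sub-pixel
  refinement applies to centers, not radii (the refined band radius is
  an internal estimate, not reported).
* The line accumulator does not wrap suppression across the theta
  seam (a near-vertical line split across theta ≈ 0/pi can yield two
  peaks).
* Matching assumes the frame template's anchor pair is uniquely the
  most separated pair and that detections differ from the template by
  a similarity; strong perspective or non-rigid distortion is out of
  scope.
* Volumetric (spherical) Hough detection is not implemented; the
  three-dimensional structure here is the (a, b, r) parameter space,
  with 3-D positions obtained by stacking in-plane detections.
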