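# Methods

## Problem and scope

`meibomorph` quantifies meibomian-gland architecture from paired binary
masks (gland, tarsus) of infrared meibography images and relates the
resulting indicators to ordinal MGD severity grades 0–3. It deliberately
starts *after* segmentation: producing the masks (by deep network or
otherwise) is out of scope, as are functional indicators (secretion
quality, orifice obstruction) and meiboscore-style composite grading.

## Mask preprocessing and contour model

A mask is a strictly binary raster; loading reduces multi-channel images by
per-pixel channel maximum and thresholds at intensity > 0 (annotation masks
are conventionally 0/255; the threshold is configurable). Resizing — e.g.
to the 640 × 1280 working geometry — is nearest-neighbour only, since any
interpolating resampler would break binarity.

Cleanup is one pass of morphological opening with the 3 × 3 cross-shaped
structuring element (center + 4-neighbours, the standard 3 × 3 "ellipse" of
mainstream vision toolkits). Pixels outside the image count as background,
so structures touching the border erode there; masks produced by the
resize convention have glands well inside the frame, where this is moot.

Connected components are 8-connected. Each component contributes its outer
boundary only; interior holes (annotation pinholes) are filled before the
area count, so `area_px` is the filled pixel count — the unit the
"area < 10 px" filter is defined in. Components with fewer than 4 boundary
vertices are also dropped; under the sub-pixel iso-contour representation
used here (marching squares at level 0.5, one vertex per pixel-edge
crossing) this second filter is nearly vacuous, and the area rule does the
real work. The boundary polygon traces the half-pixel band around the
foreground pixel centers, so a rectangle of 10 pixel columns measures
10 px across — widths and gaps come out in true pixel units without a
±1 px convention correction.

Contours are ordered by ascending centroid x (centroid = mean of filled
pixel coordinates), ties broken by ascending y so the order is total and
runs are reproducible.

## Per-gland geometry

**Principal axis.** The gland direction is the leading eigenvector of the
covariance of the boundary vertices (duplicated ring-closing vertex
removed, as it would bias the covariance), sign-normalized to dx > 0 (or
dx = 0, dy > 0). The eigenvalue ratio (elongation) flags near-isotropic
blobs: below 1.05 the direction is numerically meaningless, and the gland
is reported with NaN morphology (and excluded from per-image means) rather
than measured along an arbitrary axis.

**Sampling stations.** All boundary vertices are projected onto the axis;
50 equidistant positions spanning [t_min, t_max] inclusive each define a
perpendicular line, intersected with the boundary polygon. The chord is
the extreme pair of intersections along the perpendicular — one transverse
extent per line, deterministic also for concave boundaries. Lines that
graze the boundary (< 2 intersections, or a numerically zero chord
< 1e-6 px) yield invalid stations, which are dropped rather than imputed;
tangency at the rounded end caps typically costs the two extreme stations.

**Width** is the mean chord length over valid stations. **Length** is the
polyline length of the chord midpoints in axis order; it measures the
tip-to-tip extent of the shape (for a capped tube this includes the caps).

**Distortion** is the discrete curvature of the midline: at each interior
midpoint, the turning angle (π minus the included angle of the adjacent
segments, arccos of the clamped normalized dot product) divided by the
mean of the two adjacent segment lengths. Two numerical choices matter
here, because a three-point turning angle is a second-difference estimator
and rasterized boundaries carry half-pixel staircase noise:

1. the midline is first regularized with a short Gaussian (σ = 2 stations,
   edge mode "nearest");
2. the per-point curvatures are aggregated by their **median**.

Without them the staircase noise — heavy-tailed and strictly positive
under unsigned turning angles — dominates: straight but slightly tilted
glands read ≈ 0.02 px⁻¹ and arc curvatures overshoot by 60–240%. With
them, straight glands read below 1e-3 px⁻¹ and arcs recover 1/R with a
median error of a few percent (see the recovery batch below). The
regularization is scale-equivariant, so distortion still halves exactly
under a 2× rescale. The known cost of the unsigned formulation remains for
shapes whose bend alternates within one station spacing; at 50 stations per
gland this is below the noise floor. Distortion is reported in px⁻¹;
conversion to physical units requires an external pixel-spacing factor.

## Image-level indicators

Tarsal area is the filled area of the largest tarsus-mask component
(smaller stray components are ignored with a warning). Density is total
gland area over tarsal area; loss ratio is its complement, clamped to
[0, 1] with a warning if glands overflow the tarsus — glands are *not*
clipped to the tarsus, so the identity loss = 1 − density is only
guaranteed when containment holds (as it does by construction for the
synthetic data). Adjacent distance is the minimum boundary-vertex distance
between consecutive glands in left-to-right order ("adjacent" means
consecutive in that order, not mutual nearest neighbours); disorder is the
population (divide-by-n) standard deviation of those gaps — a census
statistic that is deterministically 0 for a single gap and undefined (NaN)
with fewer than two glands. Undefined values propagate as NaN and are
serialized as empty CSV cells, never as 0.

## Synthetic data

The generator emulates the working geometry of resized meibography masks:
a filled elliptical tarsus band (semi-axes 0.46 × width, 0.42 × height) and
5–30 near-vertical glands, each a tube of constant width around an analytic
centerline (straight segment, circular arc, or sinusoid), rasterized as the
pixels within width/2 of the densely sampled centerline. Ground truth
(centerline length, width, curvature, pixel areas, surface-to-surface gaps,
density/loss) is recorded exactly; density + loss = 1 holds by definition.

Severity grades 0–3 map linearly to generator parameters with seeded
jitter (`synthetic.GRADE_PARAM_MAP`): glands per image 16 → 7, mean width
16 → 8.5 px, mean length 280 → 115 px, mean curvature 0.001 → 0.016 px⁻¹,
and x-position jitter fraction 0.04 → 0.19. The directions encode the
clinical picture — higher grade: fewer, shorter, thinner, more tortuous
glands, lower density, higher loss ratio, wider and more variable gaps.
Placement uses left-to-right slots with a constructive lateral budget
(width + arc sagitta + orientation sway + jitter must leave the 8 px gap
floor), so rejection sampling (200 attempts per image, failure is an error
reporting the seed) almost always succeeds on the default canvas and truth
counts stay exact.

What the generator does **not** emulate: segmentation errors (ragged
boundaries, false splits/merges), branching glands, intensity-dependent
artifacts, or anatomically realistic gland-shape distributions. Passing
the recovery and statistics tests therefore shows the *measurement
pipeline* is correct and well-conditioned on clean rasterized shapes — not
that clinical AUCs of any particular magnitude would be achieved; the
synthetic grade→parameter map separates grades far more strongly than
clinical data, and its near-perfect AUCs should be read as a pipeline
sanity bound, not a clinical claim.

## Statistics

The Spearman screen correlates each indicator with grade (average-rank
ties, two-sided p via the t-approximation in scipy), excluding undefined
cells pairwise, with the effective n reported; p < 0.001 is the default
significance threshold and no multiple-testing correction is applied. Box
summaries use linear-interpolation quartiles and Tukey 1.5 · IQR fences.
The grading model is one-vs-rest logistic regression (L2, C = 1, features
mean-imputed and z-scored with statistics fit on training folds only),
evaluated as per-grade ROC AUC plus micro-average (pooled binary
decisions) and macro-average (mean per-grade AUC per fold), reported as
mean ± std over 5 stratified folds (default) or a single stratified 8:2
hold-out. Everything is deterministic given the seed.

## Problem sizes and validation experiments

The package validates itself on two standing experiments, shared by the
test suite and `scripts/acceptance.py`:

- **Geometry recovery**: 60 single glands (widths 6–20 px, lengths
  80–300 px, half straight, half arcs with R ∈ {50, 100, 200} px, tilt
  ±0.06 rad), scoring median absolute relative errors of length and width
  (≤ 5% expected), median absolute distortion of straight glands
  (≤ 1e-3 px⁻¹) and median relative distortion error of arcs (≤ 15%).
- **Graded study**: 25 images per grade at 640 × 1280, measured
  end-to-end, then screened and cross-validated; a label-permutation run
  provides the chance baseline (micro-AUC ≈ 0.5).

These sizes give stable medians and tight correlation p-values while
keeping a full run in the low minutes on one core.

## Known limitations

- Length measures axial tip-to-tip extent; for strongly bent glands
  (arc span approaching π) the PCA axis compresses the projection and
  both length and width acquire obliquity bias (width reads high where
  chords cross the tube at an angle).
- Perfectly axis-aligned rasters are a degenerate special case: the
  staircase phase locks across stations and distortion can bias by ~10%
  relative; any generic orientation behaves better.
- Overlapping glands in a mask merge into one component (counted once);
  touching glands separated only diagonally are 8-connected and also merge.
- The unsigned curvature cannot distinguish C-shaped from S-shaped
  tortuosity of equal local curvature, and under-reports tortuosity whose
  wavelength is below the station spacing.
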