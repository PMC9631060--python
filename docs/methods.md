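# Methods

This note documents the models, conventions and numerical choices behind
each quantification stage, what the synthetic scenes emulate, and the
limits of what the passing tests demonstrate.

## Conventions

All images are 0-based arrays in `(z, y, x)` (volumes) or `(y, x)`
(planar) order with a per-axis physical spacing in µm; centroids and
distances are reported in µm (index × spacing). Synthetic scenes default
to 1 µm in-plane pixels; real images must supply their calibration —
in-plane magnification is instrument-specific and is deliberately a
required input rather than a default. Confocal stacks are modelled as
200 µm deep with 5 µm z-steps (40 slices), the standard acquisition for
these hydrogels.

## Preprocessing

*Binarization* defaults to Otsu's threshold as a reproducible stand-in
for interactive manual thresholding; a fixed threshold reproduces manual
choices exactly. Thresholding is strict (`> t`).

*Rolling-ball background subtraction* is realized as grey-scale
morphological opening with a disk of the stated physical radius
(10–15 µm is the usual setting for nuclear-marker channels). Opening is
the standard algebraic equivalent of the rolling-ball filter: constants
map to zero, features smaller than the ball survive, broad gradients are
removed. The estimate is undefined within one ball radius of the image
border, as with any morphological background.

*Contrast enhancement* saturates a fixed fraction of pixels, split
equally between tails, with a monotone linear stretch over the original
value range. The conventional dialog value "0.35" denotes 0.35 %, i.e.
`saturated=0.0035`. Anchors are placed at the midpoint between the k-th
and (k+1)-th ranked values so exactly k pixels saturate per tail on
distinct-valued data; heavily tied data fall back to the full range.

## Invasion profiling

The radial profile assigns pixels to annular bins (default width one
pixel) by Euclidean distance from the centroid of the largest connected
component (the spheroid body — so stray invading specks cannot drag the
origin). Only radii whose full annulus lies inside the image are
profiled, avoiding partial-annulus bias; the cost is that foreground
beyond the inscribed disk is not profiled, which matters only for
spheroids placed near a field edge.

The r_i metrics need a unique crossing radius, but raw annulus fractions
are noisy and can cross a threshold several times. A weighted
non-increasing isotonic envelope (pool-adjacent-violators, pixel-count
weights) is fitted first and the crossing of (i/100)·max is linearly
interpolated. This guarantees r₇₅ ≤ r₅₀ ≤ r₂₅ structurally. If the
envelope never falls below the threshold, the largest profiled radius is
returned.

Total intensity integrates I(r)·2πr by the trapezoid rule, with the
profile extended to r = 0 and to the outer bin edge; on binarized images
this equals the foreground area inside the profiled disk up to
discretization (measured < 0.5 % on random masks, bound 2 %).

"Outgrowth area" is the convex hull of foreground pixels, computed as a
hull *image* and counted in pixels — a filled 100×100 square yields
exactly 10⁴ px², where a vertex-polygon shoelace on pixel centres would
yield 99². The hull is parameter-free; a concave alternative
(morphological closing + hole filling, closing radius 20 µm default) is
available behind a flag for strongly star-shaped outgrowth. Density =
total intensity / outgrowth area; discretization can push it a fraction
of a percent above 1 on perfectly solid masks, and it is reported
unclipped.

## Vessel morphometry

Skeletonization is 3D topological thinning (Lee's method via
scikit-image). The skeleton voxel graph uses 26-connectivity; voxels
with ≠ 2 neighbours become node voxels, mutually adjacent node voxels
are clustered into one node (thinning emits junction *clusters*, and
counting voxels would inflate junction density), and branches are traced
through degree-2 chains. Branch length is the sum of per-step physical
distances under the anisotropic spacing — never voxel counts — which
keeps a 45°-rotated tube's length within 0.5 % of the axis-aligned one.

Three cleanup passes reflect how thinning distorts ideal geometry:

- *Pass-through simplification*: degree-2 nodes created by staircase
  configurations are merged into a single branch (bridging step added).
- *Junction merging* (`merge_junctions_um`, default 20 µm): a multi-way
  branch point of a tube of radius r thins into nearby lower-order
  junctions whose attachment points are offset by roughly r along the
  trunk; junction pairs connected by a skeleton path shorter than a
  couple of tube radii are therefore one anatomical branch point and are
  contracted, retaining the absorbed centerline length in the total.
  Tiny self-loops at complex junctions (thinning occasionally carves a
  hole) are absorbed the same way; genuine isolated cycles are kept.
  The default assumes junctions of distinct branch points are separated
  by well over 20 µm, true for capillary-scale networks and enforced in
  the generator (≥ 60 µm).
- *Spur pruning* (`prune_um`, default 10 µm = two z-steps): terminal
  spurs shorter than the threshold attached to a junction are surface
  noise and removed; a short *isolated* segment is a real vessel and
  kept.

Metrics are normalised by the imaged stack volume (field area × 200 µm
depth). Average branch length excludes junction-internal length and is
missing (NaN) for branchless volumes.

## Proximity mapping

The distance transform is the exact Euclidean EDT with per-axis physical
sampling, computed on the 2D maximum-intensity projection (the
convention for these co-culture stacks; a 3D variant is available but
non-default). Each cell's scalar distance defaults to the *mean* of the
transform over its pixels — the pixel-wise product of distance map and
cell mask reduced to one number per cell; `min` and `centroid`
aggregations are provided since the choice is not canonical. Bins are
left-closed ([0,10), …), so a cell at exactly 50 µm falls outside the
PVN; the 50 µm cutoff follows the operational PVN definition used with
such hydrogels. Cells touching the field border are flagged (their true
nearest vessel may be outside the field) but included.

## Marker quantification

The overlap fraction of marker object m with GBM cell g is |m ∩ g| / |m|
— the marker-object area is the denominator; the cell-area denominator
is available behind a flag. A cell is positive when any marker object
reaches the threshold (default 0.30, "at least 30 %" inclusive), and a
marker object straddling two cells can make both positive — object
claiming is not arbitrated. Raising the threshold can only lose
positives (monotonicity is tested). Composite ratios (EdU⁺/KI67⁺,
treated/control, cPARP⁺/KI67⁺) are plain fraction quotients; zero
denominators yield a missing value with a warning rather than an error.

## Assay quantification

GR values use start-of-treatment signal x₀, end-of-treatment vehicle
control x_ctrl and treated signals x(c):
GR = 2^(log₂(x/x₀)/log₂(x_ctrl/x₀)) − 1. GR is computed per replicate
and averaged per concentration before fitting (matching triplicate plate
reads). The curve is the 3-parameter sigmoid with upper asymptote 1;
GEC50 is fitted in bounded space (GR_inf ∈ [−1, 1], Hill ∈ [0.05, 10])
with a least-squares fit. GR50 is solved analytically,
GEC50·(0.5/(0.5 − GR_inf))^(1/h), and reported missing when
GR_inf ≥ 0.5. "Growth reduced by 50 %" is taken as GR = 0.5; the 50 %
relative-viability crossing is interpolated log-linearly and emitted
alongside for comparison.

ΔΔCT: ΔCt = Ct_target − Ct_reference per sample cancels per-sample
loading; ΔΔCt subtracts the baseline condition's mean ΔCt (day-0
endothelial-only samples with CD31/PECAM1 reference by default, which
normalises for the extent of vascularisation); fold change = 2^(−ΔΔCt)
of the mean ΔΔCt, i.e. the geometric mean across replicates. Probe
efficiency correction is out of scope.

Cytokine arrays: background-subtracted spot intensities are divided by
the same membrane's mean positive-reference intensity (cancelling
exposure differences between membranes exactly), duplicates averaged per
analyte, and group fold changes taken against a baseline group (the
tumor-only condition by convention; its column is identically 1).

## Synthetic scenes

The generators emulate the study conditions with planted truth:

- *Spheroid scenes*: Bernoulli occupancy 1/(1+exp((r−R0)/s)) around a
  filled core, defaults R0 = 60 µm, s = 10 µm in a 256² field — sharp
  enough to resemble a day-3–7 invasion front while leaving a clear
  analytic inversion r_i = R0 + s·ln(100/i − 1).
- *Vessel trees*: 12 segments of 60–90 µm (capillary-scale branch
  lengths), tube radius 7.5 µm (15 µm diameter vessels), grown by
  bifurcation/trifurcation at leaf endpoints so branch and junction
  counts are exact by construction. Segments lie in one z-plane along
  near-45°-multiple orientations with endpoints snapped to the voxel
  grid: digital straight lines along such orientations have step-sum
  lengths equal to their Euclidean length, making the planted totals
  meaningful to < 5 %; fractional-coordinate stair patterns are also a
  known failure mode of 3D thinning and are avoided by construction.
  Non-adjacent tubes keep a clearance above one diameter so thinning
  never bridges branches.
- *Proximity scenes*: a full-height vessel band makes every pixel's
  distance its horizontal offset, so symmetric circular cells have mean
  pixel distance exactly equal to the planted offset.
- *Marker scenes*: rectangle cells with marker rectangles shifted by
  integer pixels so overlap fractions (0.35/0.25 by default, straddling
  the 30 % rule) are exact.
- *Dose-response tables*: signals inverted from the GR sigmoid
  (GR_inf = −0.2, GEC50 = 300 µM, Hill 2 — a partly cytotoxic drug over
  the 0–600 µM range used for temozolomide) with two control doublings
  and lognormal noise at 5 % CV for stochastic checks.
- *Ct tables / spot arrays*: planted folds enter as −log₂(fold) shifts
  on a baseline Ct with shared per-sample offsets the ΔΔCT method must
  cancel; spot intensities carry per-membrane exposure factors the
  reference normalization must cancel.

What the scenes do **not** emulate: optical point-spread blur, shot
noise, uneven illumination, touching cells requiring watershed-style
splitting, vessel diameter variation and loops (trees only, except the
explicit loop fixture), or drift between time-lapse frames. Passing
tests therefore demonstrate the *computations* are correct on clean,
known-truth geometry — not that segmentation of difficult real imagery
is solved, which is out of scope (inputs are binarized/labelled by the
preprocessing stage or upstream tools).

## Problem sizes

Test and acceptance workloads are sized for quick iteration: ≤ 512²
masks for the polar-integral identity, 20 spheroid scenes, 50 ≤ 64²
scenes against the brute-force distance oracle, three 12-segment trees
plus the fixed tube/Y/loop fixtures, and 50 noisy dose-response tables —
each chosen as the smallest size at which the targeted property is
genuinely exercised.

## Known limitations

- Skeleton length slightly overestimates planted length at junctions
  (arms overlap the trunk before their centerlines merge) and
  underestimates at free tube ends (thinning retracts by roughly the
  tube radius); both effects are bounded by the tube radius per feature
  and stay within 5 % for branch lengths ≳ 8× radius.
- The isotonic envelope makes r_i robust but means a genuinely
  non-monotone profile (e.g. a detached invading ring) is summarised by
  its monotone envelope.
- Convex-hull outgrowth area overestimates strongly concave outgrowth;
  the closing-based alternative trades a radius parameter for tightness.
- GR fitting assumes the upper asymptote is exactly 1; strongly noisy
  low-dose data can pull fitted parameters while leaving GR50 (the
  tested quantity) stable.
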