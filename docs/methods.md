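# Methods

## Geometry and conventions

All volumes are arrays indexed `(z, y, x)` with voxel pitch
`spacing = (dz, dy, dx)` in μm.  Physical coordinates refer to voxel
*centers*: index `(k, i, j)` sits at `(k·dz, i·dy, j·dx)` μm, and SWC
coordinates follow the same mapping (`x` = column, `y` = row, `z` = slice).
Spacing is never read from TIFF metadata — TIFF resolution tags vary too
much across microscope vendors to be trusted silently — but is an explicit
argument everywhere.  The default, `(7.6, 2.26, 2.26)` μm, is derived from
a 50×50×5-voxel region spanning 113×113×38 μm, the region geometry of the
confocal data this tool targets; it is an approximation and should be
overridden with the true acquisition pitch.

## Segmentation

The iterative selection threshold is the fixed point of
`t ← (μ_low + μ_high)/2` with `μ_low`/`μ_high` the means of intensities
at-or-below / above `t`, started at the global mean.  On a finite
histogram the iterate is confined to the open interval between the image
minimum and maximum and converges in a handful of steps; the
implementation works on the sorted histogram (one `searchsorted` per
step), stops when the update moves ≤ `convergence_tol` (default 0.5, half
a gray level), and raises after `max_iter` (default 200) carrying the last
iterate.  A constant image has no threshold and raises a degenerate-input
error.  Ties go to background: foreground is strictly `v > t`.

One threshold is computed per stack by default (sections are imaged
through their whole thickness and thresholded as a unit); per-slice
thresholding is available for data with depth-dependent attenuation.
After thresholding, 26-connected components smaller than
`min_component_voxels` (default 27 ≈ one 3×3×3 speckle) are removed.  The
cleanup size is a choice of this implementation — the underlying protocol
does not state one — so it is exposed in the configuration and echoed to
every run log.  No pre-filtering (background subtraction, vesselness
enhancement) is applied by default.

## Centerline tracing

Skeletonization is distance-ordered homotopic thinning: voxels are
deleted one at a time, in ascending order of (grid-isotropic) distance to
the background, and only if they are *simple points* — the
Malandain–Bertrand local characterization: exactly one 26-connected
foreground component in the 26-neighborhood and exactly one 6-connected
background component in the 18-neighborhood touching the face neighbors.
Curve endpoints (≤ 1 foreground neighbor) are protected.  Each distance
level is exhausted before the next is touched, so the surviving line hugs
the distance ridge (the medial axis).  Because deletion never changes
topology, the skeleton has exactly the 26-connected component count of the
mask — for any input, including even-parity-symmetric objects that have no
central voxel layer.  Terminal spurs of ≤ 2 voxels (side twigs sprouting
from surface bumps and open tube ends) are pruned afterwards, and thinning
and pruning alternate to a fixpoint because removing a spur can expose a
residual voxel triangle at a junction.  The hot loops are numba-compiled.

Thinning runs on the voxel grid — topological thinning is
spacing-agnostic — while radii use physical distances: each node's radius
is the anisotropy-aware Euclidean distance transform of the mask
(`scipy.ndimage.distance_transform_edt` with `sampling=spacing`) at the
node's voxel.  At 3.4× axial anisotropy this grid/physical split avoids
resampling artifacts, at the cost of slightly off-center axial placement
for vessels running near the optical axis; this is a documented
approximation.

Graph building is deterministic: nodes are created in lexicographic voxel
order, each 26-connected skeleton component is rooted at its
lexicographically smallest voxel and spanned breadth-first with
lexicographic neighbor order, and edges that would close a cycle
(26-adjacency triangles along diagonal staircases) are dropped and
counted in the log.  SWC output is therefore reproducible bit for bit.
Nodes are one per skeleton voxel, with no spline smoothing or resampling.

### Diameter convention and its biases

Diameter is `2 ×` the distance-transform value at the node.  Distances are
center-to-center, which carries a positive bias of up to about half a
voxel per radius (the nearest background *center* lies beyond the true
surface).  Conversely, when a vessel axis falls near the mid-point between
lattice lines (sub-voxel offset ≳ 0.4 voxel in two axes simultaneously),
the distance transform can *under*-read the radius by up to ~0.7 voxel —
e.g. a radius-5 tube at offset (0.48, 0.32) voxels admits a maximum
center-to-center distance of √20 ≈ 4.47.  Neither bias is corrected; both
are inside the one-voxel tolerance used throughout validation, and the
phantom suites place axes within ±0.3 voxel of a lattice position so the
documented regime is the tested one.  Within about one tube radius of an
open vessel end, both the thinned centerline and the distance transform
are additionally corrupted (end-cone effect, thinning tails), so
diameter-recovery measurements exclude one to two radii of arc length at
each path end.

## Validation protocols

*Segmentation scoring*: `n` regions of interest (default 100, extent
50×50×5 voxels) are drawn with origins uniform over valid positions from a
seeded generator; when a reference mask is supplied, ROIs without any
reference foreground are rejected and redrawn (bounded retries), standing
in for the unstated rule that audited regions contain vessels.  Each ROI
is compared on its z-axis maximum intensity projection — the 2D form a
human rater can trace — with 3D voxelwise comparison available as an
option.  Metrics use the manual mask as ground truth; a metric whose
denominator is zero is reported as NaN (never coerced to 0 or 1) and
excluded from the mean ± SD summary with a logged count.  Dispersion is
the sample (n−1) standard deviation; a single ROI reports SD 0 with a
warning.

*Diameter comparison*: the "manual" measurement is emulated explicitly as
the full width at half maximum of a linearly interpolated intensity
profile perpendicular to the vessel, above a robust background (median of
the outer 20% of the profile), since the human procedure has no formal
rule; both the background rule and the line length are configurable.  The
traced measurement takes the nodes nearest to five equally spaced interior
arc-length positions along the vessel's main path (endpoints are never
selected).  Both sides contribute exactly five values (configurable) and
are compared by the absolute difference of their means.

## Phantom generator

A phantom is a list of tubes — polylines in physical μm with scalar or
per-point radii — rasterized exactly: a voxel is foreground iff its center
lies within the (linearly tapered) radius of some centerline point, the
union-of-spheres sweep.  For tapered segments the point-to-cone test is
solved in closed form (the distance-minus-radius objective is convex in
the segment parameter).  The ground-truth graph resamples each centerline
at ≤ 1 voxel (minimum spacing) arc steps with interpolated radii; a tube
whose first point coincides with an existing node attaches there, so a
constructed bifurcation is one degree-3 node.

The rendered stack is `background + (foreground − background)·mask`
convolved with an anisotropic Gaussian PSF (default σ = (3, 1, 1) μm,
axial ≥ lateral, the standard confocal approximation — no optical
parameters are given for the real system), then noised and quantized to
16 bit.  Two noise models are provided: additive Gaussian, and Poisson
shot noise on photon-scaled intensities (`scale` counts per intensity
unit), the physical model for photon-limited fluorescence.  All
randomness flows through one `numpy` generator seeded from the spec, so
identical specs are bit-identical.

Suites used by the tests:

* `straight` — radii 2–8 voxels at isotropic 1 μm spacing, axes jittered
  ±0.3 voxel around a lattice position, tubes spanning the full volume
  (no end caps), PSF- and noise-free: isolates digitization effects.
* `branching` — five Y-junctions with varied angles, noise-free.
* `web` — one volume with four disjoint tubes of mixed orientation.
* `thin-vessel` — fifty thin vessels with true diameters an even grid
  over 1.78–3.19 μm, one vessel per z-slice across ten stacks at the
  default anisotropic spacing, with PSF blur and Poisson noise (scale 1).
  Additive Gaussian noise of σ 15 on a background of 10 was rejected for
  this suite as unphysical — it clips ~40% of background at zero and the
  clipped histogram drags the iterative-selection threshold into the
  noise floor; the 200-vs-10-contrast Gaussian-σ15 condition is exercised
  separately on the straight-tube geometry where it is the stated test
  condition.

What the phantoms do *not* emulate: depth-dependent attenuation, clearing
artifacts, tile-stitching seams, vessel wrinkliness or caliber variation
along real microvessels, and partial-volume intensity (voxels are binary
before blurring).  Passing phantom tests therefore demonstrates correct
geometry, topology and calibration of the algorithms under controlled
imaging physics — not segmentation accuracy on real tissue, which depends
on labeling quality and background structure that only a manual audit of
real data can quantify.

## Problem sizes in the test and reproduction runs

The shipped suites are sized for a single CPU: straight tubes are 30–40³×90
voxel volumes, the thin-vessel suite is ten 7×100×100 stacks, the
threshold oracle runs 1000 random ≤ 16×16×4 volumes against an exhaustive
fixed-point scan.  These sizes were chosen so the complete acceptance run
finishes in seconds while every measured quantity (Dice, diameter error,
branch counts) is already stable to the reported precision across seeds.

## Known limitations

* The thinning is sequential and exact rather than parallel and
  approximate; very large volumes (≫ 10⁷ foreground voxels) will be slow.
* Radius estimates below ~1 voxel are dominated by the lattice (a
  one-voxel-wide line reads radius = one lateral spacing); in the
  thin-vessel regime the traced diameter is accordingly biased upward by
  roughly one voxel, which is why validation there compares against the
  image-based FWHM measurement rather than the sub-voxel analytic truth.
* Vessels running near the optical axis at high anisotropy are thinned on
  the grid, not in physical space; their centerlines may zigzag axially.
* No gap-closing: a vessel fragmented by the threshold stays fragmented in
  the graph.
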