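"""End-to-end recovery experiments on phantom suites.

These routines run the pipeline on synthetic phantoms with analytic ground
truth and measure how well each stage recovers it: threshold agreement
with a brute-force fixed-point scan, segmentation Dice under noise, radius
and branch-topology recovery, and the manual-vs-traced diameter protocol
on thin vessels at confocal spacing.  They are shared by the test suite
and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .phantoms import PhantomSpec, Tube, generate_phantom, phantom_suite
from .quantify_validate import (
    main_path,
    profile_diameter,
    score_segmentation,
    select_path_nodes,
)
from .segmentation import SegmentationParams, iterative_selection_threshold, segment_stack
from .tracing import trace
from .volio import BinaryMask, VesselGraph


# ---------------------------------------------------------------------------
# threshold oracle

def threshold_fixed_points(values, tol: float = 0.5) -> list[float]:
    """Brute-force scan of every candidate iterative-selection fixed point.

    For each split of the sorted values into a low part of size ``k`` and
    the rest, the candidate ``t = (mean(low) + mean(high)) / 2`` is a fixed
    point iff the split it induces is the split it came from, i.e.
    ``v[k-1] <= t < v[k]``.  All self-consistent candidates are returned
    (a ``tol``-relaxation keeps candidates whose induced update moves by
    at most ``tol``).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    csum = np.cumsum(v)
    out = []
    for k in range(1, n):
        if v[k - 1] == v[k]:
            continue  # same split as a neighboring k
        mu_low = csum[k - 1] / k
        mu_high = (csum[-1] - csum[k - 1]) / (n - k)
        t = 0.5 * (mu_low + mu_high)
        if v[k - 1] - tol <= t < v[k] + tol:
            out.append(float(t))
    return out


def threshold_oracle_trials(n_trials: int = 1000, seed: int = 0, tol: float = 0.5):
    """Match rate of the iterative threshold against the exhaustive scan.

    Draws random small 8-bit volumes (mixtures of two intensity classes
    plus uniform outliers, plus fully uniform images) and checks that the
    iterated threshold lies within ``tol`` of some brute-force fixed point.
    """
    rng = np.random.default_rng(seed)
    matches = 0
    done = 0
    while done < n_trials:
        shape = tuple(int(rng.integers(2, s)) for s in (17, 17, 5))
        if rng.random() < 0.5:
            lo = int(rng.integers(0, 100))
            hi = int(rng.integers(lo + 20, 256))
            p_fg = float(rng.uniform(0.05, 0.5))
            img = np.where(
                rng.random(shape) < p_fg,
                rng.integers(max(0, hi - 20), hi + 1, shape),
                rng.integers(lo, lo + 21, shape),
            )
        else:
            img = rng.integers(0, 256, shape)
        img = img.astype(np.uint8)
        if img.min() == img.max():
            continue  # constant draw: no threshold defined, redraw
        done += 1
        t = iterative_selection_threshold(img, tol=tol)
        candidates = threshold_fixed_points(img, tol=tol)
        if candidates and min(abs(t - c) for c in candidates) <= tol:
            matches += 1
    return matches, n_trials


def threshold_oracle_match_rate(n_trials: int = 1000, seed: int = 0) -> float:
    matches, total = threshold_oracle_trials(n_trials=n_trials, seed=seed)
    return matches / total


# ---------------------------------------------------------------------------
# segmentation recovery

def dice(auto: BinaryMask, truth: BinaryMask) -> float:
    return score_segmentation(auto.voxels, truth.voxels).dice


def noisy_straight_suite(seed: int = 0, n_phantoms: int = 20, noise_sigma: float = 15.0):
    """Seeded suite of noisy straight-tube phantoms (contrast 200 vs 10).

    Radii cycle over 2–8 voxels at isotropic 1 μm spacing with additive
    Gaussian noise; no PSF, so the truth mask is the exact noise-free
    foreground.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_phantoms):
        radius = 2 + (i % 7)
        ny = nz = 2 * radius + 14
        nx = 60
        cy = ny // 2 + float(rng.uniform(-0.3, 0.3))
        cz = nz // 2 + float(rng.uniform(-0.3, 0.3))
        spec = PhantomSpec(
            shape=(nz, ny, nx),
            tubes=(Tube(np.array([[cz, cy, 0.0], [cz, cy, nx - 1.0]]), float(radius)),),
            spacing=(1.0, 1.0, 1.0),
            foreground=200.0, background=10.0,
            psf_sigma=(0.0, 0.0, 0.0),
            noise=("gaussian", noise_sigma),
            seed=int(rng.integers(2**31)),
        )
        out.append((spec, generate_phantom(spec)))
    return out


def noisy_dice_scores(seed: int = 0, n_phantoms: int = 20, noise_sigma: float = 15.0,
                      min_component_voxels: int = 27) -> list[float]:
    """Per-phantom Dice of segmentation vs truth on the noisy suite."""
    params = SegmentationParams(min_component_voxels=min_component_voxels)
    scores = []
    for _spec, (stack, truth, _graph) in noisy_straight_suite(seed, n_phantoms, noise_sigma):
        mask = segment_stack(stack, params)
        scores.append(dice(mask, truth))
    return scores


# ---------------------------------------------------------------------------
# radius recovery

def interior_path_diameters(graph: VesselGraph, exclude_arc_um: float = 2.0) -> np.ndarray:
    """Diameters (2·radius) of main-path nodes away from the path ends.

    Nodes within ``exclude_arc_um`` of arc length from either end are
    dropped: near an open tube end both the thinned centerline and the
    distance transform are corrupted over roughly one tube radius, so
    callers typically exclude one to two radii of arc.  If the exclusion
    would empty the path, the full path is used.
    """
    path = main_path(graph)
    by_id = {n.id: n for n in graph.nodes}
    pts = np.array([[by_id[i].z, by_id[i].y, by_id[i].x] for i in path])
    diam = np.array([2.0 * by_id[i].radius for i in path])
    if len(path) < 3:
        return diam
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    keep = (arc >= exclude_arc_um) & (arc <= arc[-1] - exclude_arc_um)
    return diam[keep] if keep.any() else diam


def radius_recovery(seed: int = 0) -> dict[int, float]:
    """Mean interior diameter error (voxels) per true radius 2..8.

    Runs the straight suite through segmentation-free tracing (the truth
    mask is traced directly, isolating the radius estimator from
    segmentation), returning ``{true_radius: mean interior diameter}``.
    """
    out = {}
    for spec, (_stack, truth, _graph) in phantom_suite("straight", seed=seed):
        r_true = float(np.asarray(spec.tubes[0].radius).max())
        graph = trace(truth)
        diams = interior_path_diameters(graph, exclude_arc_um=2.0 * r_true)
        out[int(round(r_true))] = float(diams.mean())
    return out


# ---------------------------------------------------------------------------
# topology recovery

def branch_node_count(graph: VesselGraph) -> int:
    """Number of nodes with more than two neighbors (bifurcation nodes)."""
    g = graph.to_networkx()
    return sum(1 for _n, deg in g.degree if deg > 2)


def branching_recovery(seed: int = 0) -> list[tuple[int, int]]:
    """(constructed, traced) bifurcation counts for every branching phantom.

    Each phantom is segmented noise-free from its rendered stack and traced;
    the constructed count comes from the truth graph.
    """
    results = []
    for _spec, (stack, truth, truth_graph) in phantom_suite("branching", seed=seed):
        constructed = branch_node_count(truth_graph)
        mask = segment_stack(stack, SegmentationParams(min_component_voxels=27))
        traced = branch_node_count(trace(mask))
        results.append((constructed, traced))
    return results


# ---------------------------------------------------------------------------
# thin-vessel end-to-end protocol

def thin_vessel_experiment(seed: int = 0) -> dict:
    """Thin-vessel end-to-end run: segmentation quality plus the
    five-point manual-vs-traced diameter protocol.

    For every volume of the ``thin-vessel`` suite, the stack is segmented
    and scored voxelwise against the truth mask.  For every vessel, a
    "manual" diameter is measured as the mean of five perpendicular FWHM
    profiles on the vessel's image slice, and the traced diameter as the
    mean of five nodes along the traced centerline of that slice; the two
    are compared by absolute difference.

    Returns per-volume sensitivity/specificity/dice lists and per-vessel
    absolute diameter differences (μm), with lateral pixel size for
    voxel-unit conversion.
    """
    suite = phantom_suite("thin-vessel", seed=seed)
    params = SegmentationParams()
    sens, spec_, dices, diffs = [], [], [], []
    pixel_size = None
    for pspec, (stack, truth, _tg) in suite:
        dz, dy, dx = pspec.spacing
        pixel_size = dy
        mask = segment_stack(stack, params)
        s = score_segmentation(mask.voxels, truth.voxels)
        sens.append(s.sensitivity)
        spec_.append(s.specificity)
        dices.append(s.dice)
        for tube in pspec.tubes:
            d = _vessel_diameter_difference(stack, mask, tube, (dz, dy, dx))
            if d is not None:
                diffs.append(d)
    return {
        "sensitivity": sens,
        "specificity": spec_,
        "dice": dices,
        "abs_diameter_diff_um": diffs,
        "pixel_size_um": pixel_size,
    }


def _vessel_diameter_difference(stack, mask, tube: Tube, spacing) -> float | None:
    """Manual (FWHM) vs traced mean diameter for one in-plane vessel."""
    dz, dy, dx = spacing
    p0, p1 = tube.points[0], tube.points[-1]
    k = int(round(p0[0] / dz))
    image = stack.voxels[k].astype(float)

    # manual protocol: five perpendicular FWHM profiles along the vessel
    direction = (p1 - p0)[1:]  # (y, x) μm
    direction = direction / np.linalg.norm(direction)
    perp = np.array([direction[1], -direction[0]])  # (i, j) pixel direction
    manual = []
    for frac in np.linspace(0.0, 1.0, 7)[1:-1][:5]:
        pt_um = p0[1:] + frac * (p1 - p0)[1:]
        pt_px = (pt_um[0] / dy, pt_um[1] / dx)
        try:
            manual.append(
                profile_diameter(image, pt_px, tuple(perp), pixel_size=dy)
            )
        except ValueError:
            continue
    if len(manual) < 3:
        return None

    # traced protocol: five nodes along the traced centerline of this slice
    slice_mask = np.zeros(mask.shape, dtype=bool)
    slice_mask[k] = mask.voxels[k]
    graph = trace(BinaryMask(slice_mask, mask.spacing))
    if len(graph) < 3:
        return None
    nodes = select_path_nodes(graph, n=5)
    traced = [2.0 * n.radius for n in nodes]
    return abs(float(np.mean(manual)) - float(np.mean(traced)))
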