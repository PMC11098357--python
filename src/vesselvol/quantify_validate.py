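"""Quantification and validation of segmented / traced vasculature.

Two validation protocols are provided, mirroring how automated output is
audited against a human rater:

* **Segmentation scoring** — random regions of interest (default
  50x50x5 voxels) are sampled from a volume, each ROI is flattened to a
  z-axis maximum intensity projection, and the automated mask is scored
  against the manual mask pixelwise (sensitivity, specificity, Dice),
  summarized as mean ± sample SD across ROIs.
* **Diameter comparison** — a "manual" diameter is the mean of five
  perpendicular-line full-width-at-half-maximum measurements on a MIP; the
  traced diameter is the mean of five node diameters along the same
  vessel; the two means are compared by absolute difference.

Density and per-node diameter distributions cover the routine
quantification of binary vessel volumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import BinaryMask, SwcNode, VesselGraph

logger = logging.getLogger(__name__)

#: Default ROI extent in voxels, (dk, di, dj) = 5 slices of 50x50 pixels.
DEFAULT_ROI_EXTENT: tuple[int, int, int] = (5, 50, 50)


class RoiError(ValueError):
    """Invalid ROI geometry or exhausted ROI sampling budget."""


class NoVesselError(ValueError):
    """An intensity profile never rises above half maximum."""


class EmptyGraphError(ValueError):
    """A quantification was requested on a graph with no nodes."""


# ---------------------------------------------------------------------------
# ROI handling

@dataclass(frozen=True)
class RoiSpec:
    """A half-open subvolume ``[origin, origin + extent)`` in voxel indices."""

    origin: tuple[int, int, int]
    extent: tuple[int, int, int] = DEFAULT_ROI_EXTENT

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.origin) or any(e < 1 for e in self.extent):
            raise RoiError(f"invalid ROI origin={self.origin} extent={self.extent}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + e) for o, e in zip(self.origin, self.extent))

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        if any(o + e > s for o, e, s in zip(self.origin, self.extent, shape)):
            raise RoiError(f"ROI {self} exceeds volume shape {shape}")


def sample_rois(
    shape: tuple[int, int, int],
    extent: tuple[int, int, int] = DEFAULT_ROI_EXTENT,
    n: int = 100,
    seed: int = 0,
    reference: BinaryMask | None = None,
    max_retries: int = 1000,
) -> list[RoiSpec]:
    """Draw ``n`` random in-bounds ROIs with origins uniform over valid
    positions.

    If ``reference`` is given, ROIs whose reference subvolume contains no
    foreground are rejected and redrawn (up to ``max_retries`` draws per
    ROI), so every returned ROI contains vessel signal.  The same seed
    always yields the same list.
    """
    if n < 1:
        raise RoiError("n must be >= 1")
    span = [s - e for s, e in zip(shape, extent)]
    if any(v < 0 for v in span):
        raise RoiError(f"extent {extent} does not fit inside shape {shape}")
    rng = np.random.default_rng(seed)
    rois: list[RoiSpec] = []
    for _ in range(n):
        for _attempt in range(max_retries):
            origin = tuple(int(rng.integers(0, v + 1)) for v in span)
            roi = RoiSpec(origin, tuple(extent))
            if reference is None or reference.voxels[roi.slices()].any():
                rois.append(roi)
                break
        else:
            raise RoiError(
                f"could not find a vessel-containing ROI in {max_retries} draws"
            )
    return rois


# ---------------------------------------------------------------------------
# confusion-count scoring

@dataclass(frozen=True)
class SegmentationScore:
    """Pixelwise confusion counts with the manual mask as ground truth.

    The derived fractions follow the usual definitions; a fraction whose
    denominator is zero is reported as NaN (undefined, never coerced to 0
    or 1) and excluded from summaries.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pixels(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def dice(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else math.nan


def score_segmentation(auto, manual) -> SegmentationScore:
    """Score an automated binary array against a manual one (ground truth).

    Works on 2D MIPs or 3D subvolumes; shapes must match exactly.
    """
    a = np.asarray(auto).astype(bool)
    m = np.asarray(manual).astype(bool)
    if a.shape != m.shape:
        raise ValueError(f"shape mismatch: auto {a.shape} vs manual {m.shape}")
    tp = int(np.count_nonzero(a & m))
    fp = int(np.count_nonzero(a & ~m))
    fn = int(np.count_nonzero(~a & m))
    tn = int(np.count_nonzero(~a & ~m))
    return SegmentationScore(tp=tp, fp=fp, tn=tn, fn=fn)


_METRICS = ("sensitivity", "specificity", "dice")


def validate_segmentation(
    auto_mask: BinaryMask,
    manual_mask: BinaryMask,
    rois: list[RoiSpec],
    mode: str = "mip",
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Score an automated mask against a manual mask over a set of ROIs.

    ``mode="mip"`` (default) compares the z-axis maximum intensity
    projection of each ROI subvolume — the form a human rater traces;
    ``mode="3d"`` compares the subvolumes voxelwise.

    Returns
    -------
    table : pandas.DataFrame
        One row per ROI with origin, counts, and the three metrics.
    summary : dict
        ``{metric: (mean, sd)}`` across ROIs, with sample (n-1) standard
        deviation; a single ROI reports SD 0 with a logged warning, and
        NaN (undefined) metrics are excluded with a logged count.
    """
    if mode not in ("mip", "3d"):
        raise ValueError(f"mode must be 'mip' or '3d', got {mode!r}")
    if not auto_mask.same_geometry(manual_mask):
        raise ValueError("auto and manual masks must share shape and spacing")
    rows = []
    for roi in rois:
        roi.check_inside(auto_mask.shape)
        a = auto_mask.voxels[roi.slices()]
        m = manual_mask.voxels[roi.slices()]
        if mode == "mip":
            a, m = a.max(axis=0), m.max(axis=0)
        s = score_segmentation(a, m)
        rows.append(
            {
                "k": roi.origin[0], "i": roi.origin[1], "j": roi.origin[2],
                "tp": s.tp, "fp": s.fp, "tn": s.tn, "fn": s.fn,
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "dice": s.dice,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 1:
        logger.warning("validate_segmentation: single ROI, reporting SD = 0")
    summary: dict[str, tuple[float, float]] = {}
    for metric in _METRICS:
        col = table[metric].dropna()
        n_undef = len(table) - len(col)
        if n_undef:
            logger.info("validate_segmentation: %d undefined %s value(s) excluded", n_undef, metric)
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        summary[metric] = (mean, sd)
    return table, summary


# ---------------------------------------------------------------------------
# diameter measurement

def profile_diameter(
    image: np.ndarray,
    point: tuple[float, float],
    direction: tuple[float, float],
    pixel_size: float,
    background: float | None = None,
    step_px: float = 0.05,
    max_len_px: float | None = None,
) -> float:
    """Full width at half maximum of a perpendicular intensity profile.

    Emulates the manual measurement of a vessel on a MIP: intensity is
    sampled by linear interpolation along the line through ``point`` with
    the given ``direction`` (in (i, j) = (row, col) image components), and
    the diameter is the FWHM above background of the profile's central
    lobe, in μm.

    ``background`` defaults to the median of the outer 20% of the sampled
    profile — an explicit, configurable stand-in for the rater's visual
    judgment of the local background level.

    Raises :class:`NoVesselError` when the profile never rises above its
    half-maximum level around ``point``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    i0, j0 = float(point[0]), float(point[1])
    if not (0 <= i0 <= img.shape[0] - 1 and 0 <= j0 <= img.shape[1] - 1):
        raise ValueError(f"point {point} outside image of shape {img.shape}")
    d = np.asarray(direction, dtype=float)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    if max_len_px is None:
        max_len_px = float(max(img.shape))
    s = np.arange(-max_len_px, max_len_px + step_px / 2, step_px)
    coords = np.stack([i0 + s * d[0], j0 + s * d[1]])
    inside = (
        (coords[0] >= 0) & (coords[0] <= img.shape[0] - 1)
        & (coords[1] >= 0) & (coords[1] <= img.shape[1] - 1)
    )
    s = s[inside]
    profile = ndimage.map_coordinates(img, coords[:, inside], order=1, mode="nearest")
    if background is None:
        n_outer = max(1, int(0.1 * len(profile)))
        background = float(np.median(np.concatenate([profile[:n_outer], profile[-n_outer:]])))

    # climb from the sample nearest the point to the local peak of the
    # central lobe, then walk outward to the half-maximum crossings
    center = int(np.argmin(np.abs(s)))
    peak = center
    while peak + 1 < len(profile) and profile[peak + 1] > profile[peak]:
        peak += 1
    left_peak = center
    while left_peak - 1 >= 0 and profile[left_peak - 1] > profile[left_peak]:
        left_peak -= 1
    peak = peak if profile[peak] >= profile[left_peak] else left_peak
    if profile[peak] <= background:
        raise NoVesselError(f"no intensity peak above background at point {point}")
    half = background + 0.5 * (profile[peak] - background)

    def _crossing(start: int, step: int) -> float:
        idx = start
        while 0 <= idx + step < len(profile):
            nxt = idx + step
            if profile[nxt] < half:
                # linear interpolation between samples
                frac = (profile[idx] - half) / (profile[idx] - profile[nxt])
                return s[idx] + frac * (s[nxt] - s[idx])
            idx = nxt
        raise NoVesselError(
            f"profile never falls below half maximum within {max_len_px} px of {point}"
        )

    right = _crossing(peak, +1)
    left = _crossing(peak, -1)
    return float((right - left) * pixel_size)


@dataclass(frozen=True)
class DiameterComparison:
    """Manual-vs-traced diameter agreement for one vessel (μm)."""

    manual_mean: float
    traced_mean: float

    @property
    def abs_difference(self) -> float:
        return abs(self.manual_mean - self.traced_mean)


def compare_vessel_diameter(
    manual, traced, expected_count: int = 5
) -> DiameterComparison:
    """Compare the mean of manual perpendicular-line diameters with the
    mean of traced node diameters for one vessel.

    Both sets must contain exactly ``expected_count`` strictly positive μm
    values (five by default, matching the measurement protocol).
    """
    manual = np.asarray(manual, dtype=float)
    traced = np.asarray(traced, dtype=float)
    for name, vals in (("manual", manual), ("traced", traced)):
        if vals.shape != (expected_count,):
            raise ValueError(f"{name} must hold exactly {expected_count} values, got {vals.shape}")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"{name} diameters must be positive and finite")
    return DiameterComparison(float(manual.mean()), float(traced.mean()))


# ---------------------------------------------------------------------------
# quantification

def vessel_density(mask: BinaryMask, region: RoiSpec | None = None) -> float:
    """Foreground voxel fraction of a region (whole volume if ``None``)."""
    vox = mask.voxels
    if region is not None:
        region.check_inside(mask.shape)
        vox = vox[region.slices()]
    if vox.size == 0:
        raise RoiError("empty region")
    return float(np.count_nonzero(vox)) / vox.size


def diameter_summary(graph: VesselGraph) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-node diameter table and distribution statistics.

    Diameters are ``2 * radius`` per node (μm).  Returns the node table and
    ``{"mean", "sd", "min", "max", "n"}`` over all nodes; SD is the sample
    (n-1) standard deviation, 0 for a single node.
    """
    if len(graph) == 0:
        raise EmptyGraphError("cannot summarize an empty graph")
    table = graph.to_dataframe()
    table["diameter"] = 2.0 * table["radius"]
    d = table["diameter"].to_numpy()
    stats = {
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "min": float(d.min()),
        "max": float(d.max()),
        "n": int(len(d)),
    }
    return table, stats


# ---------------------------------------------------------------------------
# node selection along a traced vessel

def _component_paths(graph: VesselGraph):
    import networkx as nx

    g = graph.to_networkx()
    pos = {n.id: np.array([n.z, n.y, n.x]) for n in graph.nodes}
    for u, v in g.edges:
        g.edges[u, v]["length"] = float(np.linalg.norm(pos[u] - pos[v]))
    return g


def main_path(graph: VesselGraph) -> list[int]:
    """Node ids of the longest arc-length path in the largest component.

    Found by double-Dijkstra (farthest node from an arbitrary start, then
    farthest from that), exact on trees — which traced components are.
    """
    import networkx as nx

    if len(graph) == 0:
        raise EmptyGraphError("empty graph has no path")
    g = _component_paths(graph)
    comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(comp)
    start = min(comp)
    dist = nx.single_source_dijkstra_path_length(sub, start, weight="length")
    a = max(dist, key=lambda k: (dist[k], -k))
    dist_a, paths_a = nx.single_source_dijkstra(sub, a, weight="length")
    b = max(dist_a, key=lambda k: (dist_a[k], -k))
    return paths_a[b]


def select_path_nodes(graph: VesselGraph, n: int = 5) -> list[SwcNode]:
    """Nodes nearest to ``n`` equally spaced arc-length positions along the
    traced vessel's main path.

    Target positions are the interior points of an (n+2)-point uniform
    subdivision of the path, so endpoints (whose radii are biased by open
    vessel ends) are never selected.
    """
    path = main_path(graph)
    by_id = {node.id: node for node in graph.nodes}
    pts = np.array([[by_id[i].z, by_id[i].y, by_id[i].x] for i in path])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n + 2)[1:-1]
    chosen = []
    for t in targets:
        idx = int(np.argmin(np.abs(arc - t)))
        chosen.append(by_id[path[idx]])
    return chosen
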