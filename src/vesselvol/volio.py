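"""Image-stack and vessel-graph I/O with a single geometric convention.

Arrays are indexed ``(z, y, x)``; ``spacing`` is ``(dz, dy, dx)`` in
micrometres per voxel.  Physical coordinates map voxel *centers*:
``x = j * dx``, ``y = i * dy``, ``z = k * dz`` for 0-based indices
``(k, i, j)``.  Voxel spacing is never read from TIFF tags (dialects vary
too much to trust); it is an explicit input everywhere, with a default
derived from a 50x50x5-voxel region spanning 113x113x38 μm — the geometry
of the confocal stacks this tool targets.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile

#: Default voxel spacing (dz, dy, dx) in μm: 38/5 axially, 113/50 laterally.
DEFAULT_SPACING: tuple[float, float, float] = (7.6, 2.26, 2.26)

#: SWC structure-type code written for vessel nodes (7 = custom).
SWC_VESSEL_TYPE = 7

#: SWC parent id marking a root node.
SWC_ROOT_PARENT = -1


# ---------------------------------------------------------------------------
# errors

class StackIOError(Exception):
    """Base class for image-stack I/O failures."""


class MissingFileError(StackIOError, FileNotFoundError):
    """The requested stack file does not exist."""


class MultiChannelImageError(StackIOError):
    """The TIFF holds multi-channel / RGB pages; only single-channel
    grayscale stacks are supported."""


class EmptyStackError(StackIOError):
    """The TIFF contains zero pages or zero-sized pages."""


class SwcParseError(Exception):
    """Base class for malformed SWC input."""


class DuplicateNodeIdError(SwcParseError):
    """Two SWC rows share the same node id."""


class DanglingParentError(SwcParseError):
    """A node references a parent id that is not defined in the file."""


class NonPositiveRadiusError(SwcParseError):
    """A node radius is zero, negative, or non-finite."""


class CyclicParentError(SwcParseError):
    """Parent links form a cycle instead of a forest."""


# ---------------------------------------------------------------------------
# geometry types

def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not math.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive finite μm values, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class VolumeStack:
    """A 3D single-channel intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(nz, ny, nx)`` with finite, non-negative
        intensities (arbitrary fluorescence units).
    spacing
        ``(dz, dy, dx)`` voxel pitch in μm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be a non-empty 3D array, got shape {vox.shape}")
        if np.issubdtype(vox.dtype, np.floating):
            if not np.isfinite(vox).all():
                raise ValueError("intensities must be finite")
        if vox.size and vox.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge lengths of the volume in μm (``shape * spacing``)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class BinaryMask:
    """Boolean vessel/background labeling sharing a stack's geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"mask must be a non-empty 3D array, got shape {vox.shape}")
        vox = vox.astype(bool, copy=False)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing


@dataclass(frozen=True)
class SwcNode:
    """One node of a traced vessel tree (SWC row).

    Coordinates are physical μm; ``radius`` is the vessel radius in μm
    (diameter = 2·radius).  ``parent`` is another node id or -1 for roots.
    """

    id: int
    x: float
    y: float
    z: float
    radius: float
    parent: int = SWC_ROOT_PARENT
    type: int = SWC_VESSEL_TYPE


class VesselGraph:
    """Traced centerline: nodes with per-node radius, edges via parent links.

    The parent links must form a forest (acyclic, every non-root parent
    defined); this is validated at construction.
    """

    def __init__(self, nodes: list[SwcNode] | None = None):
        self.nodes: list[SwcNode] = list(nodes) if nodes else []
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        seen: set[int] = set()
        for i in ids:
            if i in seen:
                raise DuplicateNodeIdError(f"duplicate node id {i}")
            if i <= 0:
                raise SwcParseError(f"node ids must be positive, got {i}")
            seen.add(i)
        for n in self.nodes:
            if not math.isfinite(n.radius) or n.radius <= 0:
                raise NonPositiveRadiusError(f"node {n.id} has radius {n.radius}")
            if n.parent != SWC_ROOT_PARENT and n.parent not in seen:
                raise DanglingParentError(f"node {n.id} references missing parent {n.parent}")
        # cycle check by walking each parent chain with a visited color map
        parent = {n.id: n.parent for n in self.nodes}
        state: dict[int, int] = {}  # 0 in-progress, 1 done
        for start in parent:
            chain = []
            cur = start
            while cur != SWC_ROOT_PARENT and state.get(cur) != 1:
                if state.get(cur) == 0:
                    raise CyclicParentError(f"parent links cycle through node {cur}")
                state[cur] = 0
                chain.append(cur)
                cur = parent[cur]
            for c in chain:
                state[c] = 1

    # -- basic queries ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    @property
    def roots(self) -> list[int]:
        return [n.id for n in self.nodes if n.parent == SWC_ROOT_PARENT]

    @property
    def edges(self) -> list[tuple[int, int]]:
        """(child, parent) pairs."""
        return [(n.id, n.parent) for n in self.nodes if n.parent != SWC_ROOT_PARENT]

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes], dtype=float)

    def positions(self) -> np.ndarray:
        """Node positions as an ``(n, 3)`` array of (z, y, x) μm."""
        return np.array([[n.z, n.y, n.x] for n in self.nodes], dtype=float).reshape(-1, 3)

    def to_networkx(self):
        """Undirected graph on node ids; node attrs hold position/radius."""
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, x=n.x, y=n.y, z=n.z, radius=n.radius)
        g.add_edges_from(self.edges)
        return g

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [(n.id, n.type, n.x, n.y, n.z, n.radius, n.parent) for n in self.nodes],
            columns=["id", "type", "x", "y", "z", "radius", "parent"],
        )


# ---------------------------------------------------------------------------
# TIFF stack I/O

def read_stack(path: str | os.PathLike, spacing=DEFAULT_SPACING) -> VolumeStack:
    """Read a single-channel multi-page TIFF as a :class:`VolumeStack`.

    Page order becomes the z axis; a single-page TIFF yields shape
    ``(1, H, W)``.  Intensities are preserved bit-exactly.
    """
    if not os.path.exists(path):
        raise MissingFileError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) == 0:
            raise EmptyStackError(f"stack {path} has no pages")
        series = tf.series[0]
        # 'S' = samples per pixel (RGB/RGBA), 'C' = channel axis
        if "S" in series.axes or "C" in series.axes:
            raise MultiChannelImageError(
                f"expected single-channel grayscale pages, got axes {series.axes!r} in {path}"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise MultiChannelImageError(
            f"expected single-channel grayscale pages, got array of shape {arr.shape}"
        )
    if arr.size == 0:
        raise EmptyStackError(f"stack {path} has no pixels")
    return VolumeStack(arr, spacing)


def read_mask(path: str | os.PathLike, spacing=DEFAULT_SPACING) -> BinaryMask:
    """Read a TIFF as a boolean mask (any non-zero pixel is foreground)."""
    stack = read_stack(path, spacing)
    return BinaryMask(stack.voxels > 0, spacing)


def write_stack(stack: VolumeStack | BinaryMask, path: str | os.PathLike) -> None:
    """Write a stack or mask as a multi-page grayscale TIFF.

    Masks are written 8-bit with foreground 255 and background 0; intensity
    stacks keep their dtype so a read-back is bit-identical.
    """
    if isinstance(stack, BinaryMask):
        data = np.where(stack.voxels, np.uint8(255), np.uint8(0))
    else:
        data = stack.voxels
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


# ---------------------------------------------------------------------------
# SWC I/O

def read_swc(path: str | os.PathLike) -> VesselGraph:
    """Parse an SWC morphology file into a :class:`VesselGraph`.

    Expected format: whitespace-separated columns
    ``id type x y z radius parent``; lines starting with ``#`` are comments.
    Malformed files raise the named :class:`SwcParseError` subclasses.
    """
    if not os.path.exists(path):
        raise MissingFileError(f"no such SWC file: {path}")
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
            nodes.append(SwcNode(nid, x, y, z, radius, parent, ntype))
    return VesselGraph(nodes)


def write_swc(graph: VesselGraph, path: str | os.PathLike, comment: str | None = None) -> None:
    """Serialize a :class:`VesselGraph` to SWC text.

    Output is deterministic: nodes are written in their stored order with a
    fixed numeric format, so identical graphs produce byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for n in graph.nodes:
            fh.write(
                f"{n.id} {n.type} {n.x:.6f} {n.y:.6f} {n.z:.6f} {n.radius:.6f} {n.parent}\n"
            )
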