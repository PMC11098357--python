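"""Automatic vessel segmentation by iterative-selection thresholding.

The iterative selection (Ridler–Calvard / ISODATA) scheme picks the
threshold ``t`` that is the fixed point of

    t  <-  ( mean{ v : v <= t }  +  mean{ v : v > t } ) / 2

starting from the global mean.  It depends only on the intensity histogram
and needs no training or tuning, which is why it suits batch processing of
whole cleared-tissue sections.  Segmentation then keeps voxels strictly
above the threshold and discards tiny 26-connected specks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .volio import BinaryMask, VolumeStack

logger = logging.getLogger(__name__)

_AXES = {"z": 0, "y": 1, "x": 2}


class ConstantImageError(ValueError):
    """All intensities are equal; no threshold separates two classes."""


class ThresholdConvergenceError(RuntimeError):
    """The threshold iteration did not converge within ``max_iter``.

    Attributes
    ----------
    last_iterate : float
        The threshold value at the final iteration.
    """

    def __init__(self, msg: str, last_iterate: float):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of automated segmentation.

    threshold_scope
        ``"stack"`` computes one threshold for the whole volume (the
        default: sections are imaged through their full thickness and
        thresholded as a unit); ``"slice"`` thresholds each z-slice
        independently, useful when intensity attenuates with depth.
    convergence_tol
        Stop when the threshold moves by no more than this many intensity
        units between iterations (default 0.5, half a gray level of an
        integer image).
    max_iter
        Iteration cap; the scheme converges in a handful of steps on any
        finite histogram, so 200 is generous.
    min_component_voxels
        26-connected foreground components with fewer voxels than this are
        removed.  Default 27 (one 3x3x3 speckle).  The cleanup size is an
        explicit choice of this implementation and is echoed to logs.
    """

    threshold_scope: str = "stack"
    convergence_tol: float = 0.5
    max_iter: int = 200
    min_component_voxels: int = 27

    def __post_init__(self) -> None:
        if self.threshold_scope not in ("stack", "slice"):
            raise ValueError(f"threshold_scope must be 'stack' or 'slice', got {self.threshold_scope!r}")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")


def iterative_selection_threshold(
    intensities, tol: float = 0.5, max_iter: int = 200
) -> float:
    """Iterative-selection (Ridler–Calvard) threshold of an intensity set.

    Parameters
    ----------
    intensities
        Any array-like of intensity values (flattened internally).
    tol
        Convergence tolerance in intensity units.
    max_iter
        Maximum number of update steps.

    Returns
    -------
    float
        A threshold ``t`` with ``|t - (mu_low + mu_high)/2| <= tol`` where
        ``mu_low``/``mu_high`` are the means of values ``<= t`` / ``> t``.

    Raises
    ------
    ConstantImageError
        If fewer than two distinct values are present.
    ThresholdConvergenceError
        If ``max_iter`` is exhausted first (carries the last iterate).
    """
    values = np.sort(np.asarray(intensities, dtype=float).ravel())
    if values.size == 0:
        raise ConstantImageError("empty intensity collection")
    if values[0] == values[-1]:
        raise ConstantImageError(
            f"constant image (all intensities equal {values[0]}); no threshold exists"
        )
    cumsum = np.cumsum(values)
    n = values.size
    total = cumsum[-1]

    t = total / n  # global mean: strictly inside (min, max)
    for _ in range(max_iter):
        k = int(np.searchsorted(values, t, side="right"))  # count of values <= t
        # mean-update keeps t strictly inside (min, max), so 1 <= k < n
        mu_low = cumsum[k - 1] / k
        mu_high = (total - cumsum[k - 1]) / (n - k)
        t_new = 0.5 * (mu_low + mu_high)
        if abs(t_new - t) <= tol:
            return float(t_new)
        t = t_new
    raise ThresholdConvergenceError(
        f"threshold iteration did not converge within {max_iter} steps", last_iterate=float(t)
    )


def segment_stack(stack: VolumeStack, params: SegmentationParams | None = None) -> BinaryMask:
    """Convert a fluorescence stack into a binary vessel mask.

    Voxels strictly above the iterative-selection threshold are foreground
    (one threshold for the whole stack, or one per z-slice, per
    ``params.threshold_scope``); 26-connected components smaller than
    ``params.min_component_voxels`` are then removed.  An all-foreground or
    all-background result is returned with a logged warning, not an error.
    """
    params = params or SegmentationParams()
    vox = stack.voxels
    if params.threshold_scope == "stack":
        t = iterative_selection_threshold(vox, params.convergence_tol, params.max_iter)
        fg = vox > t
        logger.info("segment_stack: whole-stack threshold %.3f", t)
    else:
        fg = np.empty(vox.shape, dtype=bool)
        for k in range(vox.shape[0]):
            t = iterative_selection_threshold(vox[k], params.convergence_tol, params.max_iter)
            fg[k] = vox[k] > t
        logger.info("segment_stack: per-slice thresholds over %d slices", vox.shape[0])

    if params.min_component_voxels > 0:
        # connectivity=3 is full 26-connectivity in 3D; max_size is an
        # inclusive bound, so components *smaller than* the minimum go
        fg = morphology.remove_small_objects(
            fg, max_size=params.min_component_voxels - 1, connectivity=3
        )
    n_fg = int(fg.sum())
    if n_fg == 0:
        logger.warning("segment_stack produced an all-background mask")
    elif n_fg == fg.size:
        logger.warning("segment_stack produced an all-foreground mask")
    return BinaryMask(fg, stack.spacing)


def max_intensity_projection(stack: VolumeStack | BinaryMask, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection along one named axis.

    A MIP flattens a subvolume into the 2D image a rater can trace: each
    output pixel is the maximum along the projection axis, so the output
    maximum equals the stack maximum.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return stack.voxels.max(axis=_AXES[axis])
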