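"""ROI container and shape-criterion filtering of connected components.

A candidate region must look like a cell body: area within a plausible
window, centroid lying inside its own mask (rejects rings and crescents),
and convex-hull-to-area ratio no larger than the golden ratio (rejects
highly non-convex noise aggregates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

GOLDEN_RATIO = (1 + math.sqrt(5)) / 2

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(eq=False)
class ROI:
    """One segmented region of interest.

    ``pixels`` is the final (possibly dilation-corrected) mask as an (N, 2)
    integer array of (row, col) coordinates.  ``core_pixels`` is the
    pre-dilation mask; cores from different ROIs of one segmentation are
    pairwise disjoint and are what label images are rendered from.
    ``iteration`` is the 1-based segmentation iteration that produced the
    ROI, or 0 for ground-truth / unassigned ROIs.
    """

    pixels: np.ndarray
    iteration: int = 0
    core_pixels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=np.int64))
        if self.pixels.size == 0 or self.pixels.shape[1] != 2:
            raise ValueError("ROI mask must be a non-empty (N, 2) coordinate array")
        if self.core_pixels is None:
            self.core_pixels = self.pixels
        else:
            self.core_pixels = np.atleast_2d(np.asarray(self.core_pixels, dtype=np.int64))

    @property
    def area(self) -> int:
        return len(self.pixels)

    @cached_property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    @cached_property
    def solidity_ratio(self) -> float:
        """Convex-hull pixel area divided by mask pixel area (>= 1)."""
        return _hull_area(self._local_mask()) / self.area

    def _local_mask(self) -> np.ndarray:
        r0, c0 = self.pixels.min(axis=0)
        r1, c1 = self.pixels.max(axis=0)
        m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        m[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        return m

    def to_mask(self, shape: tuple[int, int], core: bool = False) -> np.ndarray:
        """Render the ROI as a full-frame boolean mask."""
        px = self.core_pixels if core else self.pixels
        m = np.zeros(shape, dtype=bool)
        m[px[:, 0], px[:, 1]] = True
        return m


@dataclass(frozen=True)
class ShapeCriteria:
    """Plausible-cell filter: area window and solidity cap.

    Defaults match a ~1.3 um/px wide-field recording where cell bodies span
    roughly 50-300 px; set ``a_max=inf`` for the local splitting step, where
    sub-regions shrink under higher thresholds.
    """

    a_min: float = 50.0
    a_max: float = 300.0
    solidity_max: float = GOLDEN_RATIO

    def __post_init__(self) -> None:
        if not (0 < self.a_min <= self.a_max):
            raise ValueError(f"need 0 < a_min <= a_max, got {self.a_min}, {self.a_max}")
        if not self.solidity_max > 1:
            raise ValueError("solidity_max must exceed 1")


def _hull_area(mask: np.ndarray) -> float:
    """Pixel count of the convex hull of a boolean mask."""
    n = int(mask.sum())
    if n < 3 or 1 in mask.shape:
        return float(n)  # a point or line is its own hull
    try:
        return float(convex_hull_image(mask).sum())
    except Exception:  # degenerate (e.g. collinear) point sets
        return float(n)


def _passes_shape(sub: np.ndarray, solidity_max: float) -> bool:
    """Centroid-inside and solidity checks on a cropped component mask."""
    rr, cc = np.nonzero(sub)
    cy = int(round(float(rr.mean())))
    cx = int(round(float(cc.mean())))
    if not sub[cy, cx]:
        return False
    return _hull_area(sub) / len(rr) <= solidity_max


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labeling."""
    return ndi.label(mask, structure=_STRUCT8)


def _surviving_components(
    mask: np.ndarray, criteria: ShapeCriteria, keep_oversize: bool
) -> tuple[np.ndarray, list[int], list]:
    lbl, n = label_components(mask)
    if n == 0:
        return lbl, [], []
    areas = np.bincount(lbl.ravel(), minlength=n + 1)
    keep: list[int] = []
    slices = ndi.find_objects(lbl)
    for i in range(1, n + 1):
        a = areas[i]
        if a < criteria.a_min:
            continue
        if a > criteria.a_max and not keep_oversize:
            continue
        sl = slices[i - 1]
        if not _passes_shape(lbl[sl] == i, criteria.solidity_max):
            continue
        keep.append(i)
    return lbl, keep, slices


def count_valid_rois(mask: np.ndarray, criteria: ShapeCriteria) -> int:
    """Number of 8-connected components passing all shape criteria.

    This is the objective the adaptive threshold search maximizes; oversize
    components never count.
    """
    _, keep, _ = _surviving_components(mask, criteria, keep_oversize=False)
    return len(keep)


def extract_rois(
    mask: np.ndarray,
    criteria: ShapeCriteria,
    keep_oversize: bool = False,
    iteration: int = 0,
    offset: tuple[int, int] = (0, 0),
) -> list[ROI]:
    """Extract surviving components of a binary mask as ROI objects.

    ``keep_oversize=True`` retains components larger than ``a_max`` (used for
    the final extraction, where oversized candidates are handed to local
    splitting rather than discarded).  ``offset`` shifts coordinates back to
    the full-image frame when ``mask`` is a cropped patch.
    """
    lbl, keep, slices = _surviving_components(mask, criteria, keep_oversize)
    out: list[ROI] = []
    dr, dc = offset
    for i in keep:
        sl = slices[i - 1]
        rr, cc = np.nonzero(lbl[sl] == i)
        px = np.column_stack(
            [rr + sl[0].start + dr, cc + sl[1].start + dc]
        ).astype(np.int64)
        out.append(ROI(pixels=px, iteration=iteration))
    return out
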