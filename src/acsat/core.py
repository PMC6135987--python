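"""The ACSAT outer loop: iterate global thresholding, split merged regions
locally, clear what was found, and stop when the global threshold converges.

Each iteration n runs the adaptive threshold search (FIBAT) on the current
working image I_n to obtain a threshold tau_n* and candidate ROIs (oversized
ones kept).  Each candidate is then recursively re-thresholded inside its own
dilated footprint (local FIBAT) to separate touching or overlapping cells.
The segmented ROIs are blanked out of the image (with a dilated margin so no
bright rim survives) and the next iteration runs at a naturally lower
threshold, picking up dimmer cells.  Iteration stops once the relative change
|tau_{n+1}* - tau_n*| / tau_1* falls below delta; the ROIs of the iteration
that triggers termination are not included in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage as ndi

from .collapse import CollapsedImage
from .fibat import FibatConfig, FibatResult, auto_epsilon, fibat
from .morphology import disk
from .rois import ROI, ShapeCriteria

logger = logging.getLogger(__name__)


class DegenerateImageError(RuntimeError):
    """Raised when the first global threshold is zero on a non-trivial image,
    which would make the relative-change termination ratio undefined."""


@dataclass(frozen=True)
class AcsatConfig:
    """Settings of the full segmentation loop.

    delta
        Termination fraction: stop when the global threshold changes by less
        than ``delta * tau_1*`` between iterations (default 10%).
    global_criteria / local_criteria
        Shape filters for the whole-image and the local splitting searches.
        Local splitting uses a smaller minimum area and no maximum, because
        sub-regions shrink under the higher local thresholds.
    clear_dilation_radius
        Disc radius (px) by which cleared ROI areas are grown before blanking.
    roi_dilation_radius
        Disc radius (px) of the size correction applied to locally split
        ROIs, preventing real cells from shrinking below the area minimum.
    """

    delta: float = 0.10
    global_criteria: ShapeCriteria = field(default_factory=ShapeCriteria)
    local_criteria: ShapeCriteria = field(
        default_factory=lambda: ShapeCriteria(a_min=20.0, a_max=np.inf)
    )
    clear_dilation_radius: int = 2
    roi_dilation_radius: int = 1
    max_iterations: int = 20
    local_recursion_depth: int = 10
    fibat: FibatConfig = field(default_factory=FibatConfig)

    def __post_init__(self) -> None:
        if not (0 < self.delta < 1):
            raise ValueError("delta must be in (0, 1)")
        if self.clear_dilation_radius < 0 or self.roi_dilation_radius < 0:
            raise ValueError("dilation radii must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    index: int
    tau_global: float
    n_before_local: int
    n_new_rois: int
    cumulative_rois: int


@dataclass
class Segmentation:
    """Full output of a segmentation run: ROIs tagged by iteration, per-
    iteration history, the configuration used, and the image shape."""

    rois: List[ROI]
    history: List[IterationRecord]
    config: AcsatConfig
    image_shape: tuple[int, int]

    @property
    def n_iterations(self) -> int:
        return len(self.history)

    @property
    def tau_trace(self) -> List[float]:
        return [rec.tau_global for rec in self.history]


def clear_rois(
    image: CollapsedImage, rois: List[ROI], radius: int
) -> CollapsedImage:
    """Blank the (dilated) union of ROI masks to zero; other pixels unchanged."""
    out = image.pixels.copy()
    if rois:
        union = np.zeros(image.shape, dtype=bool)
        for roi in rois:
            union[roi.pixels[:, 0], roi.pixels[:, 1]] = True
        if radius > 0:
            union = ndi.binary_dilation(union, structure=disk(radius))
        out[union] = 0.0
    return CollapsedImage(pixels=out, provenance=image.provenance)


def _dilate_and_clip(
    roi: ROI, footprint: np.ndarray, origin: tuple[int, int], radius: int
) -> ROI:
    """Grow a locally split ROI by a small disc, clipped to the parent
    footprint; the pre-dilation pixels are kept as the ROI core."""
    if radius == 0:
        return roi
    r0, c0 = origin
    local = np.zeros(footprint.shape, dtype=bool)
    local[roi.pixels[:, 0] - r0, roi.pixels[:, 1] - c0] = True
    grown = ndi.binary_dilation(local, structure=disk(radius)) & footprint
    rr, cc = np.nonzero(grown)
    return ROI(
        pixels=np.column_stack([rr + r0, cc + c0]),
        iteration=roi.iteration,
        core_pixels=roi.pixels,
    )


def local_split(
    roi: ROI,
    image: CollapsedImage,
    criteria: ShapeCriteria,
    config: FibatConfig,
    dilation_radius: int = 1,
    max_depth: int = 10,
    _depth: int = 0,
) -> List[ROI]:
    """Recursively re-threshold one candidate ROI to separate merged cells.

    The search runs on the image restricted to the ROI's dilated footprint
    (outside pixels treated as zero intensity).  Two or more resulting ROIs
    trigger recursion into each; exactly one (or none) stops the recursion.
    Returned ROIs are dilated by ``dilation_radius`` and clipped to the
    parent footprint.
    """
    h, w = image.shape
    pad = dilation_radius + 1
    r0 = max(int(roi.pixels[:, 0].min()) - pad, 0)
    r1 = min(int(roi.pixels[:, 0].max()) + pad + 1, h)
    c0 = max(int(roi.pixels[:, 1].min()) - pad, 0)
    c1 = min(int(roi.pixels[:, 1].max()) + pad + 1, w)

    footprint = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    footprint[roi.pixels[:, 0] - r0, roi.pixels[:, 1] - c0] = True
    if dilation_radius > 0:
        footprint = ndi.binary_dilation(footprint, structure=disk(dilation_radius))

    patch = CollapsedImage(
        pixels=np.where(footprint, image.pixels[r0:r1, c0:c1], 0.0),
        provenance=image.provenance,
    )
    result = fibat(patch, criteria, config)
    if len(result.rois) == 0:
        return [roi]  # re-thresholding found nothing plausible; keep the parent
    pieces = [
        ROI(pixels=r.pixels + np.array([r0, c0]), iteration=roi.iteration)
        for r in result.rois
    ]
    if len(pieces) == 1:
        return [_dilate_and_clip(pieces[0], footprint, (r0, c0), dilation_radius)]
    if _depth + 1 >= max_depth:
        logger.warning(
            "local split recursion depth cap (%d) reached; keeping %d pieces",
            max_depth,
            len(pieces),
        )
        return [
            _dilate_and_clip(p, footprint, (r0, c0), dilation_radius) for p in pieces
        ]
    out: List[ROI] = []
    for piece in pieces:
        out.extend(
            local_split(
                piece,
                image,
                criteria,
                config,
                dilation_radius=dilation_radius,
                max_depth=max_depth,
                _depth=_depth + 1,
            )
        )
    return out


def _deduplicate_cores(rois: List[ROI], claimed: np.ndarray) -> List[ROI]:
    """Enforce pairwise-disjoint pre-dilation cores (first come, first kept).

    ``claimed`` marks pixels already owned by earlier ROIs and is updated in
    place.  Overlaps are rare (they require a local-split footprint dilation
    to cross a sibling) but the disjointness contract is load-bearing for
    label images.
    """
    out: List[ROI] = []
    for roi in rois:
        px = roi.core_pixels
        free = ~claimed[px[:, 0], px[:, 1]]
        if not free.all():
            px = px[free]
            if px.size == 0:
                logger.debug("dropping ROI fully shadowed by earlier cores")
                continue
            roi = ROI(pixels=roi.pixels, iteration=roi.iteration, core_pixels=px)
        claimed[px[:, 0], px[:, 1]] = True
        out.append(roi)
    return out


def run_acsat(image: CollapsedImage, config: AcsatConfig = AcsatConfig()) -> Segmentation:
    """Run the full iterative segmentation on a collapsed image."""
    arr = image.pixels
    if arr.size == 0:
        raise ValueError("empty image")
    if float(arr.max()) == float(arr.min()):
        return Segmentation(rois=[], history=[], config=config, image_shape=arr.shape)

    fib_cfg = config.fibat
    if fib_cfg.epsilon == "auto":
        # the intensity resolution is a property of the original image; reuse
        # it for all iterations and all local patches
        fib_cfg = replace(fib_cfg, epsilon=auto_epsilon(arr))

    current = image
    result = fibat(current, config.global_criteria, fib_cfg)
    tau1 = result.tau_star
    if tau1 <= 0:
        raise DegenerateImageError(
            f"first global threshold is {tau1!r}; the relative-change "
            "termination criterion is undefined for this image"
        )

    all_rois: List[ROI] = []
    history: List[IterationRecord] = []
    claimed = np.zeros(arr.shape, dtype=bool)
    tau_n = tau1
    for n in range(1, config.max_iterations + 1):
        candidates = result.rois
        split: List[ROI] = []
        for cand in candidates:
            cand.iteration = n
            split.extend(
                local_split(
                    cand,
                    current,
                    config.local_criteria,
                    fib_cfg,
                    dilation_radius=config.roi_dilation_radius,
                    max_depth=config.local_recursion_depth,
                )
            )
        for roi in split:
            roi.iteration = n
        split = _deduplicate_cores(split, claimed)
        all_rois.extend(split)
        history.append(
            IterationRecord(
                index=n,
                tau_global=tau_n,
                n_before_local=len(candidates),
                n_new_rois=len(split),
                cumulative_rois=len(all_rois),
            )
        )
        if n == config.max_iterations:
            break
        current = clear_rois(current, split, config.clear_dilation_radius)
        result = fibat(current, config.global_criteria, fib_cfg)
        tau_next = result.tau_star
        if abs(tau_next - tau_n) / tau1 < config.delta:
            break
        tau_n = tau_next

    return Segmentation(
        rois=all_rois, history=history, config=config, image_shape=arr.shape
    )
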