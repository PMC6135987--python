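"""Fluorescence-intensity-based adaptive thresholding (FIBAT).

FIBAT selects the intensity threshold that maximizes the number of valid
ROIs (components passing the shape criteria).  Instead of sweeping the whole
intensity range at fine resolution, it samples T thresholds uniformly over a
search range, finds the thresholds yielding the maximum count, and narrows
the range to bracket all of them — one sample beyond on each side, clipped at
the range ends.  The search stops when the candidate range is narrower than
the intensity resolution epsilon, or when it retains at least a fraction
alpha of the previous range (further refinement would change little).  The
optimal threshold tau* is the midpoint of the smallest and largest
count-maximizing thresholds of the final round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple, Union

import numpy as np

from .collapse import CollapsedImage
from .morphology import refine_mask
from .rois import ROI, ShapeCriteria, count_valid_rois, extract_rois

EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class FibatConfig:
    """Threshold-search settings.

    n_test
        Number of test thresholds per refinement round (T).  Larger T lowers
        the chance of skipping the optimum at the cost of more component
        labeling passes; the recursive refinement makes the result largely
        insensitive to T.
    alpha
        Range-overlap termination fraction: stop once the narrowed range
        keeps at least this fraction of the previous one.
    epsilon
        Intensity resolution terminating the search, or ``"auto"`` to use the
        smallest nonzero absolute difference between 4-adjacent pixels of the
        input image.
    """

    n_test: int = 12
    alpha: float = 0.90
    epsilon: Union[float, str] = "auto"
    max_rounds: int = 64

    def __post_init__(self) -> None:
        if self.n_test < 3:
            raise ValueError("n_test must be >= 3")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.epsilon != "auto" and not (float(self.epsilon) > 0):
            raise ValueError("epsilon must be positive or 'auto'")


@dataclass
class FibatResult:
    """Outcome of one FIBAT search."""

    tau_star: float
    rois: List[ROI]
    search_trace: List[List[Tuple[float, int]]]  # per round: (threshold, count)
    rounds: int


def auto_epsilon(pixels: np.ndarray) -> float:
    """Smallest nonzero |difference| between 4-adjacent pixel pairs.

    Floored at 1e-12 to avoid degenerate floating-point search ranges.
    """
    dv = np.abs(np.diff(pixels, axis=0)).ravel()
    dh = np.abs(np.diff(pixels, axis=1)).ravel()
    diffs = np.concatenate([dv, dh])
    nz = diffs[diffs > 0]
    if nz.size == 0:
        return EPS_FLOOR
    return max(float(nz.min()), EPS_FLOOR)


def binarize_and_refine(image: CollapsedImage, tau: float) -> np.ndarray:
    """Threshold (strictly greater) then fill holes, remove spurs, break H's."""
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    return refine_mask(image.pixels > tau)


def _count_at(image: CollapsedImage, tau: float, criteria: ShapeCriteria) -> int:
    return count_valid_rois(binarize_and_refine(image, tau), criteria)


def fibat(
    image: CollapsedImage,
    criteria: ShapeCriteria,
    config: FibatConfig = FibatConfig(),
) -> FibatResult:
    """Find the ROI-count-maximizing threshold and the ROI set it yields.

    The returned ROI set is extracted at tau* with oversized components
    retained, so that merged clusters can be handed to local splitting.
    A constant image yields tau* equal to that constant and no ROIs.
    """
    arr = image.pixels
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return FibatResult(tau_star=lo, rois=[], search_trace=[], rounds=0)

    eps = auto_epsilon(arr) if config.epsilon == "auto" else float(config.epsilon)
    trace: List[List[Tuple[float, int]]] = []
    tau_star = lo
    rounds = 0
    for rounds in range(1, config.max_rounds + 1):
        taus = np.linspace(lo, hi, config.n_test)
        counts = [_count_at(image, float(t), criteria) for t in taus]
        trace.append([(float(t), int(c)) for t, c in zip(taus, counts)])
        cmax = max(counts)
        maximizers = [i for i, c in enumerate(counts) if c == cmax]
        i_lo = max(0, maximizers[0] - 1)
        i_hi = min(config.n_test - 1, maximizers[-1] + 1)
        tau_star = 0.5 * (float(taus[maximizers[0]]) + float(taus[maximizers[-1]]))
        new_lo, new_hi = float(taus[i_lo]), float(taus[i_hi])
        if (new_hi - new_lo) < eps:
            break
        if (new_hi - new_lo) >= config.alpha * (hi - lo):
            break
        lo, hi = new_lo, new_hi

    final_rois = extract_rois(
        binarize_and_refine(image, tau_star), criteria, keep_oversize=True
    )
    return FibatResult(
        tau_star=tau_star, rois=final_rois, search_trace=trace, rounds=rounds
    )
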