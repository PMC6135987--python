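"""Segmentation evaluation: SNR definitions, ROI-set matching, and
recall / precision / FDR / FNR.

Two ROIs are considered the same cell when their centroids are closer than a
distance cap (default 50 px) and their mutual overlap — the average of the
intersection area expressed as a fraction of each of the two areas — exceeds
a floor (default 60%).  Candidate pairs are matched one-to-one greedily in
descending mutual overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .collapse import CollapsedImage, ImageStack
from .rois import ROI

_KEY_SHIFT = np.int64(1) << 32


@dataclass(frozen=True)
class MatchConfig:
    max_centroid_dist: float = 50.0
    min_mutual_overlap: float = 0.60

    def __post_init__(self) -> None:
        if not self.max_centroid_dist > 0:
            raise ValueError("max_centroid_dist must be positive")
        if not (0 < self.min_mutual_overlap <= 1):
            raise ValueError("min_mutual_overlap must be in (0, 1]")


@dataclass
class MatchResult:
    """One-to-one pairing of predicted vs reference ROIs and the derived rates.

    ``degenerate_precision`` (``degenerate_recall``) flags the convention of
    reporting 0 when there are no predictions (no reference ROIs) and the
    rate is formally undefined.
    """

    pairs: List[Tuple[int, int, float]]  # (pred index, truth index, overlap)
    n_match: int
    n_pred_only: int
    n_truth_only: int
    recall: float
    precision: float
    fdr: float
    fnr: float
    degenerate_precision: bool = False
    degenerate_recall: bool = False


def _pixel_keys(roi: ROI) -> np.ndarray:
    return roi.pixels[:, 0] * _KEY_SHIFT + roi.pixels[:, 1]


def mutual_overlap(a: ROI, b: ROI) -> float:
    """Average of the intersection area as a fraction of each ROI's area.

    ``0.5 * (|a&b|/|a| + |a&b|/|b|)`` — 1.0 for identical masks, 0.0 for
    disjoint ones; symmetric in its arguments.
    """
    inter = np.intersect1d(_pixel_keys(a), _pixel_keys(b)).size
    if inter == 0:
        return 0.0
    return 0.5 * (inter / a.area + inter / b.area)


def match_roi_sets(
    pred: Sequence[ROI], truth: Sequence[ROI], cfg: MatchConfig = MatchConfig()
) -> MatchResult:
    """Greedy one-to-one matching of predicted against reference ROIs.

    Candidate pairs must have centroid distance strictly below the cap and
    mutual overlap strictly above the floor.  Pairs are consumed in
    descending overlap; ties break on smaller centroid distance, then lower
    truth index, then lower prediction index, making the result invariant to
    input ordering.
    """
    candidates: List[Tuple[float, float, int, int]] = []
    if pred and truth:
        pc = np.array([p.centroid for p in pred])
        tc = np.array([t.centroid for t in truth])
        d = np.linalg.norm(pc[:, None, :] - tc[None, :, :], axis=2)
        keys_p = [_pixel_keys(p) for p in pred]
        keys_t = [_pixel_keys(t) for t in truth]
        for i, j in zip(*np.nonzero(d < cfg.max_centroid_dist)):
            inter = np.intersect1d(keys_p[i], keys_t[j]).size
            if inter == 0:
                continue
            ov = 0.5 * (inter / pred[i].area + inter / truth[j].area)
            if ov > cfg.min_mutual_overlap:
                candidates.append((ov, float(d[i, j]), int(j), int(i)))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: List[Tuple[int, int, float]] = []
    for ov, _dist, j, i in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j, ov))

    n_match = len(pairs)
    n_pred_only = len(pred) - n_match
    n_truth_only = len(truth) - n_match
    degen_p = len(pred) == 0
    degen_t = len(truth) == 0
    precision = 0.0 if degen_p else n_match / len(pred)
    recall = 0.0 if degen_t else n_match / len(truth)
    return MatchResult(
        pairs=pairs,
        n_match=n_match,
        n_pred_only=n_pred_only,
        n_truth_only=n_truth_only,
        recall=recall,
        precision=precision,
        fdr=1.0 - precision,
        fnr=1.0 - recall,
        degenerate_precision=degen_p,
        degenerate_recall=degen_t,
    )


def snr_image(roi_mask_union: np.ndarray, image: CollapsedImage | np.ndarray) -> float:
    """Image-level SNR: 20*log10(mean ROI intensity / background std).

    Background standard deviation uses the population formula (divide by N).
    """
    arr = image.pixels if isinstance(image, CollapsedImage) else np.asarray(image, float)
    mask = np.asarray(roi_mask_union, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any() or mask.all():
        raise ValueError("both ROI and background pixel sets must be non-empty")
    mu = float(arr[mask].mean())
    sd = float(arr[~mask].std())
    if sd == 0:
        raise ValueError("background has zero variance; SNR undefined")
    if mu <= 0:
        raise ValueError("non-positive mean ROI intensity; SNR undefined")
    return 20.0 * math.log10(mu / sd)


def snr_trace(roi: ROI, stack: ImageStack) -> float:
    """Trace-level SNR of one ROI against the non-ROI background.

    The ROI trace is the per-frame mean over the ROI's pixels; the background
    trace is the per-frame mean over all other pixels.  Returns
    ``20*log10(max(ROI trace) / std(background trace))``.
    """
    frames = stack.frames
    h, w, _ = frames.shape
    mask = roi.to_mask((h, w))
    if mask.all():
        raise ValueError("ROI covers the whole frame; no background")
    roi_trace = frames[mask].mean(axis=0)
    bg_trace = frames[~mask].mean(axis=0)
    sd = float(bg_trace.std())
    if sd == 0:
        raise ValueError("background trace has zero variance; SNR undefined")
    peak = float(roi_trace.max())
    if peak <= 0:
        raise ValueError("non-positive ROI trace peak; SNR undefined")
    return 20.0 * math.log10(peak / sd)


def normalize_trace(trace: np.ndarray) -> np.ndarray:
    """Display normalization of a fluorescence trace: (F - mean) / mean."""
    trace = np.asarray(trace, dtype=float)
    mu = trace.mean()
    if mu == 0:
        raise ValueError("zero-mean trace cannot be mean-normalized")
    return (trace - mu) / mu


def iteration_metrics(segmentation, truth: Sequence[ROI], cfg: MatchConfig = MatchConfig()) -> pd.DataFrame:
    """Per-iteration cumulative performance of a segmentation against truth.

    Row k evaluates the union of ROIs from iterations 1..k, mirroring how
    performance evolves as the iterative loop proceeds.
    """
    rows = []
    for rec in segmentation.history:
        preds = [r for r in segmentation.rois if r.iteration <= rec.index]
        m = match_roi_sets(preds, list(truth), cfg)
        rows.append(
            {
                "iteration": rec.index,
                "tau_global": rec.tau_global,
                "cumulative_rois": rec.cumulative_rois,
                "recall": m.recall,
                "precision": m.precision,
                "fdr": m.fdr,
                "fnr": m.fnr,
            }
        )
    return pd.DataFrame(rows)
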