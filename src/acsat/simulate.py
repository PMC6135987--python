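"""Synthetic time-collapsed calcium-imaging images with known ground truth.

The generative model is ``I0 = E + s * (A ∘ C)``:

* ``E`` — background noise emulating the time-collapse of a movie: for each
  pixel, ``noise_frames`` i.i.d. Gaussian draws are collapsed to
  max - mean, which is non-negative and positively skewed (the collapse is
  biased toward high values), not Gaussian.
* ``A`` — cell bodies: bivariate-Gaussian intensity profiles with widths
  drawn uniformly from ``sigma_range`` and per-cell peak amplitudes drawn
  uniformly from ``amplitude_range``; overlapping cells add.
* ``C`` — smooth, strictly positive illumination field (mean 1) standing in
  for uneven lighting across the imaging field; cell centroids are sampled
  with probability proportional to C², so cells concentrate where the field
  is bright.

The scalar ``s`` is solved so that the image-level SNR (mean intensity over
the union of true ROI masks divided by the background standard deviation, in
dB) hits the requested target.  Each cell's true ROI mask is the set of
pixels where its own noiseless profile exceeds a fixed fraction of its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .collapse import CollapsedImage
from .evaluate import snr_image
from .rois import ROI


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults correspond to a full-frame wide-field recording (1024x1024 px,
    ~1.3 um/px); tests and benchmarks use 256x256 frames with the ROI count
    scaled by the same factor as the area.  ``sigma_range`` of (2, 5) px
    gives cell bodies of roughly 5-20 um diameter at that pixel scale.
    """

    height: int = 1024
    width: int = 1024
    n_rois: int = 500
    target_snr_db: float = 24.0
    sigma_range: Tuple[float, float] = (2.0, 5.0)
    amplitude_range: Tuple[float, float] = (0.5, 1.0)
    illumination_smoothing: Optional[float] = None  # default: max(h, w) / 8
    illumination_contrast: float = 0.15
    support_fraction: float = 0.2
    noise_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_rois < 0:
            raise ValueError("n_rois must be >= 0")
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")
        if not (0 < self.sigma_range[0] <= self.sigma_range[1]):
            raise ValueError("sigma_range must be positive and ordered")
        if self.noise_frames < 2:
            raise ValueError("noise_frames must be >= 2")
        if not (0 < self.support_fraction < 1):
            raise ValueError("support_fraction must be in (0, 1)")

    @property
    def smoothing(self) -> float:
        if self.illumination_smoothing is not None:
            return self.illumination_smoothing
        return max(self.height, self.width) / 8.0


@dataclass
class GroundTruth:
    """A simulated collapsed image together with everything needed to score a
    segmentation against it: the true ROI masks and the noiseless components."""

    image: CollapsedImage
    true_rois: List[ROI]
    noise: np.ndarray  # E
    signal: np.ndarray  # s * (A ∘ C)
    illumination: np.ndarray  # C
    achieved_snr_db: float
    config: SimulationConfig

    def truth_mask_union(self) -> np.ndarray:
        union = np.zeros(self.image.shape, dtype=bool)
        for roi in self.true_rois:
            union[roi.pixels[:, 0], roi.pixels[:, 1]] = True
        return union


def make_illumination(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth, strictly positive illumination field normalized to mean 1.

    Heavily blurred white noise plus a unit baseline; the blur scale controls
    the autocorrelation length of the field.
    """
    g = ndi.gaussian_filter(
        rng.standard_normal((config.height, config.width)), sigma=config.smoothing
    )
    sd = g.std()
    if sd > 0:
        g = g / sd
    field_ = 1.0 + config.illumination_contrast * g
    field_ = np.clip(field_, 0.05, None)
    return field_ / field_.mean()


def make_noise(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Background field emulating time-collapse of pure noise frames.

    Streams ``noise_frames`` standard-normal frames, keeping a running max
    and running sum; returns max - mean per pixel (>= 0, positively skewed).
    """
    shape = (config.height, config.width)
    running_max = np.full(shape, -np.inf)
    running_sum = np.zeros(shape)
    for _ in range(config.noise_frames):
        frame = rng.standard_normal(shape)
        np.maximum(running_max, frame, out=running_max)
        running_sum += frame
    return running_max - running_sum / config.noise_frames


def place_cells(
    config: SimulationConfig, illumination: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, List[ROI]]:
    """Sample cell centroids with weights C² and superpose Gaussian bodies.

    Returns the cell field ``A`` and the per-cell true ROI masks (pixels
    where that cell's own profile is at least ``support_fraction`` of its
    peak).  Overlapping cells sum; truth masks may overlap.
    """
    h, w = config.height, config.width
    A = np.zeros((h, w))
    rois: List[ROI] = []
    if config.n_rois == 0:
        return A, rois

    weights = illumination.ravel() ** 2
    weights = weights / weights.sum()
    flat_idx = rng.choice(h * w, size=config.n_rois, replace=True, p=weights)
    jitter = rng.uniform(-0.5, 0.5, size=(config.n_rois, 2))
    sigmas = rng.uniform(*config.sigma_range, size=(config.n_rois, 2))
    amps = rng.uniform(*config.amplitude_range, size=config.n_rois)

    cutoff = config.support_fraction
    for k in range(config.n_rois):
        cy = flat_idx[k] // w + jitter[k, 0]
        cx = flat_idx[k] % w + jitter[k, 1]
        sy, sx = sigmas[k]
        ry, rx = int(math.ceil(4 * sy)), int(math.ceil(4 * sx))
        r0, r1 = max(int(round(cy)) - ry, 0), min(int(round(cy)) + ry + 1, h)
        c0, c1 = max(int(round(cx)) - rx, 0), min(int(round(cx)) + rx + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        profile = np.exp(
            -((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2))
        )
        # truncate the body at the support cutoff so each declared truth mask
        # contains all of its cell's signal; keeps the image SNR strictly
        # monotone in the amplitude scale
        profile = np.where(profile >= cutoff, profile, 0.0)
        A[r0:r1, c0:c1] += amps[k] * profile
        rr, cc = np.nonzero(profile >= cutoff)
        rois.append(
            ROI(pixels=np.column_stack([rr + r0, cc + c0]), iteration=0)
        )
    return A, rois


def simulate_dataset(config: SimulationConfig) -> GroundTruth:
    """Generate one simulated collapsed image at the requested SNR.

    The signal amplitude scalar is solved by root finding so the achieved
    image SNR matches ``target_snr_db``; a mismatch beyond 0.5 dB raises.
    """
    rng = np.random.default_rng(config.seed)
    C = make_illumination(config, rng)
    E = make_noise(config, rng)
    A, rois = place_cells(config, C, rng)
    if config.n_rois == 0:
        raise ValueError("cannot reach a finite target SNR with zero ROIs")

    AC = A * C
    union = np.zeros((config.height, config.width), dtype=bool)
    for roi in rois:
        union[roi.pixels[:, 0], roi.pixels[:, 1]] = True

    def snr_minus_target(log_s: float) -> float:
        s = math.exp(log_s)
        return snr_image(union, E + s * AC) - config.target_snr_db

    lo, hi = -20.0, 20.0
    if snr_minus_target(lo) > 0 or snr_minus_target(hi) < 0:
        raise ValueError("target SNR unreachable for this configuration")
    log_s = brentq(snr_minus_target, lo, hi, xtol=1e-10)
    s = math.exp(log_s)
    signal = s * AC
    image = CollapsedImage(pixels=E + signal, provenance="max_minus_mean")
    achieved = snr_image(union, image)
    if abs(achieved - config.target_snr_db) > 0.5:
        raise RuntimeError(
            f"achieved SNR {achieved:.2f} dB misses target "
            f"{config.target_snr_db:.2f} dB by more than 0.5 dB"
        )
    return GroundTruth(
        image=image,
        true_rois=rois,
        noise=E,
        signal=signal,
        illumination=C,
        achieved_snr_db=achieved,
        config=config,
    )
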