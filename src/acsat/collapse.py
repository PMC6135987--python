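"""Time-collapse of fluorescence image sequences.

A calcium-imaging movie is reduced to a single representative 2-D image in
which each pixel holds its maximum intensity over time minus its mean over
time.  Active cells, which flash bright at some point of the recording,
stand out; static background collapses towards zero.  All downstream
thresholding operates on this collapsed image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from scipy import ndimage as ndi


class InvalidInputError(ValueError):
    """Raised when an image or stack violates the basic contracts."""


@dataclass
class ImageStack:
    """A fluorescence image sequence, height x width x time.

    Parameters
    ----------
    frames
        3-D array of non-negative intensities, shape ``(height, width, time)``.
        Integer or floating dtype; converted lazily to float for computation.
    pixel_size_um
        Optional physical scale in micrometres per pixel.
    """

    frames: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidInputError(
                f"stack must be 3-D (height, width, time), got shape {self.frames.shape}"
            )
        if min(self.frames.shape) < 1:
            raise InvalidInputError(f"empty stack with shape {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]


@dataclass
class CollapsedImage:
    """A 2-D representative image, the working canvas of all thresholding."""

    pixels: np.ndarray
    provenance: str = "external"  # max_minus_mean | texture | external

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError(
                f"collapsed image must be 2-D, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("collapsed image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def time_collapse(stack: ImageStack) -> CollapsedImage:
    """Collapse a stack to its per-pixel max-minus-mean projection.

    The result is non-negative everywhere (the maximum of a pixel trace is
    never below its mean) and is computed in floating point regardless of
    the input dtype, so the mean is exact.
    """
    frames = stack.frames.astype(np.float64, copy=False)
    collapsed = frames.max(axis=2) - frames.mean(axis=2)
    return CollapsedImage(pixels=collapsed, provenance="max_minus_mean")


def time_collapse_frames(frames: Iterable[np.ndarray]) -> CollapsedImage:
    """Streaming variant of :func:`time_collapse` for stacks too large for memory.

    Consumes an iterable of 2-D frames, maintaining only a running maximum and
    running sum; the contract is identical to the in-memory result.
    """
    running_max: Optional[np.ndarray] = None
    running_sum: Optional[np.ndarray] = None
    count = 0
    for frame in frames:
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim != 2:
            raise InvalidInputError("each frame must be 2-D")
        if running_max is None:
            running_max = frame.copy()
            running_sum = frame.copy()
        else:
            if frame.shape != running_max.shape:
                raise InvalidInputError("inconsistent frame shapes in stream")
            np.maximum(running_max, frame, out=running_max)
            running_sum += frame
        count += 1
    if count == 0:
        raise InvalidInputError("empty frame stream")
    assert running_max is not None and running_sum is not None
    return CollapsedImage(
        pixels=running_max - running_sum / count, provenance="max_minus_mean"
    )


def texture_transform(image: CollapsedImage, smoothing_scale: float = 10.0) -> CollapsedImage:
    """Texture image: absolute change between an image and its Gaussian blur.

    Useful for fields where cells read out as texture rather than raw
    brightness (e.g. dark-nucleus two-photon data).  ``smoothing_scale`` is
    the Gaussian sigma in pixels.
    """
    if not smoothing_scale > 0:
        raise InvalidInputError(f"smoothing_scale must be > 0, got {smoothing_scale}")
    blurred = ndi.gaussian_filter(image.pixels, sigma=smoothing_scale)
    return CollapsedImage(pixels=np.abs(image.pixels - blurred), provenance="texture")
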