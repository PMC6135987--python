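"""Shared fixtures: synthetic images used across the suite.

Everything is generated programmatically; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from acsat import CollapsedImage


def gaussian_blob(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float) -> None:
    """Add one isotropic Gaussian cell body to an image in place."""
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma * sigma))


def disc_image(
    shape: tuple[int, int], centers: list[tuple[int, int]], radius: int, value: float = 1.0
) -> np.ndarray:
    """Flat discs of a given intensity on a zero background."""
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius] = value
    return img


def quantized_blob_image(
    seed: int, size: int = 128, n_blobs: int = 20, levels: int = 200
) -> CollapsedImage:
    """Random Gaussian blobs of varied amplitude on an illumination ramp,
    quantized to integer intensity levels (so the threshold grid is small)."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = 0.3 * (xx / size) + 0.2 * (yy / size)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(8, size - 8, 2)
        sy, sx = rng.uniform(2.0, 5.0, 2)
        amp = rng.uniform(0.5, 1.5)
        img += amp * np.exp(
            -((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2))
        )
    q = np.floor((img - img.min()) / (img.max() - img.min()) * levels)
    return CollapsedImage(pixels=q, provenance="external")


def clustered_cells_image(spacing: float = 10.0, sigma: float = 3.0) -> CollapsedImage:
    """A dense five-cell cluster plus twelve isolated cells of varied brightness.

    At the global optimal threshold the cluster thresholds as one merged
    region (its inter-cell bridges sit well above the global threshold set by
    the isolated cells), while local re-thresholding can separate all five.
    """
    size = 160
    img = np.zeros((size, size))
    for dy, dx in [(0, 0), (spacing, 0), (-spacing, 0), (0, spacing), (0, -spacing)]:
        gaussian_blob(img, 40 + dy, 40 + dx, 1.0, sigma)
    rng = np.random.default_rng(0)
    pts = [
        (90, 30), (120, 60), (60, 100), (100, 120), (30, 120), (130, 130),
        (80, 70), (140, 30), (20, 80), (110, 20), (60, 140), (140, 90),
    ]
    for (cy, cx), a in zip(pts, rng.uniform(0.4, 1.0, len(pts))):
        gaussian_blob(img, cy, cx, a, sigma)
    return CollapsedImage(pixels=img)


@pytest.fixture
def five_cell_cluster() -> CollapsedImage:
    return clustered_cells_image()
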