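"""3x3 lookup-table morphology used to refine binarized images.

The refinement chain applied after each thresholding step is: fill interior
holes, remove spur pixels, break H-connected bridges.  Spur removal and
H-break follow the classical 3x3 lookup-table operator definitions; the two
512-entry tables ship as plain-text fixtures under ``acsat/data`` (row-major
bit order: bit ``3*i + j`` is neighborhood position ``(i, j)``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from scipy import ndimage as ndi

# weight of each 3x3 neighborhood position in the LUT index (row-major bits)
_POWERS = np.array([[1, 2, 4], [8, 16, 32], [64, 128, 256]], dtype=np.uint16)


def _load_lut(name: str) -> np.ndarray:
    text = resources.files("acsat.data").joinpath(name).read_text()
    bits = np.concatenate([np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
                           for row in text.split()])
    if bits.size != 512 or not np.isin(bits, (0, 1)).all():
        raise ValueError(f"corrupt LUT fixture {name!r}")
    return bits.astype(bool)


SPUR_LUT = _load_lut("spur_lut.txt")
HBREAK_LUT = _load_lut("hbreak_lut.txt")


def apply_lut(mask: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Apply a 512-entry 3x3 lookup table to a binary mask (zero-padded edges)."""
    codes = ndi.correlate(mask.astype(np.uint16), _POWERS, mode="constant", cval=0)
    return lut[codes]


def remove_spurs(mask: np.ndarray) -> np.ndarray:
    """Remove spur pixels: foreground pixels with exactly one 8-neighbor."""
    return apply_lut(mask, SPUR_LUT)


def break_h_connections(mask: np.ndarray) -> np.ndarray:
    """Clear the center of exact H-shaped 3x3 patterns (and the rotated H)."""
    return apply_lut(mask, HBREAK_LUT)


def refine_mask(mask: np.ndarray) -> np.ndarray:
    """Fill holes, remove spurs, break H-connections — in that order, once each."""
    mask = ndi.binary_fill_holes(mask)
    mask = remove_spurs(mask)
    mask = break_h_connections(mask)
    return mask


def disk(radius: int) -> np.ndarray:
    """Disc structuring element of the given integer radius (Euclidean)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r
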