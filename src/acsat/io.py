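"""File formats: TIFF stacks and images in, label TIFFs / CSV / JSON out,
plus the run manifest that makes every command-line run reproducible."""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .collapse import CollapsedImage, ImageStack
from .core import Segmentation
from .rois import ROI

ROI_CSV_COLUMNS = [
    "label",
    "iteration",
    "area_px",
    "centroid_row",
    "centroid_col",
    "solidity_ratio",
]


class FormatError(ValueError):
    """Raised on unreadable or unsupported image files."""


def _read_tiff_array(path: Union[str, Path]) -> np.ndarray:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes
            if any(ax in axes for ax in ("S", "C")):
                raise FormatError(
                    f"{path}: multi-sample/multi-channel TIFF (axes {axes!r}) "
                    "is not supported; grayscale only"
                )
            arr = series.asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    return arr


def read_stack(path: Union[str, Path]) -> ImageStack:
    """Read a multipage grayscale TIFF as an image stack (height, width, time).

    A single-page file becomes a one-frame stack.
    """
    arr = _read_tiff_array(path)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, 0, -1)  # pages are the time axis
    else:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return ImageStack(frames=arr)


def read_image(path: Union[str, Path]) -> CollapsedImage:
    """Read a single-page grayscale TIFF as an externally collapsed image."""
    arr = _read_tiff_array(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-page 2-D TIFF, got {arr.ndim}-D data"
        )
    return CollapsedImage(pixels=arr, provenance="external")


def write_image(path: Union[str, Path], image: Union[CollapsedImage, np.ndarray]) -> None:
    arr = image.pixels if isinstance(image, CollapsedImage) else np.asarray(image)
    tifffile.imwrite(str(path), arr.astype(np.float32) if arr.dtype.kind == "f" else arr)


def write_stack(path: Union[str, Path], stack: ImageStack) -> None:
    # photometric is explicit so a 3-frame stack is not mistaken for RGB
    tifffile.imwrite(
        str(path), np.moveaxis(stack.frames, -1, 0), photometric="minisblack"
    )


def rois_to_labels(
    rois: List[ROI], shape: tuple[int, int]
) -> np.ndarray:
    """Render ROIs as a label image from their pre-dilation cores.

    Labels are assigned iteration-major, then by descending area, so runs
    diff stably.  16-bit output, escalated to 32-bit with a warning when
    there are more than 65535 ROIs.
    """
    order = sorted(range(len(rois)), key=lambda i: (rois[i].iteration, -rois[i].area))
    dtype: Any = np.uint16
    if len(rois) > 65535:
        warnings.warn("more than 65535 ROIs; escalating label image to 32-bit")
        dtype = np.uint32
    labels = np.zeros(shape, dtype=dtype)
    for new_label, i in enumerate(order, start=1):
        px = rois[i].core_pixels
        labels[px[:, 0], px[:, 1]] = new_label
    return labels


def rois_to_table(rois: List[ROI]) -> pd.DataFrame:
    """ROI summary table matching the label image ordering and areas."""
    order = sorted(range(len(rois)), key=lambda i: (rois[i].iteration, -rois[i].area))
    rows = []
    for new_label, i in enumerate(order, start=1):
        roi = rois[i]
        core = ROI(pixels=roi.core_pixels, iteration=roi.iteration)
        cy, cx = core.centroid
        rows.append(
            {
                "label": new_label,
                "iteration": roi.iteration,
                "area_px": core.area,
                "centroid_row": cy,
                "centroid_col": cx,
                "solidity_ratio": core.solidity_ratio,
            }
        )
    return pd.DataFrame(rows, columns=ROI_CSV_COLUMNS)


def write_labels(
    segmentation_or_rois: Union[Segmentation, List[ROI]],
    labels_path: Union[str, Path],
    csv_path: Optional[Union[str, Path]] = None,
    shape: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Write the label TIFF (and optionally the ROI CSV) for a segmentation."""
    if isinstance(segmentation_or_rois, Segmentation):
        rois = segmentation_or_rois.rois
        shape = segmentation_or_rois.image_shape
    else:
        rois = segmentation_or_rois
        if shape is None:
            raise ValueError("shape is required when passing a bare ROI list")
    labels = rois_to_labels(rois, shape)
    tifffile.imwrite(str(labels_path), labels)
    if csv_path is not None:
        rois_to_table(rois).to_csv(csv_path, index=False)
    return labels


def read_labels(path: Union[str, Path]) -> List[ROI]:
    """Read a label TIFF back into a list of ROIs (iteration tag lost)."""
    labels = _read_tiff_array(path)
    if labels.ndim != 2:
        raise FormatError(f"{path}: label image must be 2-D")
    out: List[ROI] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        out.append(ROI(pixels=np.column_stack([rr, cc]), iteration=0))
    return out


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a command-line run bit-exactly."""

    command: str
    config: Dict[str, Any]
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    seeds: Dict[str, int] = field(default_factory=dict)
    iterations: List[Dict[str, Any]] = field(default_factory=list)
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        return cls.from_json(Path(path).read_text())
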