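"""Raster image container and plain-file I/O.

Micrographs are 8-bit grayscale frames, sometimes stored with the gray
channel replicated into RGB.  Acquisition metadata (exposure time, slide,
acquisition order, sample label, slide-preparation volume) does not survive
inside 8-bit rasters, so it travels in a sidecar delimited table; see
:func:`read_metadata_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RawImage",
    "read_image",
    "write_image",
    "read_metadata_table",
    "write_metadata_table",
    "METADATA_COLUMNS",
]

#: Columns of the sidecar metadata table consumed by the quantification run.
METADATA_COLUMNS = [
    "filename",
    "sample",
    "replicate",
    "slide",
    "acquisition_index",
    "exposure_ms",
    "volume_uL",
    "is_calibrator",
]


@dataclass
class RawImage:
    """An 8-bit micrograph plus its acquisition metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` uint8 array.
    exposure_ms
        Shutter time in milliseconds.
    slide_id
        Identifier of the physical slide the frame was taken from.
    acquisition_index
        0-based order of acquisition within the slide (drives the
        photobleaching bookkeeping).
    sample
        Sample / induction-condition label.
    is_calibrator
        Whether the frame belongs to the reference (maximally induced)
        calibrator sample.
    volume_uL
        Volume dispensed on the slide, in microliters (density denominator).
    image_id
        Free-form identifier, usually the filename stem.
    extras
        Renderer- or pipeline-attached diagnostics (e.g. saturation
        fraction).
    """

    pixels: np.ndarray
    exposure_ms: float = 1.0
    slide_id: str = "slide0"
    acquisition_index: int = 0
    sample: str = "sample"
    is_calibrator: bool = False
    volume_uL: float = 3.0
    image_id: str = "image"
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise ValueError(f"RawImage requires 8-bit pixels, got {px.dtype}")
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"RawImage must be (H, W) or (H, W, 3), got {px.shape}")
        self.pixels = px
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "RawImage":
        return replace(self, pixels=pixels)


def read_image(path: str | Path, **metadata: Any) -> RawImage:
    """Load a TIFF/PNG micrograph from disk as a :class:`RawImage`."""
    path = Path(path)
    px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        raise ValueError(f"{path.name}: expected 8-bit image, got {px.dtype}")
    metadata.setdefault("image_id", path.stem)
    return RawImage(pixels=px, **metadata)


def write_image(img: RawImage | np.ndarray, path: str | Path, rgb: bool = False) -> Path:
    """Write an 8-bit image to TIFF or PNG (chosen by extension).

    With ``rgb=True`` a single-channel frame is replicated into three
    identical channels, matching acquisition software that stores monochrome
    data in RGB containers.
    """
    path = Path(path)
    px = img.pixels if isinstance(img, RawImage) else np.asarray(img)
    if px.dtype != np.uint8:
        raise ValueError("write_image expects uint8 pixels")
    if rgb and px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)
    return path


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read the sidecar acquisition-metadata table (TSV or CSV).

    Required columns are listed in :data:`METADATA_COLUMNS`; extra columns
    pass through untouched.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} missing columns: {missing}")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    return df


def write_metadata_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
    return path
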