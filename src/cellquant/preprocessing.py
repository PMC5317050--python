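"""Raw micrograph → background-free, linearized irradiance image.

The pre-elaboration phase has two main steps, applied in this order:
background correction (morphological grayscale opening with a structuring
element at least as large as the cells, subtracted pixel-wise) and CRF
compensation (per-pixel replacement with normalized irradiance through the
inverse look-up table, then division by the exposure time so samples
acquired at different shutter speeds are directly comparable).  Optional
additive vignetting correction precedes both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage import morphology

from .crf import InverseLUT, VignettingField
from .images import RawImage

__all__ = [
    "IrradianceImage",
    "to_gray",
    "subtract_background",
    "apply_vignetting",
    "linearize",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass
class IrradianceImage:
    """Real-valued image in normalized irradiance per millisecond of
    exposure, with provenance metadata."""

    values: np.ndarray
    exposure_ms: float
    source_id: str = ""
    se_radius_px: int | None = None
    saturated_fraction: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("irradiance values must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def to_gray(raw: RawImage | np.ndarray) -> np.ndarray:
    """Collapse an 8-bit 1- or 3-channel image to a single gray channel.

    Monochrome cameras saved through RGB containers replicate the gray
    channel; if the channels differ, the first channel is used and a
    warning is logged.
    """
    px = raw.pixels if isinstance(raw, RawImage) else np.asarray(raw)
    if px.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got {px.dtype}")
    if px.ndim == 2:
        return px
    if px.ndim == 3 and px.shape[2] == 3:
        if not (np.array_equal(px[:, :, 0], px[:, :, 1]) and np.array_equal(px[:, :, 0], px[:, :, 2])):
            logger.warning("RGB channels differ; using the first channel")
        return px[:, :, 0]
    raise ValueError(f"unsupported image shape {px.shape}")


def subtract_background(
    img: np.ndarray, se_radius_px: int = 15, recenter: bool = True
) -> np.ndarray:
    """Remove spurious fluorescence (e.g. medium autofluorescence) by
    subtracting a grayscale-opening background estimate.

    The opening with a disk of radius ``se_radius_px`` — which must be at
    least as large as the cells' half-width — removes structures smaller
    than the element, leaving the background; the estimate is subtracted
    pixel-wise and negatives are clipped to 0.  Works for non-uniform
    backgrounds since no assumption is made about their shape.

    On noisy images the opening (a min-then-max filter) sits below the
    true background by roughly the noise amplitude, which would bias every
    cell's fluorescence upward.  ``recenter`` (default on) removes that
    floor by subtracting the median of the difference image — zero for
    noise-free inputs whenever cells cover less than half the field, so
    noise-free results are unchanged.
    """
    img = np.asarray(img)
    if se_radius_px < 1:
        raise ValueError("se_radius_px must be a positive integer")
    if 2 * se_radius_px + 1 > min(img.shape):
        raise ValueError(
            f"structuring element radius {se_radius_px} exceeds image size {img.shape}"
        )
    selem = morphology.disk(se_radius_px)
    background = morphology.opening(img, selem)
    out = img.astype(float) - background.astype(float)
    if recenter:
        out -= np.median(out)
    return np.clip(out, 0.0, None)


def apply_vignetting(img: np.ndarray, vignetting: VignettingField | None) -> np.ndarray:
    """Additively compensate lens falloff; identity when no field is
    configured (set-ups whose flat fields are already uniform)."""
    img = np.asarray(img)
    if vignetting is None:
        return img
    if vignetting.field.shape != img.shape:
        raise ValueError(
            f"vignetting field shape {vignetting.field.shape} != image shape {img.shape}"
        )
    return np.clip(img.astype(float) + vignetting.field, 0.0, 255.0)


def linearize(
    img: np.ndarray,
    lut: InverseLUT,
    exposure_ms: float,
    source_id: str = "",
    saturation_warn_fraction: float = 0.01,
) -> IrradianceImage:
    """Replace each gray level with its normalized irradiance (via the
    inverse-CRF LUT) divided by the exposure time.

    Saturated pixels (gray 255) are retained but counted; a saturated
    fraction above ``saturation_warn_fraction`` logs a warning recommending
    a shorter shutter time.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.floating):
        # background-subtracted images are float; re-quantize for the LUT
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    sat = float(np.mean(img == 255))
    if sat > saturation_warn_fraction:
        logger.warning(
            "%s: %.1f%% saturated pixels; consider a shorter shutter time",
            source_id or "image", 100 * sat,
        )
    values = lut.apply(img) / exposure_ms
    return IrradianceImage(
        values=values,
        exposure_ms=exposure_ms,
        source_id=source_id,
        saturated_fraction=sat,
    )


def preprocess(
    raw: RawImage,
    lut: InverseLUT,
    se_radius_px: int = 15,
    vignetting: VignettingField | None = None,
    linearize_first: bool = False,
) -> IrradianceImage:
    """Full pre-elaboration: gray conversion, optional vignetting
    correction, background subtraction, CRF linearization.

    Background subtraction happens on gray levels before linearization by
    default; ``linearize_first=True`` swaps the order (subtracting in
    linear space), in which case the subtraction operates on the
    irradiance values directly.
    """
    gray = to_gray(raw)
    gray = apply_vignetting(gray, vignetting)
    if linearize_first:
        irr = linearize(
            np.asarray(gray), lut, raw.exposure_ms, source_id=raw.image_id
        )
        vals = irr.values - _float_opening(irr.values, se_radius_px)
        irr.values = np.clip(vals, 0.0, None)
        irr.se_radius_px = se_radius_px
        return irr
    sub = subtract_background(np.asarray(gray), se_radius_px=se_radius_px)
    irr = linearize(sub, lut, raw.exposure_ms, source_id=raw.image_id)
    irr.se_radius_px = se_radius_px
    return irr


def _float_opening(img: np.ndarray, se_radius_px: int) -> np.ndarray:
    from scipy import ndimage

    selem = morphology.disk(se_radius_px).astype(bool)
    return ndimage.grey_opening(img, footprint=selem)
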