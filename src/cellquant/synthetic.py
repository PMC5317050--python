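"""Forward-model micrograph simulator with known ground truth.

Emulates fields of rod-shaped bacteria (spherocylinder footprints, the
morphology of *E. coli* at ~40x where cells span a few hundred pixels) with
log-normal per-cell fluorescence, additive background (optionally with a
planar gradient), Gaussian read noise (optional Poisson shot noise), a
cubic camera response, additive vignetting falloff, and per-acquisition
exponential photobleaching.  Every rendered frame is traceable to a
:class:`SceneTruth` so each pipeline stage can be validated against exact
ground truth.

Per-cell fluorescence is log-normal because expression levels are strictly
positive and the squared coefficient of variation (CV²) parameterizes the
distribution in closed form: for target mean ``m`` and CV² ``c``,
``σ²_log = ln(1 + c)`` and ``μ_log = ln m − σ²_log / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .crf import CRFModel
from .images import RawImage

__all__ = [
    "SceneSpec",
    "CellTruth",
    "SceneTruth",
    "AcquisitionSpec",
    "SceneTooDenseError",
    "generate_scene",
    "render_image",
    "render_slide_series",
    "render_calibration_stack",
    "write_truth_table",
    "read_truth_table",
]


class SceneTooDenseError(RuntimeError):
    """Raised when rejection sampling cannot place all requested cells."""


@dataclass
class SceneSpec:
    """Parameters of a synthetic field of view.

    Geometry is in pixels; fluorescence and background are in true
    normalized-irradiance units on ``(0, 1]``.  ``cv2_true`` is the squared
    coefficient of variation ``(σ/μ)²`` of the per-cell fluorescence
    distribution.  ``background_gradient`` is the total planar drop
    ``(row, col)`` across the image, and ``noise_sd`` the Gaussian read
    noise in gray levels added at render time.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_cells: int = 100
    cell_length_px_range: tuple[float, float] = (18.0, 32.0)
    cell_width_px_range: tuple[float, float] = (6.0, 9.0)
    mean_fluorescence: float = 0.5
    cv2_true: float = 0.09
    background_level: float = 0.1
    background_gradient: tuple[float, float] | None = None
    noise_sd: float = 5.0
    shot_noise: bool = False
    min_separation_px: int = 5
    allow_touching: bool = False
    max_attempts_per_cell: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not (0.0 < self.mean_fluorescence <= 1.0):
            raise ValueError("mean_fluorescence must lie in (0, 1]")
        if self.cv2_true < 0:
            raise ValueError("cv2_true must be non-negative")
        if not (0.0 <= self.background_level < 1.0):
            raise ValueError("background_level must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("cell_length_px_range", "cell_width_px_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    orientation_rad: float
    length_px: float
    width_px: float
    true_fluorescence: float


@dataclass
class SceneTruth:
    """Scene ground truth: cell geometries and fluorescences, the realized
    background field, the integer footprint label map used for rendering,
    and the generating spec/seed."""

    cells: list[CellTruth]
    background: np.ndarray
    label_map: np.ndarray
    spec: SceneSpec
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def fluorescence_field(self) -> np.ndarray:
        """Per-pixel true cell fluorescence (0 outside cells)."""
        lookup = np.zeros(self.n_cells + 1)
        for cell in self.cells:
            lookup[cell.cell_id] = cell.true_fluorescence
        return lookup[self.label_map]


@dataclass
class AcquisitionSpec:
    """Camera/illumination parameters for rendering one frame.

    ``exposure_ms / exposure_ref_ms`` scales irradiance before the CRF
    (irradiance 1.0 at the reference exposure maps to gray 255);
    ``vignetting_amplitude`` is the irradiance lost at the image corners
    (radially increasing falloff); photobleaching multiplies cell
    fluorescence by ``exp(−photobleach_rate · acquisition_time_s)``;
    ``psf_sigma_px`` optionally blurs the pre-noise irradiance field to
    emulate optics (0 = ideal binary edges).
    """

    exposure_ms: float = 10.0
    exposure_ref_ms: float = 10.0
    crf: CRFModel | None = None
    vignetting_amplitude: float = 0.0
    photobleach_rate: float = 0.0
    acquisition_time_s: float = 0.0
    psf_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0 or self.exposure_ref_ms <= 0:
            raise ValueError("exposure times must be positive")
        if self.vignetting_amplitude < 0:
            raise ValueError("vignetting_amplitude must be >= 0")
        if self.photobleach_rate < 0:
            raise ValueError("photobleach_rate must be >= 0")
        if self.acquisition_time_s < 0:
            raise ValueError("acquisition_time_s must be >= 0")


def _capsule_footprint(
    shape: tuple[int, int],
    center: tuple[float, float],
    orientation: float,
    length: float,
    width: float,
) -> tuple[np.ndarray, tuple[int, int]] | None:
    """Boolean footprint of a spherocylinder (rod with semicircular caps),
    returned on a tight bounding window with its (row, col) offset.

    A pixel belongs to the cell when its distance to the central axis
    segment (length ``length − width``) is at most ``width / 2``.
    """
    r0, c0 = center
    half = max(length - width, 0.0) / 2.0
    rad = width / 2.0
    dr, dc = math.sin(orientation), math.cos(orientation)

    extent = half + rad + 1.0
    rmin = int(math.floor(r0 - extent))
    rmax = int(math.ceil(r0 + extent))
    cmin = int(math.floor(c0 - extent))
    cmax = int(math.ceil(c0 + extent))
    if rmin < 0 or cmin < 0 or rmax >= shape[0] or cmax >= shape[1]:
        return None

    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    # projection of each pixel onto the axis segment, clamped to the caps
    pr, pc = rr - r0, cc - c0
    t = np.clip(pr * dr + pc * dc, -half, half)
    dist2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    return dist2 <= rad * rad, (rmin, cmin)


def _sample_fluorescence(rng: np.random.Generator, n: int, mean: float, cv2: float) -> np.ndarray:
    if cv2 == 0.0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Place non-overlapping rods by rejection sampling and draw their
    fluorescences; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    sep = 0 if spec.allow_touching else spec.min_separation_px
    sep_structure = None
    if sep > 0:
        y, x = np.mgrid[-sep : sep + 1, -sep : sep + 1]
        sep_structure = (y * y + x * x) <= sep * sep

    cells: list[CellTruth] = []
    for cid in range(1, spec.n_cells + 1):
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            length = rng.uniform(*spec.cell_length_px_range)
            width = rng.uniform(*spec.cell_width_px_range)
            width = min(width, length)
            orient = rng.uniform(0.0, math.pi)
            margin = length / 2.0 + 2.0 + sep
            if 2 * margin >= min(shape):
                raise SceneTooDenseError(
                    f"cell length {length:.0f}px does not fit a "
                    f"{shape[0]}x{shape[1]} image"
                )
            r0 = rng.uniform(margin, shape[0] - margin)
            c0 = rng.uniform(margin, shape[1] - margin)
            fp = _capsule_footprint(shape, (r0, c0), orient, length, width)
            if fp is None:
                continue
            mask, (roff, coff) = fp
            win = (
                slice(roff, roff + mask.shape[0]),
                slice(coff, coff + mask.shape[1]),
            )
            if np.any(occupied[win] & mask):
                continue
            labels[win][mask] = cid
            if sep_structure is not None:
                # pad so the dilation is not truncated at the window border
                grown = ndimage.binary_dilation(np.pad(mask, sep), structure=sep_structure)
                gwin = (
                    slice(roff - sep, roff + mask.shape[0] + sep),
                    slice(coff - sep, coff + mask.shape[1] + sep),
                )
                occupied[gwin] |= grown
            else:
                occupied[win] |= mask
            cells.append(CellTruth(cid, (r0, c0), orient, length, width, 0.0))
            placed = True
            break
        if not placed:
            achieved = (cid - 1) / (shape[0] * shape[1])
            raise SceneTooDenseError(
                f"scene too dense: placed {cid - 1} of {spec.n_cells} cells "
                f"after {spec.max_attempts_per_cell} attempts each "
                f"(achievable density ~{achieved:.2e} cells/px at these sizes)"
            )

    fluor = _sample_fluorescence(rng, len(cells), spec.mean_fluorescence, spec.cv2_true)
    for cell, f in zip(cells, fluor):
        cell.true_fluorescence = float(f)

    rows = np.arange(shape[0])[:, None] / max(shape[0] - 1, 1)
    cols = np.arange(shape[1])[None, :] / max(shape[1] - 1, 1)
    background = np.full(shape, spec.background_level)
    if spec.background_gradient is not None:
        gr, gc = spec.background_gradient
        background = background + gr * (rows - 0.5) + gc * (cols - 0.5)
        background = np.clip(background, 0.0, 1.0)

    return SceneTruth(cells=cells, background=background, label_map=labels, spec=spec, seed=spec.seed)


def render_image(
    truth: SceneTruth,
    acq: AcquisitionSpec,
    seed: int | None = None,
    image_id: str = "synthetic",
    **metadata,
) -> RawImage:
    """Render one 8-bit frame from ground truth through the acquisition
    model.

    Irradiance field = background + cell fluorescence × photobleach decay,
    optionally blurred (optics) and dimmed toward the corners (vignetting);
    it is scaled by the exposure ratio, clipped to the CRF domain [0, 1]
    (the clipped fraction is reported as ``saturation_fraction``), mapped
    through the CRF to gray levels, and corrupted by read (and optional
    shot) noise before 8-bit quantization.  Deterministic given ``seed``
    (default: derived from the scene seed).
    """
    spec = truth.spec
    decay = math.exp(-acq.photobleach_rate * acq.acquisition_time_s)
    irr = truth.background + truth.fluorescence_field() * decay
    if acq.psf_sigma_px > 0:
        irr = ndimage.gaussian_filter(irr, acq.psf_sigma_px, mode="nearest")

    if acq.vignetting_amplitude > 0:
        h, w = irr.shape
        rr = (np.arange(h)[:, None] - (h - 1) / 2.0) / ((h - 1) / 2.0)
        cc = (np.arange(w)[None, :] - (w - 1) / 2.0) / ((w - 1) / 2.0)
        radial = (rr * rr + cc * cc) / 2.0  # 0 at center, 1 at corners
        irr = irr - acq.vignetting_amplitude * radial

    scaled = irr * (acq.exposure_ms / acq.exposure_ref_ms)
    saturation_fraction = float(np.mean(scaled >= 1.0))
    scaled = np.clip(scaled, 0.0, 1.0)

    crf = acq.crf if acq.crf is not None else CRFModel.identity()
    gray = 255.0 * np.asarray(crf(scaled), dtype=float)

    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    if spec.shot_noise:
        gray = rng.poisson(np.clip(gray, 0.0, None)).astype(float)
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)
    pixels = np.clip(np.round(gray), 0, 255).astype(np.uint8)

    metadata.setdefault("exposure_ms", acq.exposure_ms)
    img = RawImage(pixels=pixels, image_id=image_id, **metadata)
    img.extras["saturation_fraction"] = saturation_fraction
    img.extras["photobleach_decay"] = decay
    return img


def render_slide_series(
    truth: SceneTruth,
    acq: AcquisitionSpec,
    n_images: int,
    interval_s: float,
    **metadata,
) -> list[RawImage]:
    """Render a slide's acquisition series: frame ``k`` (0-based) carries
    cumulative excitation time ``acq.acquisition_time_s + k · interval_s``,
    so mean cell signal decays as ``exp(−rate · k · interval_s)``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    series = []
    for k in range(n_images):
        acq_k = replace(acq, acquisition_time_s=acq.acquisition_time_s + k * interval_s)
        img = render_image(
            truth,
            acq_k,
            seed=truth.seed + 1 + k,
            image_id=f"{metadata.get('slide_id', 'slide0')}_{k:03d}",
            acquisition_index=k,
            **{k2: v for k2, v in metadata.items() if k2 not in ("acquisition_index", "image_id")},
        )
        series.append(img)
    return series


def render_calibration_stack(
    exposures_ms: Sequence[float],
    crf: CRFModel | None = None,
    shape: tuple[int, int] = (128, 128),
    noise_sd: float = 0.0,
    seed: int = 0,
    max_irradiance: float = 0.98,
) -> list[RawImage]:
    """Exposure-bracketed stack of a static smooth-gradient phantom for CRF
    self-calibration.

    The phantom is a diagonal irradiance ramp spanning (0, ``max_irradiance``]
    at the longest exposure, so the stack covers most of the gray range
    (mimicking a brightfield field of view with broad intensity content).
    """
    exposures = [float(t) for t in exposures_ms]
    t_max = max(exposures)
    h, w = shape
    ramp = (np.arange(h)[:, None] + np.arange(w)[None, :] + 1.0) / (h + w)
    irr = ramp * max_irradiance
    crf = crf if crf is not None else CRFModel.identity()

    rng = np.random.default_rng(seed)
    stack = []
    for i, t in enumerate(exposures):
        gray = 255.0 * np.asarray(crf(np.clip(irr * (t / t_max), 0.0, 1.0)))
        if noise_sd > 0:
            gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
        px = np.clip(np.round(gray), 0, 255).astype(np.uint8)
        stack.append(RawImage(pixels=px, exposure_ms=t, image_id=f"calib_{i:02d}"))
    return stack


# ---------------------------------------------------------------------------
# truth-table text export
# ---------------------------------------------------------------------------

def write_truth_table(truth: SceneTruth, path: str | Path) -> Path:
    """Persist ground truth as a delimited text table (one row per cell)
    with all scene parameters and the seed in a comment header."""
    path = Path(path)
    spec = truth.spec
    header = [
        f"# image_height_px = {spec.image_height_px}",
        f"# image_width_px = {spec.image_width_px}",
        f"# n_cells = {spec.n_cells}",
        f"# cell_length_px_range = {spec.cell_length_px_range[0]} {spec.cell_length_px_range[1]}",
        f"# cell_width_px_range = {spec.cell_width_px_range[0]} {spec.cell_width_px_range[1]}",
        f"# mean_fluorescence = {spec.mean_fluorescence}",
        f"# cv2_true = {spec.cv2_true}",
        f"# background_level = {spec.background_level}",
        f"# background_gradient = {spec.background_gradient}",
        f"# noise_sd = {spec.noise_sd}",
        f"# seed = {truth.seed}",
    ]
    rows = [
        "cell_id\trow\tcol\torientation_rad\tlength_px\twidth_px\ttrue_fluorescence"
    ]
    for c in truth.cells:
        rows.append(
            f"{c.cell_id}\t{c.center[0]:.3f}\t{c.center[1]:.3f}\t"
            f"{c.orientation_rad:.6f}\t{c.length_px:.3f}\t{c.width_px:.3f}\t"
            f"{c.true_fluorescence:.8g}"
        )
    path.write_text("\n".join(header + rows) + "\n")
    return path


def read_truth_table(path: str | Path) -> pd.DataFrame:
    """Load a truth table written by :func:`write_truth_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
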