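"""Camera response function (CRF) calibration and inversion.

A camera maps scene irradiance to recorded gray level through its response
function ``g = f(E)``, which is non-linear in general and distorts the
empirical fluorescence distribution if left uncorrected.  Here the CRF is
modeled as a cubic polynomial on normalized axes (irradiance ``E`` and gray
level ``g`` both in ``[0, 1]``, with ``f(0) = 0`` and ``f(1) = 1`` fixing the
gauge freedom of the calibration problem).

Calibration follows the radiometric self-calibration idea: multiple images
of a static scene at different exposure times constrain the *inverse*
response, because the underlying irradiance of any pixel scales exactly with
exposure, ``f⁻¹(g_j) = (t_j / t_i) · f⁻¹(g_i)``.  The fit is a
Tikhonov-regularized least-squares problem whose weight is picked at the
corner of the L-curve (point of maximum curvature of the log residual-norm
vs log solution-norm trade-off).  The fitted cubic is inverted analytically
with Cardano's formula and tabulated into a 256-entry look-up table, one
entry per 8-bit gray level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage, optimize

from .images import RawImage

__all__ = [
    "CRFModel",
    "InverseLUT",
    "VignettingField",
    "VignettingReport",
    "PairSet",
    "cubic_real_roots",
    "collect_intensity_pairs",
    "fit_crf",
    "invert_crf",
    "build_vignetting_field",
    "check_vignetting_needed",
]

logger = logging.getLogger(__name__)

_MONOTONE_GRID = np.linspace(0.0, 1.0, 1025)


@dataclass
class CRFModel:
    """Cubic camera response ``g = a0 + a1·E + a2·E² + a3·E³`` on [0, 1]².

    ``regularization_weight`` is the Tikhonov weight selected on the L-curve
    during fitting and ``fit_residual`` the root-mean-square residual of the
    self-calibration constraints at that weight.
    """

    coefficients: np.ndarray
    regularization_weight: float = 0.0
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (4,):
            raise ValueError("CRFModel needs exactly 4 coefficients a0..a3")
        self.coefficients = c

    @classmethod
    def identity(cls) -> "CRFModel":
        return cls(np.array([0.0, 1.0, 0.0, 0.0]))

    def __call__(self, e: np.ndarray | float) -> np.ndarray | float:
        a0, a1, a2, a3 = self.coefficients
        e = np.asarray(e, dtype=float)
        out = a0 + e * (a1 + e * (a2 + e * a3))
        return out if out.shape else float(out)

    def derivative(self, e: np.ndarray | float) -> np.ndarray | float:
        _, a1, a2, a3 = self.coefficients
        e = np.asarray(e, dtype=float)
        out = a1 + e * (2.0 * a2 + e * 3.0 * a3)
        return out if out.shape else float(out)

    def is_valid(self, atol: float = 1e-6) -> bool:
        """Normalized (f(0)=0, f(1)=1) and increasing on [0, 1] (the
        derivative may touch zero at isolated points, e.g. f(E)=E³ at 0)."""
        ends_ok = abs(self(0.0)) <= atol and abs(self(1.0) - 1.0) <= atol
        return bool(ends_ok and np.all(self.derivative(_MONOTONE_GRID) >= -1e-9))

    def validate(self) -> None:
        if not self.is_valid():
            raise ValueError(
                "CRF not invertible; widen exposure range "
                f"(coefficients {self.coefficients.tolist()})"
            )


def cubic_real_roots(coeffs: Sequence[float], y: np.ndarray) -> np.ndarray:
    """Real roots of ``a0 + a1·x + a2·x² + a3·x³ = y`` by Cardano's method.

    Vectorized over the target values ``y``; returns an ``(len(y), 3)``
    array with NaN placeholders where fewer than three real roots exist.
    Degenerate leading coefficients fall back to the quadratic / linear
    closed forms.  Each real root receives one Newton polish step: the
    closed-form expressions lose a few digits to cancellation on
    near-degenerate cubics.
    """
    a0, a1, a2, a3 = (float(c) for c in coeffs)
    y = np.asarray(y, dtype=float)
    out = np.full(y.shape + (3,), np.nan)

    scale = max(abs(a0), abs(a1), abs(a2), abs(a3), 1.0)
    if abs(a3) < 1e-12 * scale:
        if abs(a2) < 1e-12 * scale:  # linear a1·x = y − a0
            if abs(a1) < 1e-12 * scale:
                return out
            out[..., 0] = (y - a0) / a1
            return out
        disc = a1 * a1 - 4.0 * a2 * (a0 - y)
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        out[..., 0] = np.where(ok, (-a1 + sq) / (2.0 * a2), np.nan)
        out[..., 1] = np.where(ok, (-a1 - sq) / (2.0 * a2), np.nan)
        return out

    # depressed cubic t³ + p·t + q = 0 with x = t − a2/(3·a3)
    b, c = a2 / a3, a1 / a3
    d = (a0 - y) / a3
    shift = b / 3.0
    p = c - b * b / 3.0
    q = 2.0 * b**3 / 27.0 - b * c / 3.0 + d

    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    three = disc < -1e-15 * scale  # three distinct real roots
    single = ~three

    if np.any(three):
        m = 2.0 * np.sqrt(-p / 3.0)
        theta = np.arccos(np.clip(3.0 * q[three] / (p * m), -1.0, 1.0)) / 3.0
        for k in range(3):
            out[three, k] = m * np.cos(theta - 2.0 * np.pi * k / 3.0) - shift

    if np.any(single):
        dd = np.maximum(disc[single], 0.0)
        sq = np.sqrt(dd)
        u = np.cbrt(-q[single] / 2.0 + sq)
        v = np.cbrt(-q[single] / 2.0 - sq)
        out[single, 0] = u + v - shift

    real = ~np.isnan(out)
    if np.any(real):
        x = out[real]
        yy = np.broadcast_to(y[..., None], out.shape)[real]
        fx = a0 + x * (a1 + x * (a2 + x * a3)) - yy
        dfx = a1 + x * (2.0 * a2 + x * 3.0 * a3)
        safe = np.abs(dfx) > 1e-12
        x = np.where(safe, x - fx / np.where(dfx == 0, 1.0, dfx), x)
        out[real] = x
    return out


def _invert_on_grid(coeffs: np.ndarray, targets: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Invert the cubic at a sorted grid of targets, selecting the root in
    [0, 1] and breaking rare ties by continuity with the previous entry.

    A single Newton step polishes each analytic root: the closed-form
    expressions lose a few digits to cancellation on near-degenerate
    cubics, and the polish restores full double precision.
    """
    a0, a1, a2, a3 = (float(c) for c in coeffs)
    roots = cubic_real_roots(coeffs, targets)
    inside = (roots >= -tol) & (roots <= 1.0 + tol)
    picked = np.empty(len(targets))
    prev = 0.0
    for i in range(len(targets)):
        cand = roots[i][inside[i]]
        if cand.size == 0:
            raise ValueError(
                f"no CRF root in [0, 1] for normalized gray level {targets[i]:.6f}"
            )
        picked[i] = cand[np.argmin(np.abs(cand - prev))]
        prev = picked[i]
    e = np.clip(picked, 0.0, 1.0)
    f = a0 + e * (a1 + e * (a2 + e * a3))
    df = a1 + e * (2.0 * a2 + e * 3.0 * a3)
    step = np.where(np.abs(df) > 1e-12, (f - targets) / np.where(df == 0, 1.0, df), 0.0)
    return np.clip(e - step, 0.0, 1.0)


@dataclass
class InverseLUT:
    """256-entry look-up table: gray level ``g`` → normalized irradiance
    ``E`` with ``f(E) = g/255``.  Non-decreasing, entry 0 = 0, entry 255 = 1.
    """

    values: np.ndarray
    source: CRFModel | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (256,):
            raise ValueError("InverseLUT needs exactly 256 entries")
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("InverseLUT entries must be non-decreasing")
        self.values = v

    def __getitem__(self, g: int | np.ndarray) -> float | np.ndarray:
        return self.values[g]

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        """Replace each 8-bit pixel with its normalized irradiance."""
        if pixels.dtype != np.uint8:
            raise ValueError("LUT applies to 8-bit images")
        return self.values[pixels]

    @classmethod
    def identity(cls) -> "InverseLUT":
        return cls(np.arange(256) / 255.0, source=CRFModel.identity())

    def save(self, path: str | Path) -> Path:
        """Persist as a 256-line text file ``gray<TAB>irradiance`` with the
        CRF coefficients and regularization weight in a comment header."""
        path = Path(path)
        lines = []
        if self.source is not None:
            c = self.source.coefficients
            lines.append(
                "# crf_coefficients = "
                + " ".join(f"{v:.12g}" for v in c)
            )
            lines.append(
                f"# regularization_weight = {self.source.regularization_weight:.6g}"
            )
            lines.append(f"# fit_residual = {self.source.fit_residual:.6g}")
        lines += [f"{g}\t{self.values[g]:.12g}" for g in range(256)]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "InverseLUT":
        source = None
        coeffs = None
        weight = 0.0
        residual = 0.0
        values = np.zeros(256)
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("crf_coefficients"):
                    coeffs = np.array(
                        [float(v) for v in body.split("=")[1].split()]
                    )
                elif body.startswith("regularization_weight"):
                    weight = float(body.split("=")[1])
                elif body.startswith("fit_residual"):
                    residual = float(body.split("=")[1])
                continue
            g_str, e_str = line.split()
            values[int(g_str)] = float(e_str)
        if coeffs is not None:
            source = CRFModel(coeffs, weight, residual)
        return cls(values, source=source)


# ---------------------------------------------------------------------------
# self-calibration from exposure-bracketed stacks
# ---------------------------------------------------------------------------

@dataclass
class PairSet:
    """Per-pixel gray-level pairs across exposure-bracketed images.

    ``g_lo``/``g_hi`` are the gray levels of the shorter/longer exposure of
    each image pair, and ``ratio`` the exposure ratio ``t_hi / t_lo ≥ 1``.
    Saturated (255) and dark-floor pixels are excluded at collection time:
    saturated levels carry no radiometric information, and near-floor
    levels carry noise amplified by the exposure ratio into the fit.
    """

    g_lo: np.ndarray
    g_hi: np.ndarray
    ratio: np.ndarray
    excluded_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.g_lo)

    @property
    def n_distinct_gray(self) -> int:
        return len(np.unique(np.concatenate([self.g_lo, self.g_hi])))


def collect_intensity_pairs(
    stack: Sequence[RawImage],
    dark_floor: int = 20,
    max_pairs_per_image_pair: int = 100_000,
    seed: int = 0,
    allow_equal_exposures: bool = False,
) -> PairSet:
    """Build the self-calibration pair set from a static-scene stack.

    Every pair of frames at distinct exposures contributes per-pixel
    ``(g_i, g_j, t_j/t_i)`` triples (longer exposure second).  Pixels
    saturated (gray 255) in either frame, or at/below the dark floor in
    either frame, are excluded; pair counts are capped at
    ``max_pairs_per_image_pair`` by seeded uniform subsampling.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 images to collect intensity pairs")
    shapes = {img.pixels.shape for img in stack}
    if len(shapes) != 1:
        raise ValueError(f"stack images differ in shape: {sorted(shapes)}")
    exposures = np.array([img.exposure_ms for img in stack], dtype=float)
    if len(np.unique(exposures)) < 2 and not allow_equal_exposures:
        raise ValueError("need at least 2 distinct exposure times")

    rng = np.random.default_rng(seed)
    g_lo, g_hi, ratio = [], [], []
    total_px = 0
    kept_px = 0
    for i in range(len(stack)):
        for j in range(i + 1, len(stack)):
            lo, hi = (i, j) if exposures[i] <= exposures[j] else (j, i)
            if exposures[lo] == exposures[hi] and not allow_equal_exposures:
                continue
            a = stack[lo].pixels.ravel()
            b = stack[hi].pixels.ravel()
            ok = (a < 255) & (b < 255) & (a > dark_floor) & (b > dark_floor)
            total_px += a.size
            idx = np.flatnonzero(ok)
            kept_px += idx.size
            if idx.size > max_pairs_per_image_pair:
                idx = rng.choice(idx, size=max_pairs_per_image_pair, replace=False)
            g_lo.append(a[idx])
            g_hi.append(b[idx])
            ratio.append(np.full(idx.size, exposures[hi] / exposures[lo]))

    excluded = 1.0 - kept_px / total_px if total_px else 0.0
    if excluded > 0.5:
        logger.warning(
            "%.0f%% of pixels excluded (saturated or dark floor); "
            "CRF fit may be unreliable", 100 * excluded,
        )
    return PairSet(
        g_lo=np.concatenate(g_lo) if g_lo else np.empty(0, dtype=np.uint8),
        g_hi=np.concatenate(g_hi) if g_hi else np.empty(0, dtype=np.uint8),
        ratio=np.concatenate(ratio) if ratio else np.empty(0),
        excluded_fraction=excluded,
    )


def _lcurve_corner(
    lams: np.ndarray,
    rho: np.ndarray,
    eta: np.ndarray,
    admissible: np.ndarray | None = None,
) -> int:
    """Index of the maximum-curvature point of the L-curve (log–log),
    optionally restricted to an admissible subset of weights."""
    x = np.log(np.maximum(rho, 1e-300))
    y = np.log(np.maximum(eta, 1e-300))
    t = np.log(lams)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx * dx + dy * dy) ** 1.5
    kappa = np.where(denom > 0, (dx * ddy - dy * ddx) / np.maximum(denom, 1e-300), 0.0)
    if admissible is not None:
        kappa = np.where(admissible, kappa, -np.inf)
    return int(np.argmax(kappa))


def fit_crf(
    pairs: PairSet,
    degree: int = 3,
    inverse_degree: int | None = None,
    n_weights: int = 50,
    refine: bool = True,
) -> CRFModel:
    """Fit the cubic CRF from exposure-bracketed pixel pairs.

    The inverse response ``h(g)`` is first fitted as a polynomial of degree
    ``inverse_degree`` (default ``2·degree − 1``) by ridge-regularized
    linear least squares on the self-calibration constraints
    ``h(g_hi) = ratio · h(g_lo)``, gauge-fixed to ``h(0)=0, h(1)=1``.  The
    Tikhonov weight is chosen at the L-curve corner over ``n_weights``
    log-spaced weights.  A forward cubic ``f`` with ``f(0)=0, f(1)=1`` is
    then fitted through the recovered inverse curve and, when ``refine`` is
    on, polished by a short nonlinear least-squares pass of the forward
    coefficients directly against the pair constraints.
    """
    if pairs.n_distinct_gray < 10:
        raise ValueError(
            f"pair set spans only {pairs.n_distinct_gray} distinct gray levels "
            "(need >= 10); acquire a wider-range stack"
        )
    if degree < 1:
        raise ValueError("degree must be >= 1")
    K = inverse_degree if inverse_degree is not None else max(2 * degree - 1, degree)

    x_lo = pairs.g_lo.astype(float) / 255.0
    x_hi = pairs.g_hi.astype(float) / 255.0
    R = pairs.ratio

    # basis phi_k = x_hi^k − R·x_lo^k, k = 1..K; constraint Σ c_k = 1
    phi = np.stack([x_hi**k - R * x_lo**k for k in range(1, K + 1)], axis=1)
    A = phi[:, :-1] - phi[:, -1:]
    b = -phi[:, -1]

    ata = A.T @ A
    atb = A.T @ b
    scale = np.trace(ata) / max(A.shape[1], 1)
    lams = np.logspace(-10, 2, n_weights) * max(scale, 1e-30)

    eye = np.eye(A.shape[1])
    rho = np.empty(n_weights)
    eta = np.empty(n_weights)
    sols = np.empty((n_weights, A.shape[1]))
    monotone = np.zeros(n_weights, dtype=bool)
    grid = _MONOTONE_GRID
    for i, lam in enumerate(lams):
        c_red = np.linalg.solve(ata + lam * eye, atb)
        sols[i] = c_red
        rho[i] = np.linalg.norm(A @ c_red - b)
        c_full = np.append(c_red, 1.0 - c_red.sum())
        eta[i] = np.linalg.norm(c_full)
        h_i = np.polyval(np.concatenate([c_full[::-1], [0.0]]), grid)
        # tolerate numerically negligible dips (h spans [0, 1]); tiny
        # non-monotonicity is flattened before the forward refit anyway
        monotone[i] = bool(np.all(np.diff(h_i) >= -1e-4))
    if not np.any(monotone):
        raise ValueError("CRF not invertible; widen exposure range")
    # L-curve corner, restricted to weights whose inverse curve is a
    # physically admissible (monotone) response
    corner = _lcurve_corner(lams, rho, eta, admissible=monotone)
    lam = float(lams[corner])
    c = np.append(sols[corner], 1.0 - sols[corner].sum())

    h = np.polyval(np.concatenate([c[::-1], [0.0]]), grid)  # h(0)=0 built in
    h = np.maximum.accumulate(np.clip(h, 0.0, None))
    if h[-1] <= 0:
        raise ValueError("CRF not invertible; widen exposure range")
    h /= h[-1]

    # forward cubic through (E, g) = (h(grid), grid), f(0)=0, f(1)=1
    coeffs = _fit_forward(h, grid, degree)
    model = CRFModel(coeffs, regularization_weight=lam)

    if refine and degree > 1:
        model = _refine_forward(model, pairs, degree)
    model.validate()
    res = _pair_residuals(model.coefficients, x_lo, x_hi, R)
    model.fit_residual = float(np.sqrt(np.mean(res**2)))
    return model


def _fit_forward(e: np.ndarray, g: np.ndarray, degree: int) -> np.ndarray:
    """LS fit of g = Σ b_k e^k with b's summing to 1 (f(1)=1), a0 = 0."""
    cols = [e**k - e**degree for k in range(1, degree)]
    design = np.stack(cols, axis=1) if cols else np.empty((len(e), 0))
    target = g - e**degree
    bb, *_ = np.linalg.lstsq(design, target, rcond=None)
    b_full = np.append(bb, 1.0 - bb.sum())
    coeffs = np.zeros(4)
    coeffs[1 : degree + 1] = b_full
    return coeffs


def _pair_residuals(coeffs: np.ndarray, x_lo, x_hi, R) -> np.ndarray:
    levels = np.unique(np.concatenate([x_lo, x_hi]))
    try:
        inv = _invert_on_grid(coeffs, levels)
    except ValueError:
        return np.full(len(x_lo), 1e3)
    table = dict(zip(levels, inv))
    e_lo = np.array([table[v] for v in x_lo])
    e_hi = np.array([table[v] for v in x_hi])
    return e_hi - R * e_lo


def _coeffs_from_free(bb: np.ndarray, degree: int) -> np.ndarray:
    """Forward coefficients a0..a3 from the free parameters b1..b_{d-1}
    (a0 = 0 and Σ b = 1 fix the gauge)."""
    coeffs = np.zeros(4)
    coeffs[1:degree] = bb
    coeffs[degree] = 1.0 - np.sum(bb)
    return coeffs


def _refine_forward(model: CRFModel, pairs: PairSet, degree: int, bound: float = 8.0) -> CRFModel:
    """Polish the forward coefficients against the pair constraints.

    The forward family has only ``degree − 1`` free parameters, so the
    direct self-calibration objective is well posed where the flexible
    inverse-polynomial stage is not.  A coarse grid search over monotone
    candidates guards against the degenerate basin (arbitrarily steep
    responses make all pair residuals vanish), and a bounded trust-region
    pass finishes from the best of {linear-stage estimate, grid winner}.
    """
    n = len(pairs)
    step = max(1, n // 3000)
    x_lo = pairs.g_lo[::step].astype(float) / 255.0
    x_hi = pairs.g_hi[::step].astype(float) / 255.0
    R = pairs.ratio[::step]

    def cost(bb: np.ndarray) -> float:
        coeffs = _coeffs_from_free(bb, degree)
        if not CRFModel(coeffs).is_valid(atol=1e-6):
            return np.inf
        r = _pair_residuals(coeffs, x_lo, x_hi, R)
        return float(np.sum(r * r))

    b_init = model.coefficients[1:degree].copy()
    axis = np.linspace(-3.0, 3.0, 13)
    if degree == 2:
        grid_pts = axis[:, None]
    else:
        grid_pts = np.stack(np.meshgrid(axis, axis), axis=-1).reshape(-1, 2)
    grid_costs = np.array([cost(bb) for bb in grid_pts])
    order = np.argsort(grid_costs)
    starts = [b_init] + [grid_pts[i] for i in order[:5] if np.isfinite(grid_costs[i])]
    grid_best: np.ndarray | None = (
        grid_pts[order[0]] if np.isfinite(grid_costs[order[0]]) else None
    )
    if len(starts) == 1 and not np.isfinite(cost(b_init)):
        return model

    def residuals(bb: np.ndarray) -> np.ndarray:
        coeffs = _coeffs_from_free(bb, degree)
        r = _pair_residuals(coeffs, x_lo, x_hi, R)
        # soft barrier keeping the response monotone: non-monotone cubics
        # can fake small pair residuals through spurious root branches
        min_deriv = float(np.min(CRFModel(coeffs).derivative(_MONOTONE_GRID)))
        penalty = 50.0 * max(0.0, -min_deriv) * np.sqrt(len(r))
        return np.append(r, penalty)

    best: tuple[float, np.ndarray] | None = None
    for start in starts:
        sol = optimize.least_squares(
            residuals,
            np.clip(start, -bound + 1e-6, bound - 1e-6),
            method="trf",
            bounds=(-bound, bound),
            max_nfev=80,
        )
        candidate = CRFModel(_coeffs_from_free(sol.x, degree))
        if candidate.is_valid() and (best is None or sol.cost < best[0]):
            best = (float(sol.cost), sol.x.copy())
    if best is None:
        if model.is_valid():
            return model  # keep the regularized solution if the polish strayed
        if grid_best is not None:
            return CRFModel(
                _coeffs_from_free(grid_best, degree),
                regularization_weight=model.regularization_weight,
            )
        return model
    return CRFModel(
        _coeffs_from_free(best[1], degree),
        regularization_weight=model.regularization_weight,
    )


def invert_crf(model: CRFModel) -> InverseLUT:
    """Tabulate the analytic (Cardano) inverse at the 256 gray levels."""
    model.validate()
    targets = np.arange(256) / 255.0
    values = _invert_on_grid(model.coefficients, targets)
    values[0] = 0.0
    values[255] = 1.0
    return InverseLUT(values, source=model)


# ---------------------------------------------------------------------------
# vignetting
# ---------------------------------------------------------------------------

@dataclass
class VignettingField:
    """Additive per-pixel correction: adding ``field`` to the flat-field
    source image yields a spatially uniform image."""

    field: np.ndarray
    exposure_ms: float

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        tifffile.imwrite(path, self.field.astype(np.float32))
        return path

    @classmethod
    def load(cls, path: str | Path, exposure_ms: float = 0.0) -> "VignettingField":
        return cls(field=tifffile.imread(path).astype(float), exposure_ms=exposure_ms)


def build_vignetting_field(flat: RawImage, max_saturated_fraction: float = 0.01) -> VignettingField:
    """Correction field from a flat-field image of a uniform emitter:
    ``field = median(flat) − flat`` pixel-wise."""
    px = flat.pixels.astype(float)
    if px.ndim == 3:
        px = px[:, :, 0].astype(float)
    sat = np.mean(px >= 255)
    if sat > max_saturated_fraction:
        raise ValueError(
            f"flat-field image saturated over {100 * sat:.1f}% of pixels "
            f"(limit {100 * max_saturated_fraction:.0f}%); reduce exposure"
        )
    return VignettingField(field=np.median(px) - px, exposure_ms=flat.exposure_ms)


@dataclass
class VignettingReport:
    """Per-exposure spatial nonuniformity of flat-field images."""

    exposure_ms: list[float]
    nonuniformity: list[float]
    flagged: list[bool]
    threshold: float

    @property
    def correction_recommended(self) -> bool:
        return any(self.flagged)


def check_vignetting_needed(
    flats: Sequence[RawImage],
    threshold: float = 0.02,
    smoothing_sigma: float | None = None,
) -> VignettingReport:
    """Assess whether vignetting correction is warranted.

    The nonuniformity statistic is the relative range (max − min over the
    median) of a Gaussian-smoothed flat field; exposures whose statistic
    reaches ``threshold`` (boundary inclusive) are flagged.
    """
    if not flats:
        raise ValueError("need at least one flat-field image")
    exposures, stats, flags = [], [], []
    for flat in flats:
        px = flat.pixels.astype(float)
        if px.ndim == 3:
            px = px[:, :, 0].astype(float)
        sigma = smoothing_sigma if smoothing_sigma is not None else max(3.0, min(px.shape) / 32.0)
        smooth = ndimage.gaussian_filter(px, sigma, mode="nearest")
        med = np.median(smooth)
        stat = float((smooth.max() - smooth.min()) / med) if med > 0 else np.inf
        exposures.append(flat.exposure_ms)
        stats.append(stat)
        flags.append(stat >= threshold)
    return VignettingReport(exposures, stats, flags, threshold)
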