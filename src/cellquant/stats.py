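"""Population statistics, calibrator normalization, and QC reports.

Single-cell fluorescence values only become comparable across sessions,
instruments and exposure settings after normalization to a calibrator — a
reference sample (the maximally induced culture) measured in every
experiment, so that unmodeled multiplicative drifts (lamp aging,
temperature) cancel.  Population noise is quantified by the squared
coefficient of variation, CV² = (σ/μ)², which is dimensionless and hence
invariant under that normalization.  Before comparing populations their
cardinalities are equalized by seeded subsampling, preventing distortions
from unequal sample sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats as sps

__all__ = [
    "SampleDistribution",
    "PopulationStats",
    "FitResult",
    "PhotobleachReport",
    "population_stats",
    "normalize_to_calibrator",
    "equalize_cardinality",
    "compare_distributions",
    "cross_instrument_fit",
    "assess_photobleaching",
    "subgroup_stability",
]


@dataclass
class SampleDistribution:
    """Per-cell fluorescence values of one sample/induction condition."""

    sample_id: str
    values: np.ndarray
    induction_label: str = ""
    is_calibrator: bool = False
    n_biological_replicates: int = 1
    replicate_ids: np.ndarray | None = None  # per-value replicate assignment

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be a 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        self.values = v
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != v.shape:
                raise ValueError("replicate_ids must align with values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class PopulationStats:
    """Mean, sample SD, standard error and CV² = (σ/μ)² of a population.

    The SE is computed across biological-replicate means when replicate
    structure is available (``se_method = "replicates"``), otherwise as
    σ/√n (``se_method = "sem"``).
    """

    mean: float
    sd: float
    se: float
    cv2: float
    n: int
    se_method: str = "sem"


def population_stats(
    values: Sequence[float] | SampleDistribution,
    replicate_ids: Sequence | None = None,
) -> PopulationStats:
    """Statistical modes of a fluorescence distribution: average, sample
    (n−1) standard deviation, standard error, and CV² = (σ/μ)²."""
    if isinstance(values, SampleDistribution):
        replicate_ids = values.replicate_ids if replicate_ids is None else replicate_ids
        values = values.values
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for population statistics")
    mu = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd > 0 and mu == 0:
        raise ValueError("CV^2 undefined: zero mean with nonzero dispersion")
    cv2 = 0.0 if sd == 0 else (sd / mu) ** 2

    if replicate_ids is not None:
        rep = np.asarray(replicate_ids)
        rep_means = [float(np.mean(v[rep == r])) for r in np.unique(rep)]
        if len(rep_means) > 1:
            se = float(np.std(rep_means, ddof=1) / math.sqrt(len(rep_means)))
            return PopulationStats(mu, sd, se, cv2, v.size, se_method="replicates")
    se = sd / math.sqrt(v.size)
    return PopulationStats(mu, sd, se, cv2, v.size, se_method="sem")


def normalize_to_calibrator(
    sample: SampleDistribution, calibrator: SampleDistribution
) -> SampleDistribution:
    """Divide every value by the calibrator's mean fluorescence.

    The calibrator (tested circuit at the highest induction level) sees
    the same session-specific distortions as the sample, so the division
    is an implicit correction factor; the calibrator normalized by itself
    has mean exactly 1.
    """
    cal_mean = calibrator.mean
    if cal_mean <= 0:
        raise ValueError(f"calibrator '{calibrator.sample_id}' has non-positive mean")
    return replace(sample, values=sample.values / cal_mean)


def equalize_cardinality(
    samples: Sequence[SampleDistribution], n_target: int, seed: int = 0
) -> list[SampleDistribution]:
    """Subsample every population to exactly ``n_target`` cells (uniform,
    without replacement, deterministic given ``seed``)."""
    if n_target < 1:
        raise ValueError("n_target must be positive")
    for s in samples:
        if s.n < n_target:
            raise ValueError(
                f"sample '{s.sample_id}' has only {s.n} cells (< n_target={n_target})"
            )
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        if s.n == n_target:
            out.append(s)
            continue
        idx = rng.choice(s.n, size=n_target, replace=False)
        rep = s.replicate_ids[idx] if s.replicate_ids is not None else None
        out.append(replace(s, values=s.values[idx], replicate_ids=rep))
    return out


def compare_distributions(
    a: SampleDistribution | Sequence[float], b: SampleDistribution | Sequence[float]
) -> float:
    """Two-sided Mann–Whitney U p-value between two populations.

    Exact null enumeration is used for small tie-free samples (both
    n ≤ 20); otherwise the normal approximation with tie and continuity
    corrections.
    """
    va = a.values if isinstance(a, SampleDistribution) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, SampleDistribution) else np.asarray(b, dtype=float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need at least 2 values per group for the rank-sum test")
    if len(va) < 8 or len(vb) < 8:
        warnings.warn(
            "rank-sum test on fewer than 8 values per group has very "
            "limited power", stacklevel=2,
        )
    has_ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
    method = "exact" if (len(va) <= 20 and len(vb) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(va, vb, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class FitResult:
    """Polynomial dose-response / cross-instrument fit summary."""

    degree: int
    coefficients: np.ndarray  # ascending powers
    r_squared: float
    mse: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return npoly.polyval(np.asarray(x, dtype=float), self.coefficients)


def cross_instrument_fit(
    x: Sequence[float], y: Sequence[float], degree: int = 1
) -> FitResult:
    """Ordinary least-squares polynomial fit (degree 1 or 2) between
    condition-level values measured on two instruments, with R² and MSE
    evaluated on the fitted points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if len(np.unique(x)) < degree + 1:
        raise ValueError("degenerate (collinear/duplicate) x values for this degree")
    coeffs = npoly.polyfit(x, y, degree)
    pred = npoly.polyval(x, coeffs)
    resid = y - pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(degree=degree, coefficients=coeffs, r_squared=r2, mse=mse)


@dataclass
class PhotobleachReport:
    """First-third vs last-third signal comparison for one slide's
    acquisition series."""

    slide_id: str
    mean_first_third: float
    mean_last_third: float
    decay_ratio: float
    passed: bool
    threshold: float
    n_images: int


#: Acquisition caps under which photobleaching decay stays negligible on
#: the reference set-up: at most 15 images and 120 s of excitation per slide.
MAX_IMAGES_PER_SLIDE = 15
MAX_SLIDE_TIME_S = 120.0


def assess_photobleaching(
    per_image_means: Sequence[float],
    threshold: float = 0.95,
    slide_id: str = "",
) -> PhotobleachReport:
    """Compare the average fluorescence of the first and last third of a
    slide's images; the slide passes when the last/first ratio is at least
    ``threshold``.

    With ``n`` images each third holds ``floor(n/3)`` images (so for 3
    images: first third = image 1, last third = image 3).
    """
    means = np.asarray(per_image_means, dtype=float)
    if means.size < 3:
        raise ValueError("need at least 3 images to assess photobleaching")
    k = means.size // 3
    first = float(np.mean(means[:k]))
    last = float(np.mean(means[-k:]))
    ratio = last / first if first != 0 else np.inf
    return PhotobleachReport(
        slide_id=slide_id,
        mean_first_third=first,
        mean_last_third=last,
        decay_ratio=ratio,
        passed=bool(ratio >= threshold),
        threshold=threshold,
        n_images=means.size,
    )


def subgroup_stability(
    samples: Sequence[SampleDistribution],
    group_sizes: Sequence[int],
    statistic: str = "mean",
    seed: int = 0,
) -> dict[int, float]:
    """Correlation between disjoint-subgroup statistics and full-population
    statistics, per subgroup size.

    For each size, every condition's population is split (after a seeded
    shuffle) into disjoint groups of that size; the per-condition group
    statistic is correlated (Pearson) with the per-condition full-population
    statistic, and correlations are averaged over the disjoint groups.
    This measures how many cells are needed before subsampled acquisition
    reproduces the full-population dose response.
    """
    if statistic not in ("mean", "cv2"):
        raise ValueError("statistic must be 'mean' or 'cv2'")

    def stat_of(v: np.ndarray) -> float:
        if statistic == "mean":
            return float(np.mean(v))
        return population_stats(v).cv2

    full = np.array([stat_of(s.values) for s in samples])
    rng = np.random.default_rng(seed)
    shuffled = [rng.permutation(s.values) for s in samples]
    out: dict[int, float] = {}
    for size in group_sizes:
        n_groups = min(s.n for s in samples) // size
        if n_groups < 1:
            raise ValueError(f"group size {size} exceeds the smallest population")
        corrs = []
        for g in range(n_groups):
            sub = np.array(
                [stat_of(v[g * size : (g + 1) * size]) for v in shuffled]
            )
            corrs.append(float(np.corrcoef(sub, full)[0, 1]))
        out[size] = float(np.mean(corrs))
    return out
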