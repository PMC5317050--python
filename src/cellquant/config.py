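"""Run configuration: a plain-text key = value file, overridable from the
command line."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "parse_config_file"]


@dataclass
class RunConfig:
    """Parameters of a quantification run.

    Segmentation: ``sigma_px`` (Gaussian smoothing), ``threshold_multiplier``
    (gradient gate as a multiple of the robust noise scale), ``se_radius_px``
    (background structuring-element radius, at least the cells' half-width),
    ``min_area_px``/``max_area_px`` (component filter), ``erosion_iterations``
    (0 disables the finishing erosion).  Analysis: ``n_target`` cells per
    population after cardinality equalization, ``photobleach_threshold`` for
    the first/last-third decay ratio, and per-slide acquisition caps.
    """

    input_dir: str = "."
    output_dir: str = ""  # empty → 'Results' sibling of input_dir
    metadata_path: str = ""
    lut_path: str = ""
    vignetting_path: str = ""
    sigma_px: float = 2.0
    threshold_multiplier: float = 3.0
    gradient_threshold: float = -1.0  # <0 → adaptive (noise-scaled)
    se_radius_px: int = 15
    min_area_px: int = 20
    max_area_px: int = 2000
    erosion_iterations: int = 2
    linearize_first: bool = False
    fov_fraction: float = 1.0
    n_target: int = 12000
    seed: int = 0
    photobleach_threshold: float = 0.95
    max_images_per_slide: int = 15
    max_slide_time_s: float = 120.0
    vignetting_nonuniformity_threshold: float = 0.02
    verbosity: str = "info"

    def validate(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.se_radius_px < 1:
            raise ValueError("se_radius_px must be >= 1")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must be <= max_area_px")
        if not (0 < self.photobleach_threshold <= 1):
            raise ValueError("photobleach_threshold must lie in (0, 1]")
        if self.n_target < 1:
            raise ValueError("n_target must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        values = parse_config_file(path)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(values)

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(values) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _coerce(field_type: str, raw: str):
    raw = raw.strip()
    if field_type == "bool":
        return raw.lower() in ("1", "true", "yes", "on")
    if field_type == "int":
        return int(raw)
    if field_type == "float":
        return float(raw)
    return raw


def parse_config_file(path: str | Path) -> dict:
    """Parse ``key = value`` lines (``#`` comments allowed) into typed
    values matching :class:`RunConfig` fields."""
    types = {f.name: f.type for f in fields(RunConfig)}
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in types:
            raise ValueError(f"{path}:{lineno}: unknown config key '{key}'")
        out[key] = _coerce(types[key], raw)
    return out
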