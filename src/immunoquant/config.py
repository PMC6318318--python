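"""Structured configuration for every pipeline stage.

Defaults anchor to the published analysis parameters: 5-px closing
kernel, solidity cutoff 0.8, 2% image-area feeder rule, 1%/1% contrast
saturation, size band up to twice the diffraction limit, 5x/0.5x
typical-cell-area rules and the radius/3 cytoplasm band. Everything a
user might legitimately retune is exposed here; unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for malformed or constraint-violating configuration."""


@dataclass
class SegmentationConfig:
    """Parameters for DAPI nucleus segmentation and the exclusion filters."""

    min_object_px: int = 64
    closing_radius_px: int = 5
    solidity_min: float = 0.8
    max_area_fraction: float = 0.02
    connectivity: int = 2
    keep_border_objects: bool = True

    def validate(self) -> None:
        if self.min_object_px < 1:
            raise ConfigError("min_object_px must be a positive integer")
        if self.closing_radius_px < 1:
            raise ConfigError("closing_radius_px must be a positive integer")
        if not (0.0 < self.solidity_min <= 1.0):
            raise ConfigError("solidity_min must lie in (0, 1]")
        if not (0.0 < self.max_area_fraction < 1.0):
            raise ConfigError("max_area_fraction must lie in (0, 1)")
        if self.connectivity not in (1, 2):
            raise ConfigError("connectivity must be 1 (4-conn) or 2 (8-conn)")


@dataclass
class FociConfig:
    """Parameters for band-pass punctum detection and control calibration.

    ``diffraction_limit_px`` is a required optics parameter (it depends on
    the microscope and camera, which vary between runs); the band of
    accepted sizes is ``(noise_size_px, max_size_factor * diffraction_limit_px]``.
    """

    diffraction_limit_px: float = 3.0
    noise_size_px: float = 2.5
    max_size_factor: float = 2.0
    saturate_low_pct: float = 1.0
    saturate_high_pct: float = 1.0
    min_peak_prominence: float = 0.25
    response_threshold: float | None = None  # None -> Otsu on positive response
    control_stat: str = "mean"

    @property
    def upper_band_px(self) -> float:
        return self.max_size_factor * self.diffraction_limit_px

    def validate(self) -> None:
        if self.diffraction_limit_px <= 0:
            raise ConfigError("diffraction_limit_px must be positive")
        if self.noise_size_px <= 0:
            raise ConfigError("noise_size_px must be positive")
        if self.noise_size_px >= self.upper_band_px:
            raise ConfigError(
                "noise_size_px must be below max_size_factor * diffraction_limit_px"
            )
        if not (0 <= self.saturate_low_pct < 50 and 0 <= self.saturate_high_pct < 50):
            raise ConfigError("saturation percentages must lie in [0, 50)")
        if self.min_peak_prominence < 0:
            raise ConfigError("min_peak_prominence must be nonnegative")
        if self.control_stat != "mean":
            raise ConfigError("control_stat must be 'mean'")


@dataclass
class FollicleConfig:
    """Parameters for tissue-cell segmentation and per-compartment statistics.

    ``typical_cell_area_px`` mirrors the manually established cell size
    and is required per run.
    """

    typical_cell_area_px: float = 0.0  # required; 0 means unset
    log_sigma_px: float = 3.0  # ~half the typical cell radius
    median_filter_radius_px: int = 3
    large_object_factor: float = 5.0
    small_object_factor: float = 0.5
    band_fraction: float = 1.0 / 3.0
    outlier_rule: str = "iqr_fence"
    outlier_fence_multiplier: float = 3.0
    tie_break_compartment: str = "GC"

    def validate(self, require_cell_area: bool = True) -> None:
        if require_cell_area and self.typical_cell_area_px <= 0:
            raise ConfigError("typical_cell_area_px is required and must be positive")
        if self.log_sigma_px <= 0:
            raise ConfigError("log_sigma_px must be positive")
        if self.median_filter_radius_px < 1:
            raise ConfigError("median_filter_radius_px must be a positive integer")
        if not (0 < self.small_object_factor < 1 < self.large_object_factor):
            raise ConfigError(
                "need 0 < small_object_factor < 1 < large_object_factor"
            )
        if not (0 < self.band_fraction < 1):
            raise ConfigError("band_fraction must lie in (0, 1)")
        if self.outlier_rule != "iqr_fence":
            raise ConfigError("outlier_rule must be 'iqr_fence'")
        if self.outlier_fence_multiplier <= 0:
            raise ConfigError("outlier_fence_multiplier must be positive")
        if self.tie_break_compartment not in ("GC", "FO"):
            raise ConfigError("tie_break_compartment must be 'GC' or 'FO'")


@dataclass
class SceneParams:
    """Parameters of a synthetic feeder-coculture field for focus counting."""

    image_height_px: int = 512
    image_width_px: int = 512
    n_bcell_nuclei: int = 50
    bcell_radius_px: float = 14.0
    n_feeder_nuclei: int = 3
    feeder_radius_px: float = 45.0
    n_multinuclear: int = 2
    # int (fixed k), {"poisson": mean}, or {"uniform": [lo, hi]} inclusive
    foci_per_nucleus: Any = 3
    focus_sigma_px: float = 1.2
    focus_amplitude: float = 20000.0
    focus_min_separation_px: float = 8.0
    nucleus_amplitude: float = 20000.0
    background_level: float = 2000.0
    noise_sigma: float = 0.0
    poisson_noise: bool = False
    min_gap_px: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ConfigError("scene must be at least 64x64")
        for name in ("bcell_radius_px", "feeder_radius_px", "focus_sigma_px",
                     "focus_amplitude", "nucleus_amplitude"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_bcell_nuclei", "n_feeder_nuclei", "n_multinuclear"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.background_level < 0 or self.noise_sigma < 0:
            raise ConfigError("background_level and noise_sigma must be nonnegative")
        spec = self.foci_per_nucleus
        if isinstance(spec, dict):
            if set(spec) == {"poisson"}:
                if spec["poisson"] < 0:
                    raise ConfigError("poisson mean must be nonnegative")
            elif set(spec) == {"uniform"}:
                lo, hi = spec["uniform"]
                if not (0 <= lo <= hi):
                    raise ConfigError("uniform bounds must satisfy 0 <= lo <= hi")
            else:
                raise ConfigError(
                    "foci_per_nucleus dict must be {'poisson': mean} or "
                    "{'uniform': [lo, hi]}")
        elif not (isinstance(spec, int) and spec >= 0):
            raise ConfigError(
                "foci_per_nucleus must be a nonneg int, {'poisson': mean} "
                "or {'uniform': [lo, hi]}")


@dataclass
class FollicleSceneParams:
    """Parameters of a synthetic follicle section with a central GC."""

    image_height_px: int = 320
    image_width_px: int = 320
    typical_cell_area_px: float = 100.0
    n_cells_gc: int = 200
    n_cells_fo: int = 300
    marker_mean_gc: float = 20000.0
    marker_mean_fo: float = 10000.0
    intensity_cv: float = 0.2
    n_outlier_cells: int = 0
    outlier_multiplier: float = 10.0
    dapi_cell_level: float = 20000.0
    noise_sigma: float = 0.0
    jitter_frac: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ConfigError("scene must be at least 64x64")
        if self.typical_cell_area_px <= 0:
            raise ConfigError("typical_cell_area_px must be positive")
        if self.n_cells_gc < 0 or self.n_cells_fo < 0:
            raise ConfigError("cell counts must be nonnegative")
        if self.n_cells_gc + self.n_cells_fo < 1:
            raise ConfigError("need at least one cell")
        if self.marker_mean_gc < 0 or self.marker_mean_fo < 0:
            raise ConfigError("marker means must be nonnegative")
        if self.intensity_cv < 0 or self.noise_sigma < 0:
            raise ConfigError("intensity_cv and noise_sigma must be nonnegative")
        if self.n_outlier_cells < 0:
            raise ConfigError("n_outlier_cells must be nonnegative")
        if self.n_outlier_cells and self.outlier_multiplier <= 1:
            raise ConfigError("outlier_multiplier must exceed 1")
        if not (0 <= self.jitter_frac < 0.5):
            raise ConfigError("jitter_frac must lie in [0, 0.5)")


@dataclass
class RunConfig:
    """Top-level run configuration with one nested section per stage."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    foci: FociConfig = field(default_factory=FociConfig)
    follicle: FollicleConfig = field(default_factory=FollicleConfig)
    scene: SceneParams = field(default_factory=SceneParams)
    follicle_scene: FollicleSceneParams = field(default_factory=FollicleSceneParams)
    channels: dict[str, int] = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, require_cell_area: bool = False) -> None:
        self.segmentation.validate()
        self.foci.validate()
        self.follicle.validate(require_cell_area=require_cell_area)
        self.scene.validate()
        self.follicle_scene.validate()


_SECTION_TYPES = {
    "segmentation": SegmentationConfig,
    "foci": FociConfig,
    "follicle": FollicleConfig,
    "scene": SceneParams,
    "follicle_scene": FollicleSceneParams,
}
_SCALAR_KEYS = {"channels", "output_dir", "seed", "log_level"}


def _build_section(cls: type, data: dict[str, Any], section: str) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"bad value in [{section}]: {exc}") from exc


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a nested dict."""
    data = dict(data or {})
    unknown = set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    sections: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        raw = data.pop(name, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"section [{name}] must be a mapping")
        sections[name] = _build_section(cls, raw, name)
    cfg = RunConfig(**sections, **{k: data[k] for k in data})
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; omitted fields take the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the effective configuration."""
    canon = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def dump_effective_config(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Echo the defaults-filled configuration next to the outputs."""
    out = Path(out_dir) / "effective_config.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
    return out
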