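"""Shared in-memory containers for the quantification pipelines.

Coordinates are 0-based ``(row, col)`` with the row index increasing
downward; every table written by the package uses this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChannelImage:
    """One fluorescence channel as a 2-D nonnegative intensity grid.

    Parameters
    ----------
    pixels
        2-D array of finite, nonnegative intensities.
    channel_name
        Free-text channel identifier (e.g. ``"DAPI"``, ``"gH2AX"``).
    pixel_size_um
        Physical pixel pitch in micrometres, if known.
    """

    pixels: np.ndarray
    channel_name: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"channel image must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError(
                f"channel image must be at least 64x64, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("channel image contains negative intensities")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """Integer-labelled segmentation grid; 0 is background.

    Positive labels are consecutive from 1 and each is one connected
    component under the stated connectivity (1 = 4-connected,
    2 = 8-connected, matching the scikit-image convention).
    """

    labels: np.ndarray
    connectivity: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class NucleusObject:
    """Geometry record for one candidate nucleus, with audit flags."""

    label: int
    area_px: int
    convex_area_px: int
    solidity: float
    centroid: tuple[float, float]
    passed_solidity: bool = True
    passed_size: bool = True

    @property
    def retained(self) -> bool:
        return self.passed_solidity and self.passed_size


@dataclass
class FocusRecord:
    """One detected fluorescent punctum."""

    focus_id: int
    centroid: tuple[float, float]
    equivalent_diameter_px: float
    mean_intensity: float
    parent_nucleus_label: int = 0
    passed_control_threshold: bool = True


@dataclass
class FociSummary:
    """Per-nucleus focus counts plus the headline mean-per-cell statistic."""

    per_nucleus_counts: dict[int, int]
    n_nuclei: int
    control_threshold: float

    @property
    def total_foci(self) -> int:
        return int(sum(self.per_nucleus_counts.values()))

    @property
    def mean_foci_per_cell(self) -> float:
        if self.n_nuclei == 0:
            return float("nan")
        return self.total_foci / self.n_nuclei


@dataclass
class CellRecord:
    """One segmented tissue cell with its cytoplasm-band measurements."""

    label: int
    area_px: int
    eccentricity: float
    cytoplasm_pixel_count: int
    median_intensity: dict[str, float] = field(default_factory=dict)
    compartment: str = "none"  # GC | FO | none
    normalized_signal: float | None = None
    is_outlier: bool = False


@dataclass
class FollicleSummary:
    """Mean normalized signal per compartment for one follicle image."""

    follicle_id: str
    gc_mean: float | None
    fo_mean: float | None
    n_gc: int
    n_fo: int


@dataclass
class MouseSummary:
    """Across-follicle averages and the GC/Fo ratio for one mouse."""

    mouse_id: str
    gc_mean: float | None
    fo_mean: float | None
    ratio: float | None
    n_follicles: int
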