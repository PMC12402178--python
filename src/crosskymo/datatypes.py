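"""Shared container types for trajectories, kymographs, tracks and fit results.

Conventions used throughout the package:

* time in seconds, positions and lengths in micrometres (µm),
  speeds in µm/min (the unit dynamic-instability rates are reported in),
  first-order rates in s⁻¹;
* kymographs are stored rows = time frames, columns = position (pixels);
* image coordinates are 0-based with pixel centers at integer coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FilamentTrajectory",
    "PhaseSegment",
    "SpeedStats",
    "FrequencyEstimate",
    "FrapTrace",
    "FrapFit",
    "ParticleTrack",
    "EventRecord",
    "OverlapTimecourse",
    "Kymograph",
    "LineRoi",
    "TestResult",
]

GROWTH = "growth"
SHRINK = "shrink"
PAUSE = "pause"

EVENT_LABELS = ("bind_unbind", "sliding", "tip_tracking", "bundling")
LOCATIONS = ("seed", "gdp_lattice", "plus_tip")


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


@dataclass
class FilamentTrajectory:
    """A microtubule tip position versus time.

    ``tip_positions`` are measured from the seed's minus end, so
    ``seed_reference`` (the seed's plus end, i.e. the boundary between the
    stable seed and the dynamic GDP lattice) lies at ``seed_length`` µm.
    """

    times: np.ndarray
    tip_positions: np.ndarray
    seed_reference: float = 0.0

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        self.tip_positions = _as_1d(self.tip_positions, "tip_positions")
        if self.times.size != self.tip_positions.size:
            raise ValueError("times and tip_positions must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.tip_positions)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def tip_at(self, t) -> np.ndarray:
        """Piecewise-linear tip position at arbitrary times (clamped at ends)."""
        return np.interp(t, self.times, self.tip_positions)


@dataclass
class PhaseSegment:
    """A single growth / shrink / pause phase.

    speed is signed and in µm/min: positive for growth, negative for shrink.
    """

    kind: str
    t_start: float
    t_end: float
    speed: float

    def __post_init__(self) -> None:
        if self.kind not in (GROWTH, SHRINK, PAUSE):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def displacement(self) -> float:
        """Displacement in µm (speed is µm/min, duration s)."""
        return self.speed * self.duration / 60.0


@dataclass
class SpeedStats:
    """Duration-weighted mean speed and its weighted standard error.

    ``weighted_se`` is NaN for a single event (the (N−1)/N factor vanishes).
    """

    weighted_mean: float
    weighted_se: float
    n_events: int
    weights: np.ndarray
    deviations: np.ndarray


@dataclass
class FrequencyEstimate:
    """Pooled transition frequency: events / exposure, error = frequency/√n."""

    frequency: float
    error: float
    n_events: int
    exposure_time: float


@dataclass
class FrapTrace:
    """A FRAP region-of-interest intensity time series."""

    times: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    roi_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        self.intensities = _as_1d(self.intensities, "intensities")
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities must have equal length")
        n = self.times.size
        if not (2 <= self.bleach_index <= n - 3):
            raise ValueError("bleach_index must leave >=2 pre- and post-bleach frames")


@dataclass
class FrapFit:
    A: float
    k_off: float
    r_squared: float
    converged: bool
    n_points: int


@dataclass
class ParticleTrack:
    """A binder particle's or actin filament's track along the filament axis."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        self.positions = _as_1d(self.positions, "positions")
        self.intensities = _as_1d(self.intensities, "intensities")
        if not (self.times.size == self.positions.size == self.intensities.size):
            raise ValueError("track fields must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def t_on(self) -> float:
        return float(self.times[0])

    @property
    def t_off(self) -> float:
        return float(self.times[-1])


@dataclass
class EventRecord:
    """A classified actin–microtubule interaction event."""

    event_id: str
    label: str
    t_on: float
    t_off: float
    n_filaments: int = 1
    location: str | None = None

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if self.t_off < self.t_on:
            raise ValueError("t_off must be >= t_on")
        if self.location is not None and self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def residence_time(self) -> float:
        return self.t_off - self.t_on


@dataclass
class OverlapTimecourse:
    times: np.ndarray
    overlap_length: np.ndarray
    actin_intensity_norm: np.ndarray
    anillin_intensity_norm: np.ndarray


@dataclass
class Kymograph:
    """Time × position intensity matrix with physical calibration."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    source_line: np.ndarray | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (rows=time, cols=position)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("kymograph contains non-finite values")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[1]


@dataclass
class LineRoi:
    """A polyline region of interest with a perpendicular averaging width."""

    vertices: np.ndarray
    width: int = 5

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or self.vertices.shape[0] < 2:
            raise ValueError("vertices must be an (n>=2, 2) array of (x, y)")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be odd and >= 1")


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n1: int
    n2: int
    note: str = ""
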