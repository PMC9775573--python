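"""Domain types and shared reductions for thermal-manikin trials.

A trial is a time series of per-zone surface temperatures (degC) and heat
losses (W) recorded on a multi-zone heated manikin standing in a climate
chamber. The reductions here — steady-state selection, window averaging,
the repeatability rule and the area-weighted mean surface temperature —
are shared by the dry (insulation) and wet (evaporative resistance)
pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import ZONE_NAMES

__all__ = [
    "Zone",
    "ManikinGeometry",
    "Environment",
    "TrialRecord",
    "SteadyWindow",
    "WindowMeans",
    "RepeatabilityResult",
    "SteadyStateError",
    "detect_steady_state",
    "average_window",
    "repeatability_check",
    "mean_surface_temperature",
    "default_geometry",
]


class SteadyStateError(RuntimeError):
    """No qualifying steady-state window exists in a trial."""


@dataclass(frozen=True)
class Zone:
    """One individually controlled manikin surface zone."""

    zone_id: str
    name: str
    area: float  # m2

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"zone {self.zone_id!r}: area must be > 0, got {self.area}")


@dataclass(frozen=True)
class ManikinGeometry:
    """Ordered zone collection; total area is the sum of zone areas."""

    zones: tuple[Zone, ...]

    def __post_init__(self) -> None:
        names = [z.name for z in self.zones]
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique within a manikin")
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique within a manikin")

    @property
    def total_area(self) -> float:
        return float(sum(z.area for z in self.zones))

    @property
    def areas(self) -> np.ndarray:
        return np.array([z.area for z in self.zones], dtype=float)

    @property
    def zone_ids(self) -> tuple[str, ...]:
        return tuple(z.zone_id for z in self.zones)

    def index_of(self, zone_id: str) -> int:
        try:
            return self.zone_ids.index(zone_id)
        except ValueError:
            raise KeyError(f"unknown zone id {zone_id!r}") from None


#: Nominal per-zone surface areas (m2) for a 17-zone male manikin, summing
#: to 1.77 m2. These are package defaults for synthetic work and examples,
#: not measured values of any particular instrument: real analyses should
#: supply the geometry of the manikin actually used.
DEFAULT_ZONE_AREAS: dict[str, float] = {
    "head": 0.140,
    "chest": 0.140,
    "back": 0.145,
    "stomach": 0.130,
    "buttocks": 0.135,
    "left_upper_arm": 0.075,
    "right_upper_arm": 0.075,
    "left_lower_arm": 0.060,
    "right_lower_arm": 0.060,
    "left_hand": 0.045,
    "right_hand": 0.045,
    "left_thigh": 0.180,
    "right_thigh": 0.180,
    "left_calf": 0.125,
    "right_calf": 0.125,
    "left_foot": 0.055,
    "right_foot": 0.055,
}


def default_geometry() -> ManikinGeometry:
    """17-zone geometry with the nominal area table (1.77 m2 total)."""
    zones = tuple(Zone(zone_id=n, name=n, area=DEFAULT_ZONE_AREAS[n]) for n in ZONE_NAMES)
    return ManikinGeometry(zones=zones)


@dataclass(frozen=True)
class Environment:
    """Chamber conditions for a trial.

    The operative temperature is the mean of air and radiant temperature;
    when the radiant temperature equals the air temperature (the usual
    chamber condition) it equals both.
    """

    air_temperature: float  # degC
    relative_humidity: float  # %
    air_velocity: float = 0.0  # m/s
    radiant_temperature: float | None = None  # degC; defaults to air temperature

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError(f"relative_humidity must be in [0, 100], got {self.relative_humidity}")
        if self.air_velocity < 0:
            raise ValueError("air_velocity must be >= 0")
        if self.radiant_temperature is None:
            object.__setattr__(self, "radiant_temperature", self.air_temperature)

    @property
    def operative_temperature(self) -> float:
        return 0.5 * (self.air_temperature + self.radiant_temperature)


@dataclass(frozen=True)
class SteadyWindow:
    """Half-open-in-neither-sense time window [start_time, end_time], seconds."""

    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not self.end_time - self.start_time > 0:
            raise ValueError("window must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class TrialRecord:
    """A manikin trial: per-zone temperature/heat-loss time series.

    ``surface_temp`` and ``heat_loss`` are (n_times, n_zones) arrays in the
    geometry's zone order. Negative instantaneous heat-loss readings are
    permitted (they occur near zero flux on heavily insulated zones) and
    are retained; flooring is applied to window *means* downstream, never
    to raw samples.
    """

    trial_id: str
    mode: str  # "dry" | "wet"
    geometry: ManikinGeometry
    environment: Environment
    timestamps: np.ndarray  # (n,), s, strictly increasing
    surface_temp: np.ndarray  # (n, z), degC
    heat_loss: np.ndarray  # (n, z), W
    skin_rh: float | None = None  # %, wet mode only

    def __post_init__(self) -> None:
        if self.mode not in ("dry", "wet"):
            raise ValueError(f"mode must be 'dry' or 'wet', got {self.mode!r}")
        t = np.asarray(self.timestamps, dtype=float)
        st = np.asarray(self.surface_temp, dtype=float)
        hl = np.asarray(self.heat_loss, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "surface_temp", st)
        object.__setattr__(self, "heat_loss", hl)
        nz = len(self.geometry.zones)
        if st.shape != (t.size, nz) or hl.shape != (t.size, nz):
            raise ValueError(
                f"expected ({t.size}, {nz}) sample arrays, got {st.shape} and {hl.shape}"
            )
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing (>= 2 samples)")
        if self.mode == "dry" and self.skin_rh is not None:
            raise ValueError("dry trials must not carry skin_rh")
        if self.skin_rh is not None and not 0.0 <= self.skin_rh <= 100.0:
            raise ValueError("skin_rh must be in [0, 100]")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class WindowMeans:
    """Arithmetic means over a steady window, the input of both reductions."""

    zone_ids: tuple[str, ...]
    surface_temp: np.ndarray  # (z,), degC
    heat_loss: np.ndarray  # (z,), W (unfloored means)
    environment: Environment
    n_samples: int
    window: SteadyWindow


@dataclass(frozen=True)
class RepeatabilityResult:
    relative_difference: float  # fraction
    threshold: float
    passed: bool


def _trend_and_cv(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Linear-trend slope (units/min), coefficient of variation, mean."""
    mean = float(np.mean(y))
    slope_per_s = float(np.polyfit(t_s, y, 1)[0])
    cv = float(np.std(y) / abs(mean)) if mean != 0 else math.inf
    return slope_per_s * 60.0, cv, mean


def detect_steady_state(
    trial: TrialRecord,
    min_duration: float = 600.0,
    slope_tolerance: float = 0.005,
    cv_tolerance: float = 0.02,
) -> SteadyWindow:
    """Find the latest steady window of length ``min_duration``.

    A window qualifies when, for both the whole-body heat loss and the
    area-weighted mean surface temperature, the absolute linear-trend slope
    does not exceed ``slope_tolerance`` x |window mean| per minute and the
    coefficient of variation does not exceed ``cv_tolerance``. Candidate
    windows start at sample times and are scanned from the latest backwards,
    so the returned window is the one with the largest start time.

    Raises
    ------
    SteadyStateError
        If no window qualifies; the message names the criterion violated by
        the latest candidate window.
    """
    if min_duration <= 0 or slope_tolerance <= 0 or cv_tolerance <= 0:
        raise ValueError("min_duration and tolerances must be > 0")
    t = trial.timestamps
    if trial.duration < min_duration:
        raise ValueError(
            f"trial spans {trial.duration:.0f} s < min_duration {min_duration:.0f} s"
        )
    w = trial.geometry.areas / trial.geometry.total_area
    total_loss = trial.heat_loss.sum(axis=1)
    mean_temp = trial.surface_temp @ w

    last_violation = "no candidate window"
    t_end = t[-1]
    starts = np.nonzero(t <= t_end - min_duration)[0]
    for i in starts[::-1]:
        mask = (t >= t[i]) & (t <= t[i] + min_duration)
        if mask.sum() < 3:
            continue
        ok = True
        for label, series in (("heat loss", total_loss), ("surface temperature", mean_temp)):
            slope, cv, mean = _trend_and_cv(t[mask], series[mask])
            if abs(slope) > slope_tolerance * abs(mean):
                last_violation = f"{label} trend slope {slope:.4g}/min exceeds tolerance"
                ok = False
                break
            if cv > cv_tolerance:
                last_violation = f"{label} coefficient of variation {cv:.4g} exceeds tolerance"
                ok = False
                break
        if ok:
            return SteadyWindow(start_time=float(t[i]), end_time=float(t[i] + min_duration))
    raise SteadyStateError(f"no steady state found: {last_violation}")


def average_window(trial: TrialRecord, window: SteadyWindow) -> WindowMeans:
    """Arithmetic per-zone means over samples falling inside the window."""
    t = trial.timestamps
    if window.start_time < t[0] or window.end_time > t[-1]:
        raise ValueError("window lies outside the trial's time span")
    mask = (t >= window.start_time) & (t <= window.end_time)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("window contains no samples")
    return WindowMeans(
        zone_ids=trial.geometry.zone_ids,
        surface_temp=trial.surface_temp[mask].mean(axis=0),
        heat_loss=trial.heat_loss[mask].mean(axis=0),
        environment=trial.environment,
        n_samples=n,
        window=window,
    )


def repeatability_check(
    value_a: float, value_b: float, threshold_fraction: float = 0.04
) -> RepeatabilityResult:
    """Duplicate-measurement agreement rule.

    The relative difference is |a - b| / mean(a, b); the pair passes when it
    does not exceed ``threshold_fraction`` (default 4%, pass at equality).
    """
    if value_a <= 0 or value_b <= 0:
        raise ValueError("repeatability_check requires strictly positive values")
    rel = abs(value_a - value_b) / (0.5 * (value_a + value_b))
    return RepeatabilityResult(
        relative_difference=rel, threshold=threshold_fraction, passed=rel <= threshold_fraction
    )


def mean_surface_temperature(
    zone_temps: Sequence[float] | np.ndarray, geometry: ManikinGeometry
) -> float:
    """Area-weighted mean surface temperature, sum(T_i A_i) / A."""
    temps = np.asarray(zone_temps, dtype=float)
    if temps.shape != (len(geometry.zones),):
        raise ValueError(
            f"expected one temperature per zone ({len(geometry.zones)}), got shape {temps.shape}"
        )
    return float(temps @ geometry.areas / geometry.total_area)
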