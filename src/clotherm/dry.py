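"""Dry-mode reduction: steady-state zone means to thermal insulation.

The total insulation of zone i is

    I_T,i = (T_s,i - T_o) * A_i / H_c,i          [m2K/W]

with T_s,i the mean zone surface temperature (degC), T_o the operative
temperature, A_i the zone area (m2) and H_c,i the dry heat loss (W). Three
aggregation methods produce the whole-body value:

* global   — area-weight the temperatures, sum the heat losses:
             I_T = (sum(T_s,i A_i)/A - T_o) * A / sum(H_c,i).
             Insensitive to near-zero zone fluxes; the package default.
* serial   — area-weighted sum of zone insulations, sum((A_i/A) I_T,i).
* parallel — area-weighted conductance summation, A / sum(A_i / I_T,i)
             (literature convention; the reciprocal-weighted form).

Serial >= parallel for heterogeneous zones (AM-HM inequality), and with a
uniform surface temperature the global and parallel forms coincide.

Basic (intrinsic) insulation removes the boundary air layer scaled by the
clothing area factor: I_cl = I_T - I_a / f_cl.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CLO_SI, HEAT_LOSS_FLOOR_W, I_A_NUDE
from .core import (
    ManikinGeometry,
    TrialRecord,
    WindowMeans,
    average_window,
    detect_steady_state,
    mean_surface_temperature,
)

__all__ = [
    "InsulationResult",
    "ZoneGroup",
    "zone_total_insulation",
    "zone_contribution",
    "group_total_insulation",
    "whole_body_total_insulation",
    "basic_insulation",
    "to_clo",
    "from_clo",
    "compute_insulation",
]

METHODS = ("global", "serial", "parallel")


@dataclass(frozen=True)
class ZoneGroup:
    """A named, non-empty set of zones (groups need not partition the body)."""

    group_id: str
    member_zones: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_zones:
            raise ValueError(f"group {self.group_id!r} must be non-empty")


@dataclass(frozen=True)
class InsulationResult:
    """Whole-body dry-insulation reduction output (all resistances m2K/W)."""

    total_insulation: float
    air_layer_insulation: float
    clothing_area_factor: float
    basic_insulation: float
    method: str
    zone_values: dict[str, float]  # I_T,i per zone
    zone_contributions: dict[str, float]  # (A_i/A) I_T,i per zone
    warnings: tuple[str, ...] = ()

    @property
    def total_insulation_clo(self) -> float:
        return to_clo(self.total_insulation)

    @property
    def basic_insulation_clo(self) -> float:
        return to_clo(self.basic_insulation)


def _floored(heat_loss: np.ndarray | float, floor: float) -> np.ndarray | float:
    return np.maximum(heat_loss, floor)


def zone_total_insulation(
    mean_temp: float,
    operative_temp: float,
    area: float,
    mean_heat_loss: float,
    floor: float = HEAT_LOSS_FLOOR_W,
    zone_id: str = "?",
) -> float:
    """I_T,i = (T_s,i - T_o) A_i / H_c,i for one zone."""
    gradient = mean_temp - operative_temp
    if gradient <= 0:
        raise ValueError(
            f"zone {zone_id!r}: non-positive temperature gradient "
            f"({mean_temp} degC surface vs {operative_temp} degC operative)"
        )
    return gradient * area / float(_floored(mean_heat_loss, floor))


def zone_contribution(zone_insulation: float, area: float, total_area: float) -> float:
    """Serial-method contribution (A_i/A) I_T,i of one zone."""
    if area <= 0 or total_area <= 0:
        raise ValueError("areas must be positive")
    return area / total_area * zone_insulation


def group_total_insulation(
    means: WindowMeans,
    group: ZoneGroup,
    operative_temp: float,
    geometry: ManikinGeometry,
    floor: float = HEAT_LOSS_FLOOR_W,
) -> float:
    """Global-method insulation of a zone group.

    (area-weighted group temperature - T_o) * group area / summed group loss.
    """
    idx = [geometry.index_of(z) for z in sorted(group.member_zones)]
    areas = geometry.areas[idx]
    temps = np.asarray(means.surface_temp)[idx]
    losses = np.asarray(means.heat_loss)[idx]
    group_area = areas.sum()
    group_loss = float(_floored(losses.sum(), floor))
    mean_temp = float(temps @ areas / group_area)
    gradient = mean_temp - operative_temp
    if gradient <= 0:
        raise ValueError(f"group {group.group_id!r}: non-positive temperature gradient")
    return gradient * group_area / group_loss


def whole_body_total_insulation(
    means: WindowMeans,
    operative_temp: float,
    geometry: ManikinGeometry,
    method: str = "global",
    floor: float = HEAT_LOSS_FLOOR_W,
) -> float:
    """Whole-body total insulation by the global, serial or parallel method."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    areas = geometry.areas
    total_area = geometry.total_area
    temps = np.asarray(means.surface_temp, dtype=float)
    losses = _floored(np.asarray(means.heat_loss, dtype=float), floor)

    if method == "global":
        mean_temp = mean_surface_temperature(temps, geometry)
        gradient = mean_temp - operative_temp
        if gradient <= 0:
            raise ValueError("non-positive whole-body temperature gradient")
        return gradient * total_area / float(losses.sum())

    zone_it = np.array(
        [
            zone_total_insulation(t, operative_temp, a, h, floor=floor, zone_id=zid)
            for t, a, h, zid in zip(temps, areas, losses, geometry.zone_ids)
        ]
    )
    if method == "serial":
        return float((areas / total_area * zone_it).sum())
    return float(total_area / (areas / zone_it).sum())  # parallel


def basic_insulation(
    total: float, air_layer: float = I_A_NUDE, fcl: float = 1.0
) -> float:
    """Intrinsic clothing insulation I_cl = I_T - I_a / f_cl.

    A negative result (thin items, f_cl near 1, printed-value rounding) is
    returned as-is with a warning rather than clamped.
    """
    if fcl < 1.0:
        raise ValueError(f"clothing area factor must be >= 1, got {fcl}")
    if total <= 0 or air_layer <= 0:
        raise ValueError("insulations must be > 0")
    icl = total - air_layer / fcl
    if icl < 0:
        warnings.warn(
            f"negative basic insulation {icl:.4g} m2K/W (I_T={total}, I_a={air_layer}, f_cl={fcl})",
            stacklevel=2,
        )
    return icl


def to_clo(insulation_si: float) -> float:
    """m2K/W -> clo (1 clo = 0.155 m2K/W)."""
    return insulation_si / CLO_SI


def from_clo(insulation_clo: float) -> float:
    """clo -> m2K/W."""
    return insulation_clo * CLO_SI


def compute_insulation(
    trial: TrialRecord,
    fcl: float = 1.0,
    air_layer: float = I_A_NUDE,
    method: str = "global",
    min_duration: float = 600.0,
    slope_tolerance: float = 0.005,
    cv_tolerance: float = 0.02,
    floor: float = HEAT_LOSS_FLOOR_W,
) -> InsulationResult:
    """Full dry pipeline: steady-state selection, averaging, reduction."""
    if trial.mode != "dry":
        raise ValueError("compute_insulation requires a dry trial")
    window = detect_steady_state(trial, min_duration, slope_tolerance, cv_tolerance)
    means = average_window(trial, window)
    t_o = trial.environment.operative_temperature
    geometry = trial.geometry
    total = whole_body_total_insulation(means, t_o, geometry, method=method, floor=floor)
    losses = _floored(np.asarray(means.heat_loss, dtype=float), floor)
    zone_vals = {
        zid: zone_total_insulation(t, t_o, a, h, floor=floor, zone_id=zid)
        for zid, t, a, h in zip(
            geometry.zone_ids, means.surface_temp, geometry.areas, losses
        )
    }
    zone_contribs = {
        zid: zone_contribution(v, geometry.areas[geometry.index_of(zid)], geometry.total_area)
        for zid, v in zone_vals.items()
    }
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        icl = basic_insulation(total, air_layer, fcl)
        notes.extend(str(w.message) for w in caught)
    return InsulationResult(
        total_insulation=total,
        air_layer_insulation=air_layer,
        clothing_area_factor=fcl,
        basic_insulation=icl,
        method=method,
        zone_values=zone_vals,
        zone_contributions=zone_contribs,
        warnings=tuple(notes),
    )
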