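"""Wet-mode reduction: evaporative resistance on a sweating manikin.

Measured under isothermal conditions (air temperature equal to the 34 degC
surface set-point) with a wetted textile skin, so that evaporation is the
only heat-exchange pathway and the measured heat loss equals the
evaporative heat loss. The total evaporative resistance is

    R_et = (p_sk - p_a) * A / sum(H_e,i)        [m2Pa/W]

where vapour pressures follow the psychrometric closed form

    p = exp(18.956 - 4030 / (T + 235)) * RH     [Pa, RH in percent]

(the exponential alone is in hPa; multiplying by RH in percent yields Pa —
at 34 degC the exponential is ~53.2, so saturation is ~5322 Pa).

The raw value R_et,raw uses the surface set-point temperature; the
corrected value uses the wetted-skin temperature, which is depressed below
the surface sensor reading by evaporative cooling:

    T_sk,i = T_s,i - 0.0132 * Q_i               [Q_i zone heat flux, W/m2]

Clothing-only resistance and the permeability indices follow:

    R_ecl = R_et - R_ea / f_cl
    i_m = I_T / (R_et * L),   i_m,cl = I_cl / (R_ecl * L)

with L = 16.5e-3 K/Pa the Lewis relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (
    HEAT_LOSS_FLOOR_W,
    LEWIS_RELATION,
    R_EA_TEXTILE_SKIN,
    SKIN_RH_DEFAULT,
)
from .core import (
    Environment,
    ManikinGeometry,
    TrialRecord,
    WindowMeans,
    average_window,
    detect_steady_state,
    mean_surface_temperature,
)

__all__ = [
    "WetSkinState",
    "EvapResult",
    "vapour_pressure",
    "corrected_skin_temperature",
    "zone_evaporative_resistance",
    "whole_body_evap_resistance",
    "clothing_evap_resistance",
    "permeability_index",
    "clothing_permeability_index",
    "compute_evap",
]

#: Skin-temperature depression per unit evaporative heat flux, K/(W/m2).
SKIN_TEMP_FLUX_COEFF = 0.0132


@dataclass(frozen=True)
class WetSkinState:
    """Corrected textile-skin temperatures for a wet trial."""

    zone_skin_temps: np.ndarray  # (z,), degC
    mean_skin_temp: float  # degC, area-weighted
    skin_rh: float = SKIN_RH_DEFAULT  # %


@dataclass(frozen=True)
class EvapResult:
    """Whole-body evaporative-resistance reduction output."""

    ret_raw: float  # m2Pa/W, set-point surface temperature
    ret: float  # m2Pa/W, corrected skin temperature
    recl: float  # m2Pa/W, clothing-only
    rea: float  # m2Pa/W, air-layer (textile-skin) value used
    im: float | None  # moisture permeability index (needs I_T)
    im_cl: float | None  # clothing permeability index (needs I_cl)
    zone_ret: dict[str, float]  # R_et,i per zone, corrected skin temperature
    heat_flux: float  # W/m2, whole-body
    zone_heat_flux: dict[str, float]  # W/m2
    evap_zone_losses: dict[str, float]  # W
    skin_state: WetSkinState
    warnings: tuple[str, ...] = ()


def vapour_pressure(temperature: float, relative_humidity: float) -> float:
    """Water vapour pressure (Pa) at ``temperature`` degC, RH in percent."""
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError(f"relative humidity must be in [0, 100], got {relative_humidity}")
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= -235):
        raise ValueError("temperature must exceed -235 degC")
    out = np.exp(18.956 - 4030.0 / (t + 235.0)) * rh
    return float(out) if out.ndim == 0 else out


def corrected_skin_temperature(surface_temp, heat_flux):
    """Wetted-skin temperature T_sk = T_s - 0.0132 Q (Q in W/m2)."""
    return surface_temp - SKIN_TEMP_FLUX_COEFF * np.asarray(heat_flux, dtype=float)


def zone_evaporative_resistance(
    skin_vp: float, air_vp: float, area: float, heat_loss: float,
    floor: float = HEAT_LOSS_FLOOR_W, zone_id: str = "?",
) -> float:
    """R_et,i = (p_sk,i - p_a) A_i / H_i for one zone."""
    gradient = skin_vp - air_vp
    if gradient <= 0:
        raise ValueError(
            f"zone {zone_id!r}: non-positive vapour-pressure gradient "
            f"({skin_vp:.1f} Pa skin vs {air_vp:.1f} Pa air)"
        )
    return gradient * area / max(heat_loss, floor)


def whole_body_evap_resistance(
    means: WindowMeans,
    environment: Environment,
    geometry: ManikinGeometry,
    skin_rh: float = SKIN_RH_DEFAULT,
    rea: float = R_EA_TEXTILE_SKIN,
    fcl: float = 1.0,
    total_insulation: float | None = None,
    basic_insulation: float | None = None,
    isothermal_tolerance: float = 0.5,
    floor: float = HEAT_LOSS_FLOOR_W,
) -> EvapResult:
    """Whole-body evaporative resistance from steady wet-trial means.

    ``ret_raw`` uses the uncorrected surface temperature; ``ret`` applies
    the flux-proportional skin-temperature correction. Both divide the
    whole-body vapour-pressure gradient by the area-normalised summed
    evaporative heat loss. Deviations from isothermality beyond
    ``isothermal_tolerance`` (degC) are flagged; beyond 3 degC the
    isothermal assumption is untenable and the reduction fails.
    """
    notes: list[str] = []
    areas = geometry.areas
    total_area = geometry.total_area
    temps = np.asarray(means.surface_temp, dtype=float)
    losses = np.maximum(np.asarray(means.heat_loss, dtype=float), 0.0)
    total_loss = losses.sum()
    if total_loss <= floor:
        raise ValueError("zero evaporative heat loss: resistance undefined")

    mean_ts = mean_surface_temperature(temps, geometry)
    dev = abs(mean_ts - environment.air_temperature)
    if dev > 3.0:
        raise ValueError(
            f"isothermal assumption violated: |T_s - T_a| = {dev:.2f} degC > 3 degC"
        )
    if dev > isothermal_tolerance:
        notes.append(
            f"isothermal deviation |T_s - T_a| = {dev:.2f} degC exceeds "
            f"tolerance {isothermal_tolerance} degC"
        )

    p_a = vapour_pressure(environment.air_temperature, environment.relative_humidity)
    zone_flux = losses / areas
    q = float(total_loss / total_area)

    # raw: vapour pressure at the (set-point) surface temperature
    p_s = vapour_pressure(mean_ts, skin_rh)
    ret_raw = (p_s - p_a) * total_area / total_loss

    # corrected: flux-depressed skin temperature
    t_sk_i = corrected_skin_temperature(temps, zone_flux)
    t_sk = float(t_sk_i @ areas / total_area)
    p_sk = vapour_pressure(t_sk, skin_rh)
    ret = (p_sk - p_a) * total_area / total_loss
    if ret <= 0 or ret_raw <= 0:
        raise ValueError("non-positive whole-body vapour-pressure gradient")

    zone_ret = {}
    for zid, t, a, h in zip(geometry.zone_ids, t_sk_i, areas, losses):
        p_z = vapour_pressure(float(t), skin_rh)
        zone_ret[zid] = zone_evaporative_resistance(p_z, p_a, a, h, floor=floor, zone_id=zid)

    recl = np.nan
    im = im_cl = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        recl = clothing_evap_resistance(ret, rea, fcl)
        notes.extend(str(w.message) for w in caught)
    if total_insulation is not None:
        im = permeability_index(total_insulation, ret)
    if basic_insulation is not None and recl > 0:
        im_cl = clothing_permeability_index(basic_insulation, recl)

    return EvapResult(
        ret_raw=float(ret_raw),
        ret=float(ret),
        recl=float(recl),
        rea=rea,
        im=im,
        im_cl=im_cl,
        zone_ret=zone_ret,
        heat_flux=q,
        zone_heat_flux=dict(zip(geometry.zone_ids, zone_flux)),
        evap_zone_losses=dict(zip(geometry.zone_ids, losses)),
        skin_state=WetSkinState(zone_skin_temps=t_sk_i, mean_skin_temp=t_sk, skin_rh=skin_rh),
        warnings=tuple(notes),
    )


def clothing_evap_resistance(
    ret: float, rea: float = R_EA_TEXTILE_SKIN, fcl: float = 1.0
) -> float:
    """Clothing-only evaporative resistance R_ecl = R_et - R_ea / f_cl."""
    if fcl < 1.0:
        raise ValueError(f"clothing area factor must be >= 1, got {fcl}")
    recl = ret - rea / fcl
    if recl < 0:
        warnings.warn(
            f"negative clothing evaporative resistance {recl:.4g} m2Pa/W", stacklevel=2
        )
    return recl


def permeability_index(it: float, ret: float, lewis: float = LEWIS_RELATION) -> float:
    """Moisture permeability index i_m = I_T / (R_et L)."""
    if ret <= 0 or it <= 0:
        raise ValueError("resistances must be > 0")
    return it / (ret * lewis)


def clothing_permeability_index(icl: float, recl: float, lewis: float = LEWIS_RELATION) -> float:
    """Clothing permeability index i_m,cl = I_cl / (R_ecl L)."""
    if recl <= 0 or icl <= 0:
        raise ValueError("resistances must be > 0")
    return icl / (recl * lewis)


def compute_evap(
    trial: TrialRecord,
    fcl: float = 1.0,
    rea: float = R_EA_TEXTILE_SKIN,
    total_insulation: float | None = None,
    basic_insulation: float | None = None,
    min_duration: float = 600.0,
    slope_tolerance: float = 0.005,
    cv_tolerance: float = 0.02,
    isothermal_tolerance: float = 0.5,
) -> EvapResult:
    """Full wet pipeline: steady-state selection, averaging, reduction."""
    if trial.mode != "wet":
        raise ValueError("compute_evap requires a wet trial")
    window = detect_steady_state(trial, min_duration, slope_tolerance, cv_tolerance)
    means = average_window(trial, window)
    return whole_body_evap_resistance(
        means,
        trial.environment,
        trial.geometry,
        skin_rh=trial.skin_rh if trial.skin_rh is not None else SKIN_RH_DEFAULT,
        rea=rea,
        fcl=fcl,
        total_insulation=total_insulation,
        basic_insulation=basic_insulation,
        isothermal_tolerance=isothermal_tolerance,
    )
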