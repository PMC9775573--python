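"""Trial-file dialect: long-format CSV plus a YAML/JSON sidecar, or a single
JSON container.

CSV columns (fixed names): ``time_s, zone, surface_temp_C, heat_loss_W``.

The sidecar (YAML or JSON by extension) holds everything that is not a
per-sample quantity::

    trial_id: dry-001
    mode: dry              # dry | wet
    skin_rh: null          # % (wet mode only)
    environment:
      air_temperature_C: 20.0
      radiant_temperature_C: 20.0   # optional, defaults to air temperature
      relative_humidity_pct: 40.0
      air_velocity_m_s: 0.18
    geometry:
      zones:
        - {zone_id: head, name: head, area_m2: 0.140}
        - ...

The JSON container form holds the same sidecar mapping with an extra
``samples`` list of ``{time_s, zone, surface_temp_C, heat_loss_W}`` records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import Environment, ManikinGeometry, TrialRecord, Zone

__all__ = ["read_trial", "write_trial", "read_trial_json", "write_trial_json"]

CSV_COLUMNS = ("time_s", "zone", "surface_temp_C", "heat_loss_W")


def _geometry_from_dict(d: dict[str, Any]) -> ManikinGeometry:
    zones = tuple(
        Zone(zone_id=str(z["zone_id"]), name=str(z.get("name", z["zone_id"])), area=float(z["area_m2"]))
        for z in d["zones"]
    )
    return ManikinGeometry(zones=zones)


def _geometry_to_dict(g: ManikinGeometry) -> dict[str, Any]:
    return {"zones": [{"zone_id": z.zone_id, "name": z.name, "area_m2": z.area} for z in g.zones]}


def _environment_from_dict(d: dict[str, Any]) -> Environment:
    return Environment(
        air_temperature=float(d["air_temperature_C"]),
        relative_humidity=float(d["relative_humidity_pct"]),
        air_velocity=float(d.get("air_velocity_m_s", 0.0)),
        radiant_temperature=(
            float(d["radiant_temperature_C"]) if d.get("radiant_temperature_C") is not None else None
        ),
    )


def _environment_to_dict(e: Environment) -> dict[str, Any]:
    return {
        "air_temperature_C": e.air_temperature,
        "radiant_temperature_C": e.radiant_temperature,
        "relative_humidity_pct": e.relative_humidity,
        "air_velocity_m_s": e.air_velocity,
    }


def _load_sidecar(path: Path) -> dict[str, Any]:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _trial_from_frames(meta: dict[str, Any], df: pd.DataFrame) -> TrialRecord:
    geometry = _geometry_from_dict(meta["geometry"])
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    wide_t = df.pivot(index="time_s", columns="zone", values="surface_temp_C")
    wide_h = df.pivot(index="time_s", columns="zone", values="heat_loss_W")
    order = list(geometry.zone_ids)
    unknown = set(wide_t.columns) - set(order)
    if unknown:
        raise ValueError(f"trial table contains zones absent from geometry: {sorted(unknown)}")
    absent = set(order) - set(wide_t.columns)
    if absent:
        raise ValueError(f"trial table missing zones: {sorted(absent)}")
    if wide_t.isna().any().any() or wide_h.isna().any().any():
        raise ValueError("every timestamp must carry exactly one sample per zone")
    return TrialRecord(
        trial_id=str(meta["trial_id"]),
        mode=str(meta["mode"]),
        geometry=geometry,
        environment=_environment_from_dict(meta["environment"]),
        timestamps=wide_t.index.to_numpy(dtype=float),
        surface_temp=wide_t[order].to_numpy(dtype=float),
        heat_loss=wide_h[order].to_numpy(dtype=float),
        skin_rh=(float(meta["skin_rh"]) if meta.get("skin_rh") is not None else None),
    )


def read_trial(csv_path: str | Path, sidecar_path: str | Path | None = None) -> TrialRecord:
    """Read a trial from CSV + sidecar (default sidecar: same stem, .yaml)."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        for ext in (".yaml", ".yml", ".json"):
            cand = csv_path.with_suffix(ext)
            if cand.exists():
                sidecar_path = cand
                break
        else:
            raise FileNotFoundError(f"no sidecar found next to {csv_path}")
    meta = _load_sidecar(Path(sidecar_path))
    df = pd.read_csv(csv_path)
    return _trial_from_frames(meta, df)


def _trial_meta(trial: TrialRecord) -> dict[str, Any]:
    return {
        "trial_id": trial.trial_id,
        "mode": trial.mode,
        "skin_rh": trial.skin_rh,
        "environment": _environment_to_dict(trial.environment),
        "geometry": _geometry_to_dict(trial.geometry),
    }


def _trial_long_frame(trial: TrialRecord) -> pd.DataFrame:
    n_t, n_z = trial.surface_temp.shape
    return pd.DataFrame(
        {
            "time_s": np.repeat(trial.timestamps, n_z),
            "zone": list(trial.geometry.zone_ids) * n_t,
            "surface_temp_C": trial.surface_temp.ravel(),
            "heat_loss_W": trial.heat_loss.ravel(),
        }
    )


def write_trial(
    trial: TrialRecord, csv_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write a trial as CSV + YAML sidecar; returns the two paths."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
    _trial_long_frame(trial).to_csv(csv_path, index=False)
    sidecar_path.write_text(yaml.safe_dump(_trial_meta(trial), sort_keys=False))
    return csv_path, sidecar_path


def read_trial_json(path: str | Path) -> TrialRecord:
    """Read a trial from the single-file JSON container form."""
    doc = json.loads(Path(path).read_text())
    df = pd.DataFrame(doc["samples"])
    return _trial_from_frames(doc, df)


def write_trial_json(trial: TrialRecord, path: str | Path) -> Path:
    doc = _trial_meta(trial)
    doc["samples"] = _trial_long_frame(trial).to_dict(orient="records")
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path
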