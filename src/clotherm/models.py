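"""Ensemble-level models: item-insulation summation and clothing-area-factor
estimation, plus the regression machinery to refit them from wardrobe data.

Whole-ensemble basic insulation is predicted from the plain sum of the
member items' basic insulation, sum(I_clu), through a linear map

    I_cl = slope * sum(I_clu) + intercept        [clo]

The conventional workwear line uses slope 0.835; on this wardrobe the
incident (turnout) ensembles keep that slope with a re-adjusted intercept
while the operational-uniform (station wear) ensembles need a fully
refitted line. The clothing area factor is likewise a linear function of
I_cl, with a firefighter-specific line (predictor in clo) and a modern
Western-wardrobe line (predictor in m2K/W).

Built-in coefficients live in ``data/model_coefficients.yaml`` and are
data, not code: refit with :func:`fit_linear` /
:func:`fit_intercept_fixed_slope` and pass the resulting
:class:`LinearModel` anywhere a model name is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .constants import CLO_SI
from .dry import from_clo, to_clo

__all__ = [
    "LinearModel",
    "load_model_coefficients",
    "get_model",
    "sum_item_insulation",
    "predict_icl",
    "estimate_fcl",
    "fit_linear",
    "fit_intercept_fixed_slope",
]


@dataclass(frozen=True)
class LinearModel:
    """y = slope * x + intercept with fit provenance."""

    slope: float
    intercept: float
    input_unit: str  # "clo" | "si"
    r_squared: float | None = None
    n_points: int | None = None
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if self.input_unit not in ("clo", "si"):
            raise ValueError(f"input_unit must be 'clo' or 'si', got {self.input_unit!r}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * x + self.intercept


def load_model_coefficients(path: str | Path | None = None) -> dict[str, dict[str, LinearModel]]:
    """Load the packaged (or a user-supplied) model-coefficient file."""
    if path is None:
        text = (resources.files("clotherm") / "data" / "model_coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out: dict[str, dict[str, LinearModel]] = {}
    for family in ("icl_summation", "fcl_estimation"):
        out[family] = {}
        for name, d in doc[family].items():
            out[family][name] = LinearModel(
                slope=float(d["slope"]),
                intercept=float(d["intercept"]),
                input_unit=str(d["input_unit"]),
                fitted_on=str(d.get("fitted_on", "")),
            )
    return out


_BUILTIN = None


def get_model(family: str, name: str) -> LinearModel:
    """Look up a built-in model, e.g. get_model('fcl_estimation', 'firefighter')."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_model_coefficients()
    try:
        return _BUILTIN[family][name]
    except KeyError:
        known = {f: sorted(m) for f, m in _BUILTIN.items()}
        raise KeyError(f"unknown model {family}/{name}; available: {known}") from None


def sum_item_insulation(
    composition: Iterable[str], items: pd.DataFrame
) -> tuple[float, float]:
    """Plain sum of member items' basic insulation.

    Returns (sum in m2K/W, sum in clo). ``items`` is the wardrobe item
    table indexed or keyed by ``item_id`` with an ``iclu`` column.
    """
    table = items.set_index("item_id") if "item_id" in items.columns else items
    ids = [str(i) for i in composition]
    missing = [i for i in ids if i not in table.index]
    if missing:
        raise KeyError(f"unknown item id(s) in composition: {missing}")
    total_si = float(table.loc[ids, "iclu"].sum()) if ids else 0.0
    return total_si, to_clo(total_si)


def _resolve(model: str | LinearModel, family: str, aliases: dict[str, str]) -> LinearModel:
    if isinstance(model, LinearModel):
        return model
    return get_model(family, aliases.get(model, model))


def predict_icl(sum_iclu_clo: float, model: str | LinearModel = "standard") -> float:
    """Predict ensemble basic insulation (clo) from the item sum (clo).

    ``model`` is 'standard', 'incident', 'operational_uniform' (alias 'ou')
    or any LinearModel with input_unit 'clo'.
    """
    if sum_iclu_clo < 0:
        raise ValueError("item insulation sum must be >= 0")
    m = _resolve(model, "icl_summation", {"ou": "operational_uniform"})
    if m.input_unit != "clo":
        raise ValueError("summation models take the item sum in clo")
    return float(m.predict(sum_iclu_clo))


def estimate_fcl(icl: float, model: str | LinearModel = "firefighter", unit: str = "clo") -> float:
    """Estimate the clothing area factor from basic insulation.

    The unit of ``icl`` ('clo' or 'si') must match the model's input unit;
    a mismatch is an error rather than a silent conversion.
    """
    if icl < 0:
        raise ValueError("basic insulation must be >= 0")
    if unit not in ("clo", "si"):
        raise ValueError("unit must be 'clo' or 'si'")
    m = _resolve(model, "fcl_estimation", {})
    if unit != m.input_unit:
        raise ValueError(
            f"model expects I_cl in {m.input_unit!r} but got {unit!r}; "
            f"convert with to_clo/from_clo first"
        )
    fcl = float(m.predict(icl))
    if fcl < 1.0:
        raise ValueError(f"estimated f_cl {fcl:.3f} < 1; input outside model range")
    return fcl


def fit_linear(
    x: Sequence[float], y: Sequence[float], input_unit: str = "clo", fitted_on: str = ""
) -> LinearModel:
    """Ordinary least squares y = a x + b with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        input_unit=input_unit,
        r_squared=float(res.rsquared),
        n_points=int(x.size),
        fitted_on=fitted_on,
    )


def fit_intercept_fixed_slope(
    x: Sequence[float],
    y: Sequence[float],
    slope: float,
    input_unit: str = "clo",
    fitted_on: str = "",
) -> LinearModel:
    """Least-squares intercept with the slope held fixed.

    intercept = mean(y) - slope * mean(x); R^2 is reported against the
    constrained fit and can be lower than the free fit's (never higher).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired observations")
    intercept = float(np.mean(y) - slope * np.mean(x))
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return LinearModel(
        slope=slope,
        intercept=intercept,
        input_unit=input_unit,
        r_squared=max(r2, 0.0),
        n_points=int(x.size),
        fitted_on=fitted_on,
    )
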