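"""Prediction tables and coefficient exports for fitted models.

All model arithmetic happens on the sqrt-yield scale; predictions are
back-transformed (squared) to t ha-1, so reported yields are nonnegative by
construction.  Curves evaluate the fitted model over an N grid at a single
covariate profile (default: each weather variable at its observed mean);
surfaces sweep one weather variable over a grid crossed with the N grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lexp_core
from .selection import WeatherLEXPModel

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionProfile",
    "predict_curve",
    "response_surface",
    "export_coefficients",
    "coefficients_from_frame",
]

COEFFICIENT_HEADER = ["parameter", "variable", "coefficient", "se"]


@dataclass
class PredictionProfile:
    """Covariate profile at which to evaluate a fitted model.

    Every weather variable in the model must have exactly one value
    (default choice: its observed mean); factor levels name the cultivar
    and, when present, the mineral treatment.
    """

    cultivar: str | None = None
    treatment: str | None = None
    weather: dict[str, float] = field(default_factory=dict)
    n_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 288.0, 49))

    def as_mapping(self) -> dict:
        profile = dict(self.weather)
        if self.cultivar is not None:
            profile["cultivar"] = self.cultivar
        if self.treatment is not None:
            profile["treatment"] = self.treatment
        return profile


def _check_profile(model: WeatherLEXPModel, profile: PredictionProfile) -> dict:
    mapping = profile.as_mapping()
    extrapolated = []
    for var, (lo, hi) in model.design.weather_ranges.items():
        if var not in mapping:
            raise ValueError(f"profile is missing weather variable {var!r}")
        v = float(mapping[var])
        if v < lo or v > hi:
            extrapolated.append(var)
            logger.warning(
                "profile value %.3g for %s outside observed range [%.3g, %.3g]: "
                "extrapolating", v, var, lo, hi)
    mapping["_extrapolated"] = extrapolated
    return mapping


def predict_curve(model: WeatherLEXPModel, profile: PredictionProfile
                  ) -> pd.DataFrame:
    """Back-transformed N-response curve at one covariate profile.

    Returns a table with columns ``n_rate``, ``sqrt_yield``,
    ``yield_t_ha`` and ``extrapolated`` (flag for out-of-range covariates).
    """
    mapping = _check_profile(model, profile)
    extrapolated = bool(mapping.pop("_extrapolated"))
    a, b, c = model.parameter_values(mapping)
    params = lexp_core.LEXPParams(a=a, b=b, c=c, r=model.r)
    grid = np.asarray(profile.n_grid, dtype=float)
    sqrt_pred = lexp_core.lexp_eval(params, grid)
    return pd.DataFrame(
        {
            "n_rate": grid,
            "sqrt_yield": sqrt_pred,
            "yield_t_ha": lexp_core.back_transform(sqrt_pred),
            "extrapolated": extrapolated,
        }
    )


def response_surface(model: WeatherLEXPModel, variable: str, grid,
                     profile: PredictionProfile) -> pd.DataFrame:
    """Back-transformed yield over a weather-variable x N grid.

    The swept variable overrides its profile value; all other covariates
    stay fixed.  With a negative "(2)" coefficient the surface shows an
    interior optimum in the swept variable.
    """
    if variable not in model.design.weather_ranges:
        raise ValueError(f"{variable!r} is not a weather variable of this model")
    frames = []
    for value in np.asarray(grid, dtype=float):
        p = PredictionProfile(
            cultivar=profile.cultivar,
            treatment=profile.treatment,
            weather={**profile.weather, variable: float(value)},
            n_grid=profile.n_grid,
        )
        curve = predict_curve(model, p)
        curve.insert(0, variable, value)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def export_coefficients(model: WeatherLEXPModel) -> pd.DataFrame:
    """Flat coefficient table in first-level-zero presentation.

    Columns are exactly ``parameter, variable, coefficient, se``; baseline
    rows are labelled ``Intercept`` and quadratic rows carry the
    "(1)"/"(2)" suffix of their basis column.
    """
    rows = []
    for label, beta, se in zip(model.fit.labels, model.fit.beta, model.fit.se):
        param, variable = label.split(":", 1)
        rows.append({"parameter": param, "variable": variable,
                     "coefficient": float(beta), "se": float(se)})
    return pd.DataFrame(rows, columns=COEFFICIENT_HEADER)


def coefficients_from_frame(model: WeatherLEXPModel, frame: pd.DataFrame
                            ) -> np.ndarray:
    """Rebuild the coefficient vector of ``model`` from an exported table
    (serialization round trip for predictions)."""
    lookup = {
        (row["parameter"], row["variable"]): float(row["coefficient"])
        for _, row in frame.iterrows()
    }
    beta = np.empty(len(model.fit.labels))
    for j, label in enumerate(model.fit.labels):
        param, variable = label.split(":", 1)
        if (param, variable) not in lookup:
            raise ValueError(f"exported table is missing term {label!r}")
        beta[j] = lookup[(param, variable)]
    return beta
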