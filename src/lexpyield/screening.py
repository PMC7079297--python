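"""Weather-variable screening before model building.

Candidate explanatory variables are monthly weather summaries over the
cropping season (total rainfall "TR <Month>" and mean temperature
"MT <Month>").  Screening proceeds in two steps:

1. Pearson correlations of annual grain yield with every candidate are
   computed separately for each N rate (and mineral treatment, when
   present); the mean absolute correlation across strata ranks the
   candidates.
2. A greedy pass in decreasing rank order retains a candidate only if its
   absolute correlation with every already-retained candidate does not
   exceed a threshold (default 0.3); otherwise it is dropped and the
   retained variable that triggered the removal is recorded.

The greedy rule anchored to the yield-correlation ranking is the minimal
procedure consistent with keeping, among collinear variables, the one with
the highest mean absolute yield correlation.  The retained set depends on
the ranking; the dropped-variable audit trail is exported so that this
sensitivity can be inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "ScreenResult",
    "yield_weather_correlations",
    "screen_collinear",
    "rank_for_entry",
]


def _tie_break_key(variable: str, month_order: list[str]) -> tuple[int, int, str]:
    """Deterministic tie-break: rainfall before temperature, earlier month."""
    try:
        kind, month = variable.split(" ", 1)
    except ValueError:
        return (2, len(month_order), variable)
    kind_rank = {"TR": 0, "MT": 1}.get(kind, 2)
    month_rank = month_order.index(month) if month in month_order else len(month_order)
    return (kind_rank, month_rank, variable)


@dataclass
class CorrelationReport:
    """Yield-weather and weather-weather Pearson correlations.

    yield_corr : DataFrame, one row per stratum (N rate x treatment), one
        column per weather variable.
    mean_abs_corr : Series, per-variable mean absolute yield correlation
        across strata (NaN if undefined everywhere).
    weather_corr : symmetric weather-weather correlation matrix.
    month_order : season month names, used only for deterministic tie-breaks.
    """

    yield_corr: pd.DataFrame
    mean_abs_corr: pd.Series
    weather_corr: pd.DataFrame
    month_order: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        """Variables with defined correlations, best first, ties broken
        rainfall-before-temperature then earlier-month (logged)."""
        defined = self.mean_abs_corr.dropna()
        if defined.empty:
            return []
        rounded = defined.round(12)
        dup = rounded[rounded.duplicated(keep=False)]
        if not dup.empty:
            logger.warning(
                "tie in mean absolute correlation among %s; applying "
                "rainfall-before-temperature, earlier-month tie-break",
                sorted(dup.index.tolist()),
            )
        return sorted(
            defined.index,
            key=lambda v: (-defined[v], _tie_break_key(v, self.month_order)),
        )


def yield_weather_correlations(
    yields: pd.DataFrame,
    weather_vars: pd.DataFrame,
    stratifiers: tuple[str, ...] = ("n_rate",),
    *,
    yield_col: str = "yield_t_ha",
    year_col: str = "harvest_year",
    month_order: list[str] | None = None,
) -> CorrelationReport:
    """Correlate annual yield with each seasonal weather variable.

    ``weather_vars`` is indexed by harvest year with one column per weather
    variable (the output of :func:`lexpyield.io_cli.season_table`).
    Zero-variance series give undefined correlations, reported as NaN and
    excluded from the ranking.  Missing yield cells are dropped pairwise.
    """
    if weather_vars.empty:
        raise ValueError("weather_vars is empty")
    years = weather_vars.index
    rows = {}
    for stratum, sub in yields.groupby(list(stratifiers), dropna=False):
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        annual = sub.groupby(year_col)[yield_col].mean()
        annual = annual.reindex(years)
        if annual.notna().sum() < 3:
            raise ValueError(
                f"stratum {stratum} has fewer than 3 years with yield data"
            )
        rows[stratum] = {
            var: _pearson(annual, weather_vars[var]) for var in weather_vars.columns
        }
    index = pd.MultiIndex.from_tuples(list(rows), names=list(stratifiers))
    yield_corr = pd.DataFrame(list(rows.values()), index=index,
                              columns=weather_vars.columns)
    mean_abs = yield_corr.abs().mean(axis=0, skipna=True)
    mean_abs[yield_corr.isna().all(axis=0)] = np.nan
    weather_corr = weather_vars.corr()
    if month_order is None:
        month_order = []
        for var in weather_vars.columns:
            parts = var.split(" ", 1)
            if len(parts) == 2 and parts[1] not in month_order:
                month_order.append(parts[1])
    return CorrelationReport(
        yield_corr=yield_corr,
        mean_abs_corr=mean_abs,
        weather_corr=weather_corr,
        month_order=month_order,
    )


def _pearson(x: pd.Series, y: pd.Series) -> float:
    mask = x.notna() & y.notna()
    if mask.sum() < 3:
        return np.nan
    xv = x[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


@dataclass
class ScreenResult:
    """Outcome of the greedy collinearity screen."""

    retained: list[str]
    dropped: pd.DataFrame  # variable, mean_abs_corr, conflict_with, rho
    threshold: float


def screen_collinear(report: CorrelationReport, threshold: float = 0.3) -> ScreenResult:
    """Greedy collinearity elimination at ``|rho| > threshold``.

    Variables are visited in decreasing order of mean absolute yield
    correlation; a variable is retained iff its absolute correlation with
    every already-retained variable is <= threshold.  The retained set is
    pairwise |rho| <= threshold by construction (asserted).
    """
    order = report.ranking()
    if not order:
        raise ValueError("no candidate variables with defined correlations")
    corr = report.weather_corr
    retained: list[str] = []
    dropped_rows = []
    for var in order:
        conflicts = [
            (u, float(corr.loc[var, u]))
            for u in retained
            if abs(corr.loc[var, u]) > threshold
        ]
        if conflicts:
            worst = max(conflicts, key=lambda t: abs(t[1]))
            dropped_rows.append(
                {
                    "variable": var,
                    "mean_abs_corr": float(report.mean_abs_corr[var]),
                    "conflict_with": worst[0],
                    "rho": worst[1],
                }
            )
            logger.info("screen: dropped %s (|rho|=%.3f with %s)",
                        var, abs(worst[1]), worst[0])
        else:
            retained.append(var)
    for i, u in enumerate(retained):
        for v in retained[i + 1:]:
            assert abs(corr.loc[u, v]) <= threshold + 1e-12
    return ScreenResult(
        retained=retained,
        dropped=pd.DataFrame(
            dropped_rows, columns=["variable", "mean_abs_corr", "conflict_with", "rho"]
        ),
        threshold=threshold,
    )


def rank_for_entry(report: CorrelationReport, retained: list[str]) -> list[str]:
    """Order retained variables for model entry, best mean |rho| first."""
    if not retained:
        raise ValueError("retained variable list is empty")
    order = report.ranking()
    missing = set(retained) - set(order)
    if missing:
        raise ValueError(f"retained variables without correlations: {sorted(missing)}")
    return [v for v in order if v in set(retained)]
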