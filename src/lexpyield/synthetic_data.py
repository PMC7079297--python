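"""Synthetic long-term-experiment data with a known weather-parameterized
LEXP truth.

The generator emulates the structure of multi-decade cereal N-response
trials: a fixed plot layout of N rates (and, for spring barley, mineral
treatments) observed every harvest year, cultivars changing in eras,
monthly weather with configurable marginals and cross-correlations, and
heteroscedastic yields produced by adding Gaussian noise on the sqrt-yield
scale (so raw-scale variance grows with the mean, as in field data).

The LEXP formula is evaluated inline here, deliberately sharing no code
with :mod:`lexpyield.lexp_core`, so the generator and the fitter serve as
mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NRate",
    "CultivarEra",
    "TrialDesign",
    "WeatherGeneratorConfig",
    "WeatherEffect",
    "TrueModel",
    "gen_weather",
    "gen_yields",
    "rothamsted_like_presets",
    "rothamsted_weather_config",
    "replace_years",
]


@dataclass(frozen=True)
class NRate:
    """An N application rate (kg N ha-1), optionally introduced later."""

    rate: float
    from_year: int | None = None


@dataclass(frozen=True)
class CultivarEra:
    name: str
    first: int
    last: int


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a long-term N-response trial."""

    crop: str
    years: tuple[int, int]
    n_rates: tuple[NRate, ...]
    cultivars: tuple[CultivarEra, ...]
    treatments: tuple[str, ...] | None = None
    excluded_years: frozenset[int] = frozenset()
    missing_cells: frozenset[tuple[int, str]] = frozenset()

    def __post_init__(self):
        covered: set[int] = set()
        for era in self.cultivars:
            span = set(range(era.first, era.last + 1))
            if span & covered:
                raise ValueError(f"cultivar eras overlap at {sorted(span & covered)}")
            covered |= span
        wanted = set(self.years_included())
        if not wanted <= covered:
            raise ValueError(
                f"cultivar eras do not cover years {sorted(wanted - covered)}"
            )

    def years_included(self) -> list[int]:
        y0, y1 = self.years
        return [y for y in range(y0, y1 + 1) if y not in self.excluded_years]

    def cultivar_for(self, year: int) -> str:
        for era in self.cultivars:
            if era.first <= year <= era.last:
                return era.name
        raise KeyError(f"no cultivar era covers harvest year {year}")

    def rates_for(self, year: int) -> list[float]:
        return [nr.rate for nr in self.n_rates
                if nr.from_year is None or year >= nr.from_year]


@dataclass(frozen=True)
class WeatherGeneratorConfig:
    """Marginals and dependence for monthly weather.

    Temperatures are normal (mean/SD per month, deg C); rainfall totals are
    gamma (shape/scale per month, mm), which keeps them nonnegative and
    right-skewed.  Dependence enters through a Gaussian copula whose
    correlation entries are listed as ((month, kind), (month, kind), rho)
    with kind in {"rain", "temp"}.
    """

    temp_mean: tuple[float, ...]
    temp_sd: tuple[float, ...]
    rain_shape: tuple[float, ...]
    rain_scale: tuple[float, ...]
    correlations: tuple[tuple[tuple[int, str], tuple[int, str], float], ...] = ()

    def __post_init__(self):
        for name in ("temp_mean", "temp_sd", "rain_shape", "rain_scale"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must have 12 monthly entries")

    @staticmethod
    def _idx(month: int, kind: str) -> int:
        if kind not in ("rain", "temp") or not (1 <= month <= 12):
            raise ValueError(f"bad correlation key ({month}, {kind})")
        return 2 * (month - 1) + (0 if kind == "rain" else 1)

    def correlation_matrix(self) -> np.ndarray:
        C = np.eye(24)
        for (m1, k1), (m2, k2), rho in self.correlations:
            i, j = self._idx(m1, k1), self._idx(m2, k2)
            if i == j:
                raise ValueError("correlation entry refers to one variable twice")
            C[i, j] = C[j, i] = float(rho)
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )
        return C


def gen_weather(config: WeatherGeneratorConfig, years, seed: int) -> pd.DataFrame:
    """Sample a monthly weather table (columns year, month, rain_mm, temp_c).

    Reproducible given the seed.  A Gaussian copula induces the configured
    cross-correlations; marginals are transformed per variable, so zero
    SDs/scales yield constant series at the configured location.
    """
    years = [int(y) for y in years]
    C = config.correlation_matrix()
    # tiny jitter keeps Cholesky defined at the PSD boundary
    L = np.linalg.cholesky(C + 1e-12 * np.eye(24))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(years), 24)) @ L.T
    u = stats.norm.cdf(z)
    rows = []
    for i, year in enumerate(years):
        for m in range(1, 13):
            u_rain = u[i, 2 * (m - 1)]
            z_temp = z[i, 2 * (m - 1) + 1]
            shape, scale = config.rain_shape[m - 1], config.rain_scale[m - 1]
            rain = (float(stats.gamma.ppf(u_rain, shape, scale=scale))
                    if scale > 0 else 0.0)
            temp = config.temp_mean[m - 1] + config.temp_sd[m - 1] * z_temp
            rows.append({"year": year, "month": m,
                         "rain_mm": rain, "temp_c": float(temp)})
    return pd.DataFrame(rows, columns=["year", "month", "rain_mm", "temp_c"])


@dataclass(frozen=True)
class WeatherEffect:
    """A generating effect of one seasonal weather variable on one LEXP
    parameter: contribution = coef * (x - center)**degree."""

    parameter: str
    variable: str
    coef: float
    degree: int = 1
    center: float = 0.0


@dataclass(frozen=True)
class TrueModel:
    """Generating truth: fixed r, per-treatment baseline (a, b, c),
    additive weather and cultivar effects, Gaussian noise on sqrt scale."""

    r: float
    baselines: dict
    weather_effects: tuple[WeatherEffect, ...] = ()
    cultivar_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.15


def gen_yields(design: TrialDesign, weather: pd.DataFrame, truth: TrueModel,
               seed: int) -> pd.DataFrame:
    """Generate plot-year yields (t ha-1) from the weather-shifted truth.

    sqrt-yield = LEXP(a', b', c', r; N) + noise, floored at 0 and squared;
    a', b', c' are the treatment baselines shifted by the configured
    weather and cultivar effects.
    """
    from .io_cli import align_season  # deferred: avoids an import cycle

    rng = np.random.default_rng(seed)
    treatments = design.treatments or (None,)
    for eff in truth.weather_effects:
        if eff.parameter not in ("a", "b", "c"):
            raise ValueError(f"unknown LEXP parameter {eff.parameter!r}")
    rows = []
    for year in design.years_included():
        wx = align_season(weather, year, design.crop)
        for eff in truth.weather_effects:
            if eff.variable not in wx.index:
                raise ValueError(
                    f"truth references weather variable {eff.variable!r} "
                    f"absent from the {design.crop} season window"
                )
        cultivar = design.cultivar_for(year)
        shift = {"a": 0.0, "b": 0.0, "c": 0.0}
        for eff in truth.weather_effects:
            shift[eff.parameter] += (
                eff.coef * (float(wx[eff.variable]) - eff.center) ** eff.degree
            )
        for p, per_cv in truth.cultivar_effects.items():
            shift[p] += float(per_cv.get(cultivar, 0.0))
        for treat in treatments:
            if treat is not None and (year, treat) in design.missing_cells:
                continue
            base_a, base_b, base_c = truth.baselines[treat]
            a = base_a + shift["a"]
            b = base_b + shift["b"]
            c = base_c + shift["c"]
            for n in design.rates_for(year):
                # independent LEXP evaluation (no lexp_core code)
                mu = a + b * truth.r ** n + c * n
                s = mu + rng.normal(0.0, truth.noise_sd)
                s = max(s, 0.0)
                rows.append({
                    "harvest_year": year,
                    "crop": design.crop,
                    "plot": f"{treat or 'N'}-{int(n)}",
                    "treatment": treat,
                    "cultivar": cultivar,
                    "n_rate": float(n),
                    "yield_t_ha": s * s,
                })
    return pd.DataFrame(rows, columns=[
        "harvest_year", "crop", "plot", "treatment", "cultivar",
        "n_rate", "yield_t_ha",
    ])


def rothamsted_weather_config() -> WeatherGeneratorConfig:
    """Monthly climate resembling a southern-England lowland site, with a
    negative June temperature-rainfall association."""
    return WeatherGeneratorConfig(
        temp_mean=(3.5, 3.7, 5.7, 8.1, 11.3, 14.3, 16.4, 16.2, 13.7, 10.3,
                   6.5, 4.2),
        temp_sd=(1.6, 1.6, 1.3, 1.1, 1.1, 1.0, 1.1, 1.1, 1.0, 1.1, 1.2, 1.5),
        rain_shape=(3.5,) * 12,
        rain_scale=(20.0, 14.9, 16.6, 15.7, 15.7, 17.1, 17.1, 18.6, 17.1,
                    21.4, 21.4, 21.4),
        correlations=(((6, "temp"), (6, "rain"), -0.4),),
    )


_WHEAT_CULTIVARS = (
    CultivarEra("Cappelle Desprez", 1968, 1978),
    CultivarEra("Flanders", 1979, 1984),
    CultivarEra("Brimstone", 1985, 1990),
    CultivarEra("Apollo", 1991, 1995),
    CultivarEra("Hereward", 1996, 2012),
    CultivarEra("Crusoe", 2013, 2016),
)

_BARLEY_CULTIVARS = (
    CultivarEra("Maris Badger", 1968, 1969),
    CultivarEra("Julia", 1970, 1979),
    CultivarEra("Georgie", 1980, 1983),
    CultivarEra("Triumph", 1984, 1991),
    CultivarEra("Alexis", 1992, 1995),
    CultivarEra("Cooper", 1996, 1999),
    CultivarEra("Optic", 2000, 2007),
    CultivarEra("Tipple", 2008, 2015),
    CultivarEra("Irina", 2016, 2016),
)


def rothamsted_like_presets() -> dict:
    """Trial layouts and generating truths emulating the two long-term
    experiments (winter wheat and spring barley), 1968-2016.

    Baseline parameter values that are published for these experiments are
    used exactly (wheat all-years curve a=2.402, b=-1.261, c=0.00085,
    r=0.985; barley per-treatment c coefficients and the PKNaMg a/b);
    unpublished barley a/b baselines for P, KNaMg and Nil are synthetic
    choices producing flatter, lower curves.
    """
    wheat_design = TrialDesign(
        crop="wheat",
        years=(1968, 2016),
        n_rates=(NRate(0), NRate(48), NRate(96), NRate(144), NRate(192),
                 NRate(240, 1985), NRate(288, 1985)),
        cultivars=_WHEAT_CULTIVARS,
        excluded_years=frozenset({2013, 2015}),
    )
    wheat_truth = TrueModel(
        r=0.985,
        baselines={None: (2.402, -1.261, 0.00085)},
        weather_effects=(
            WeatherEffect("a", "TR October", -1.65e-3, center=75.0),
            WeatherEffect("a", "MT May", -0.04, center=11.3),
            WeatherEffect("a", "MT April", -0.03, degree=2, center=11.0),
        ),
        cultivar_effects={
            "a": {"Cappelle Desprez": 0.15, "Flanders": 0.13, "Brimstone": 0.11,
                  "Apollo": 0.11, "Crusoe": 0.08},
        },
        noise_sd=0.15,
    )
    barley_design = TrialDesign(
        crop="barley",
        years=(1968, 2016),
        n_rates=(NRate(0), NRate(48), NRate(96), NRate(144)),
        cultivars=_BARLEY_CULTIVARS,
        treatments=("PKNaMg", "P", "KNaMg", "Nil"),
        missing_cells=frozenset({(2007, "KNaMg")}),
    )
    barley_truth = TrueModel(
        r=0.985,
        baselines={
            "PKNaMg": (2.59, -1.33, -0.00451),
            "P": (2.45, -1.15, -0.00483),     # synthetic a/b
            "KNaMg": (2.10, -0.90, -0.00398),  # synthetic a/b
            "Nil": (1.60, -0.45, -0.00153),    # synthetic a/b
        },
        weather_effects=(
            WeatherEffect("a", "TR April", -2.0e-4, degree=2, center=25.0),
            WeatherEffect("a", "MT February", -0.04, center=3.7),
            WeatherEffect("b", "TR September", 2.78e-3, center=60.0),
        ),
        cultivar_effects={
            "a": {"Alexis": 0.22, "Cooper": -0.19, "Georgie": 0.16,
                  "Irina": 0.18, "Julia": 0.17, "Maris Badger": 0.09,
                  "Optic": -0.18, "Triumph": 0.07},
        },
        noise_sd=0.15,
    )
    weather_cfg = rothamsted_weather_config()
    return {
        "wheat": (wheat_design, weather_cfg, wheat_truth),
        "barley": (barley_design, weather_cfg, barley_truth),
    }


def replace_years(design: TrialDesign, years: tuple[int, int]) -> TrialDesign:
    """A copy of a design restricted/extended to a new year range (cultivar
    eras are clipped; the last era extends to cover later years)."""
    y0, y1 = years
    eras = [e for e in design.cultivars if e.last >= y0 and e.first <= y1]
    eras = [CultivarEra(e.name, max(e.first, y0), min(e.last, y1)) for e in eras]
    if eras and eras[-1].last < y1:
        eras[-1] = CultivarEra(eras[-1].name, eras[-1].first, y1)
    if eras and eras[0].first > y0:
        eras[0] = CultivarEra(eras[0].name, y0, eras[0].last)
    return replace(design, years=(y0, y1), cultivars=tuple(eras),
                   excluded_years=frozenset(y for y in design.excluded_years
                                            if y0 <= y <= y1))
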