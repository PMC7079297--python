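"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lexpyield import lexp_core, synthetic_data

FIG_PARAMS = dict(a=2.402, b=-1.261, c=0.00085, r=0.985)
N_RATES_FULL = np.array([0.0, 48.0, 96.0, 144.0, 192.0, 240.0, 288.0])


def lexp_reference(a, b, c, r, n):
    """Independent arithmetic evaluation of the LEXP curve (test oracle)."""
    n = np.asarray(n, dtype=float)
    return a + b * np.exp(n * np.log(r)) + c * n


@pytest.fixture(scope="session")
def noise_free_curve():
    """Noise-free sqrt-scale yields at the seven N rates from the reference
    all-years wheat curve."""
    p = FIG_PARAMS
    y = lexp_reference(p["a"], p["b"], p["c"], p["r"], N_RATES_FULL)
    return pd.DataFrame({"n_rate": N_RATES_FULL, "sqrt_yield": y})


@pytest.fixture(scope="session")
def wheat_preset():
    design, wcfg, truth = synthetic_data.rothamsted_like_presets()["wheat"]
    return design, wcfg, truth


@pytest.fixture(scope="session")
def wheat_dataset(wheat_preset):
    """One synthetic wheat trial (weather + yields + sqrt column)."""
    design, wcfg, truth = wheat_preset
    y0, y1 = design.years
    weather = synthetic_data.gen_weather(wcfg, range(y0 - 1, y1 + 1), seed=42)
    yields = synthetic_data.gen_yields(design, weather, truth, seed=43)
    yields["sqrt_yield"] = lexp_core.sqrt_transform(yields["yield_t_ha"])
    return weather, yields


@pytest.fixture(scope="session")
def barley_dataset():
    design, wcfg, truth = synthetic_data.rothamsted_like_presets()["barley"]
    y0, y1 = design.years
    weather = synthetic_data.gen_weather(wcfg, range(y0 - 1, y1 + 1), seed=7)
    yields = synthetic_data.gen_yields(design, weather, truth, seed=8)
    yields["sqrt_yield"] = lexp_core.sqrt_transform(yields["yield_t_ha"])
    return weather, yields
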