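"""Operating-characteristic experiments for the selection machinery.

These simulations measure, on synthetic data with a known generating
truth, the statistical behaviour of the pipeline: the type-I error of the
marginal partial-F pruning step, the uniformity of the joint validation
p-value under a true null, and the rate at which the full
screen-build-select pipeline recovers the generating terms together with
the bias of their coefficient estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_cli, lexp_core, screening, selection, synthetic_data
from .synthetic_data import TrueModel, WeatherEffect

__all__ = [
    "null_term_rejection_rate",
    "eliminated_terms_pvalues",
    "RecoveryResult",
    "recovery_truth",
    "term_recovery_experiment",
]


def null_term_rejection_rate(n_replicates: int = 1000, *, alpha: float = 0.05,
                             n_obs: int = 60, seed: int = 0) -> float:
    """Fraction of replicates in which the marginal partial F-test rejects
    a term whose generating coefficient is exactly zero.

    Under Gaussian noise the test is exact, so the rate should match
    ``alpha`` up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([
        np.ones(n_obs),
        rng.standard_normal((n_obs, 4)),
    ])
    beta = np.array([1.0, 0.5, -0.3, 0.2, 0.0])  # last term is null
    idx_full = np.arange(5)
    idx_red = np.arange(4)
    rejections = 0
    for _ in range(n_replicates):
        y = X @ beta + rng.standard_normal(n_obs)
        rss_f = _rss(X[:, idx_full], y)
        rss_r = _rss(X[:, idx_red], y)
        cmp_ = selection.partial_f(rss_r, rss_f, n_obs - 4, n_obs - 5)
        if cmp_.pvalue < alpha:
            rejections += 1
    return rejections / n_replicates


def eliminated_terms_pvalues(n_replicates: int = 500, *, n_obs: int = 80,
                             n_null: int = 3, seed: int = 0) -> np.ndarray:
    """Joint-F p-values for a block of truly null terms, one per replicate.

    Under the null these are uniform on (0, 1); used to check the
    validation F-test of eliminated terms.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([
        np.ones(n_obs),
        rng.standard_normal((n_obs, 2 + n_null)),
    ])
    beta = np.concatenate([[1.0, 0.6, -0.4], np.zeros(n_null)])
    k_red = 3
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        y = X @ beta + rng.standard_normal(n_obs)
        rss_f = _rss(X, y)
        rss_r = _rss(X[:, :k_red], y)
        cmp_ = selection.partial_f(rss_r, rss_f, n_obs - k_red, n_obs - X.shape[1])
        pvals[i] = cmp_.pvalue
    return pvals


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# full-pipeline term recovery


def recovery_truth() -> TrueModel:
    """Generating truth for the recovery experiment: one linear and one
    quadratic weather variable acting on parameter ``a`` (three weather
    term columns in the raw-polynomial basis) plus a cultivar trend.

    Effect sizes are four to six times their maximal-model standard
    errors at the design's sample size, so the experiment measures the
    pipeline's behaviour under clearly detectable effects.
    """
    return TrueModel(
        r=0.985,
        baselines={None: (3.4, -0.85, 0.00085)},
        weather_effects=(
            WeatherEffect("a", "MT May", -0.38, center=11.3),
            WeatherEffect("a", "MT April", -0.11, degree=2, center=9.6),
        ),
        cultivar_effects={
            # breeding-progress trend, block contrasts several SEs wide
            "a": {"Cappelle Desprez": -0.2, "Flanders": -0.1,
                  "Brimstone": 0.2, "Apollo": 0.45, "Crusoe": 0.8},
        },
        noise_sd=0.15,
    )


# truth expressed in the raw-polynomial fitting basis:
# -0.11*(x-9.6)^2 = -0.11*x^2 + 2.112*x + const
RECOVERY_COEFFICIENTS = {
    "a:MT May": -0.38,
    "a:MT April (1)": 2.112,
    "a:MT April (2)": -0.11,
}
RECOVERY_TERMS = ("a:MT May", "a:MT April (1)", "a:MT April (2)", "a:cultivar")
RECOVERY_VARIABLES = ("MT May", "MT April", "cultivar")


@dataclass
class RecoveryResult:
    """Outcome of the replicated full-pipeline recovery experiment.

    ``all_variables_rate`` is the fraction of replicates whose selected
    model represents every generating effect (the variable appears in some
    LEXP parameter function, and the cultivar block on ``a`` is kept);
    ``all_terms_rate`` additionally requires the effect to be attributed
    to the generating parameter (``a``), which is weakly identified with
    few N rates and is reported without being a pass/fail quantity.
    """

    n_replicates: int
    all_variables_rate: float
    all_terms_rate: float
    variable_rates: dict
    term_rates: dict
    estimates: dict = field(repr=False)

    def estimate_summary(self) -> pd.DataFrame:
        rows = []
        for label, values in self.estimates.items():
            arr = np.asarray(values, dtype=float)
            n = len(arr)
            rows.append({
                "term": label,
                "truth": RECOVERY_COEFFICIENTS[label],
                "mean": arr.mean() if n else np.nan,
                "mc_se": arr.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_present": n,
            })
        return pd.DataFrame(rows)


def _one_recovery_replicate(design, wcfg, truth, seed, quadratic=("MT April",)):
    y0, y1 = design.years
    weather = synthetic_data.gen_weather(wcfg, range(y0 - 1, y1 + 1), seed)
    yields = synthetic_data.gen_yields(design, weather, truth, seed + 1_000_000)
    yields["sqrt_yield"] = lexp_core.sqrt_transform(yields["yield_t_ha"])

    # curvature from the per-year fit with a common r, as in the pipeline
    fit_by_year = lexp_core.fit_lexp(
        yields,
        lexp_core.SharingSpec(a="harvest_year", b="harvest_year",
                              c="harvest_year"),
        xatol=1e-8,
    )
    r_fixed = float(np.clip(fit_by_year.r, 0.5, 0.9995))

    years = sorted(yields["harvest_year"].unique())
    wx = io_cli.season_table(weather, years, design.crop)
    report = screening.yield_weather_correlations(yields, wx, ("n_rate",))
    screen = screening.screen_collinear(report, 0.3)
    entry = screening.rank_for_entry(report, screen.retained)

    model_data = yields.join(wx, on="harvest_year")
    dmat = selection.build_maximal(
        model_data, entry, r_fixed=r_fixed,
        factors=(selection.FactorSpec("cultivar", "Hereward", "Cv."),),
        quadratic=tuple(v for v in quadratic if v in entry),
        poly_mode="raw",
    )
    y = model_data["sqrt_yield"].to_numpy(dtype=float)
    reduced = selection.backward_aic(dmat, y)
    final = selection.prune_partial_f(dmat, y, reduced.active, 0.05)
    fit = final.fit
    term_present = {t: t in final.active for t in RECOVERY_TERMS}
    var_present = {
        "MT May": any("MT May" in g for g in final.active),
        "MT April": any("MT April" in g for g in final.active),
        "cultivar": any(g.endswith(":cultivar") for g in final.active),
    }
    estimates = {}
    for label in RECOVERY_COEFFICIENTS:
        if label in fit.labels:
            estimates[label] = float(fit.beta[fit.labels.index(label)])
    return term_present, var_present, estimates


def term_recovery_experiment(n_replicates: int = 200, seed: int = 0
                             ) -> RecoveryResult:
    """Run the full pipeline on replicated synthetic trials and measure
    how often the parsimonious model recovers the generating effects, and
    the distribution of the recovered coefficient estimates."""
    wheat_design, wcfg, _ = synthetic_data.rothamsted_like_presets()["wheat"]
    truth = recovery_truth()
    term_hits = {t: 0 for t in RECOVERY_TERMS}
    var_hits = {v: 0 for v in RECOVERY_VARIABLES}
    estimates = {t: [] for t in RECOVERY_COEFFICIENTS}
    all_terms = 0
    all_vars = 0
    for i in range(n_replicates):
        terms, variables, est = _one_recovery_replicate(
            wheat_design, wcfg, truth, seed + 7919 * i)
        for t, ok in terms.items():
            term_hits[t] += ok
        for v, ok in variables.items():
            var_hits[v] += ok
        all_terms += all(terms.values())
        all_vars += all(variables.values())
        for label, value in est.items():
            estimates[label].append(value)
    return RecoveryResult(
        n_replicates=n_replicates,
        all_variables_rate=all_vars / n_replicates,
        all_terms_rate=all_terms / n_replicates,
        variable_rates={v: h / n_replicates for v, h in var_hits.items()},
        term_rates={t: h / n_replicates for t, h in term_hits.items()},
        estimates=estimates,
    )
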