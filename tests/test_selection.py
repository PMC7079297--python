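"""Tests for design building, OLS, F machinery and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexpyield import selection
from lexpyield.selection import (
    FactorSpec,
    InteractionSpec,
    backward_aic,
    build_maximal,
    compare_models,
    exclude_outlier_years,
    fit_linear,
    flag_outlier_years,
    partial_f,
    prune_partial_f,
    validate_elimination,
)

R_FIXED = 0.985


def simple_data(n_years=50, n_vars=4, seed=0, rates=(0.0, 48.0, 96.0, 144.0)):
    """Plot-year table with generic weather-like covariates W0..Wk."""
    rng = np.random.default_rng(seed)
    years = np.arange(n_years)
    wx = rng.standard_normal((n_years, n_vars))
    rows = []
    for i, yr in enumerate(years):
        for n in rates:
            rows.append({"harvest_year": yr, "n_rate": n,
                         **{f"W{j}": wx[i, j] for j in range(n_vars)}})
    return pd.DataFrame(rows)


def response(df, coef, noise=0.1, seed=1, r=R_FIXED):
    rng = np.random.default_rng(seed)
    n = df["n_rate"].to_numpy()
    mu = 2.5 - 1.2 * r ** n + 0.0005 * n
    for (param, var), beta in coef.items():
        basis = {"a": 1.0, "b": r ** n, "c": n}[param]
        mu = mu + beta * df[var].to_numpy() * basis
    return mu + rng.normal(0, noise, len(df))


class TestBuildMaximal:
    def test_column_count_arithmetic(self):
        df = simple_data(n_years=10, n_vars=2)
        df["cultivar"] = np.where(df["harvest_year"] < 5, "old", "new")
        design = build_maximal(
            df, ["W0", "W1"], r_fixed=R_FIXED,
            factors=(FactorSpec("cultivar", "new"),))
        # 3 intercepts + factor dummies on a,b,c + 2 vars * 3 params
        assert design.X.shape[1] == 3 + 3 + 6

    def test_wheat_like_term_inventory_labels(self):
        inventory = [
            "TR October", "MT May", "TR July", "MT November", "TR February",
            "MT April", "TR June", "TR December", "TR August", "TR November",
            "TR May", "MT December", "TR January",
        ]
        rng = np.random.default_rng(2)
        df = simple_data(n_years=30, n_vars=0)
        for v in inventory:
            df[v] = rng.standard_normal(len(df))
        design = build_maximal(df, inventory, r_fixed=R_FIXED)
        labels = design.col_labels
        for v in inventory:
            for p in ("a", "b", "c"):
                assert f"{p}:{v}" in labels

    def test_identical_builds_are_identical(self):
        df = simple_data()
        d1 = build_maximal(df, ["W0", "W1", "W2"], r_fixed=R_FIXED,
                           quadratic=("W1",))
        d2 = build_maximal(df, ["W0", "W1", "W2"], r_fixed=R_FIXED,
                           quadratic=("W1",))
        assert d1.col_labels == d2.col_labels
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_rank_deficient_design_rejected_with_names(self):
        df = simple_data(n_vars=2)
        df["W1"] = df["W0"]  # duplicate column
        with pytest.raises(ValueError, match="W1"):
            build_maximal(df, ["W0", "W1"], r_fixed=R_FIXED)

    def test_quadratic_pair_labels_and_hierarchy(self):
        df = simple_data(n_vars=1)
        design = build_maximal(df, ["W0"], r_fixed=R_FIXED, quadratic=("W0",))
        assert "a:W0 (1)" in design.col_labels
        assert "a:W0 (2)" in design.col_labels
        droppable = design.droppable(design.all_groups())
        assert "a:W0 (2)" in droppable
        assert "a:W0 (1)" not in droppable  # (2) must leave first
        assert "a:Intercept" not in droppable

    def test_interactions_protect_main_effects(self):
        df = simple_data(n_vars=1)
        df["treatment"] = np.where(df["harvest_year"] % 2 == 0, "T1", "T2")
        design = build_maximal(
            df, ["W0"], r_fixed=R_FIXED,
            factors=(FactorSpec("treatment", "T1", "Treat."),),
            interactions=(InteractionSpec("treatment", "W0"),))
        droppable = design.droppable(design.all_groups())
        assert "a:treatment×W0" in droppable
        assert "a:W0" not in droppable
        assert "a:treatment" not in droppable
        remaining = design.all_groups() - {"a:treatment×W0"}
        assert "a:W0" in design.droppable(remaining)


class TestFitLinear:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        df = simple_data(n_years=25, n_vars=2, seed=8)
        design = build_maximal(df, ["W0", "W1"], r_fixed=R_FIXED)
        y = rng.standard_normal(len(df))
        fit = fit_linear(design, y)
        X = design.X
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.rss == pytest.approx(rss, abs=1e-10)
        assert fit.aic == pytest.approx(
            len(y) * np.log(rss / len(y)) + 2 * (X.shape[1] + 1))

    def test_nested_rss_ordering(self):
        df = simple_data(seed=4)
        design = build_maximal(df, ["W0", "W1", "W2", "W3"], r_fixed=R_FIXED)
        y = response(df, {("a", "W0"): 0.3}, seed=1004)
        full = fit_linear(design, y)
        reduced = fit_linear(design, y, design.all_groups() - {"a:W1"})
        assert full.rss <= reduced.rss + 1e-12

    def test_nonfinite_rejected(self):
        df = simple_data(n_years=5, n_vars=1)
        design = build_maximal(df, ["W0"], r_fixed=R_FIXED)
        y = np.full(len(df), np.nan)
        with pytest.raises(ValueError):
            fit_linear(design, y)


class TestCompareModels:
    def test_hand_arithmetic(self):
        cmp_ = partial_f(20.0, 10.0, 55, 50)
        assert cmp_.fstat == pytest.approx(10.0)
        assert (cmp_.df1, cmp_.df2) == (5, 50)

    @pytest.mark.parametrize("f, df1, df2, expected", [
        (0.392, 46, 107, 0.999),
        (0.44, 3, 760, 0.723),
        (1.42, 40, 272, 0.057),
    ])
    def test_upper_tail_probabilities(self, f, df1, df2, expected):
        # the F statistics are printed rounded to 2-3 significant figures,
        # so the p-value is reproducible to ~0.002 at 3 decimals
        p = float(stats.f.sf(f, df1, df2))
        assert p == pytest.approx(expected, abs=2e-3)

    def test_matches_bruteforce_refit_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n, k = 40, 6
            X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            y = rng.standard_normal(n)
            kr = int(rng.integers(1, k))
            # oracle: refit both models from scratch and form the ratio
            def rss_of(M):
                b = np.linalg.lstsq(M, y, rcond=None)[0]
                return float(((y - M @ b) ** 2).sum())
            rss_f, rss_r = rss_of(X), rss_of(X[:, :kr])
            F_oracle = ((rss_r - rss_f) / (k - kr)) / (rss_f / (n - k))
            cmp_ = partial_f(rss_r, rss_f, n - kr, n - k)
            assert cmp_.fstat == pytest.approx(F_oracle, abs=1e-10)
            assert cmp_.pvalue == pytest.approx(
                float(stats.f.sf(F_oracle, k - kr, n - k)), abs=1e-12)

    def test_non_nested_rejected(self):
        df = simple_data(seed=2)
        design = build_maximal(df, ["W0", "W1"], r_fixed=R_FIXED)
        y = response(df, {}, seed=1002)
        full = fit_linear(design, y)
        reduced = fit_linear(design, y, design.all_groups() - {"a:W0"})
        with pytest.raises(ValueError):
            compare_models(reduced, full)  # arguments swapped


class TestBackwardAIC:
    def test_pure_noise_covariate_eliminated(self):
        kept_signal, dropped_noise = 0, 0
        n_rep = 100
        for i in range(n_rep):
            df = simple_data(n_years=125, n_vars=2, seed=100 + i)
            y = response(df, {("a", "W0"): 0.5}, noise=0.3, seed=5200 + i)
            design = build_maximal(df, ["W0", "W1"], r_fixed=R_FIXED,
                                   weather_params=("a",))
            res = backward_aic(design, y)
            kept_signal += "a:W0" in res.active
            dropped_noise += "a:W1" not in res.active
        assert kept_signal / n_rep >= 0.95
        assert dropped_noise / n_rep >= 0.75  # AIC keeps noise w.p. ~P(chi2>2)

    def test_zero_step_trace_at_minimum(self):
        df = simple_data(n_years=100, n_vars=1, seed=5)
        y = response(df, {("a", "W0"): 1.0}, noise=0.05, seed=1005)
        design = build_maximal(df, ["W0"], r_fixed=R_FIXED,
                               weather_params=("a",))
        res = backward_aic(design, y)
        assert len(res.trace) == 0
        assert res.active == design.all_groups()

    def test_trace_strictly_decreasing(self):
        df = simple_data(n_years=60, n_vars=4, seed=6)
        y = response(df, {}, noise=0.5, seed=1006)
        design = build_maximal(df, ["W0", "W1", "W2", "W3"], r_fixed=R_FIXED)
        res = backward_aic(design, y)
        assert len(res.trace) > 0
        assert (res.trace["aic_after"] < res.trace["aic_before"]).all()
        assert res.fit.aic <= fit_linear(design, y).aic


class TestPrunePartialF:
    def test_strong_terms_unchanged(self):
        df = simple_data(n_years=80, n_vars=2, seed=7)
        y = response(df, {("a", "W0"): 1.0, ("a", "W1"): -1.0}, noise=0.05,
                     seed=1007)
        design = build_maximal(df, ["W0", "W1"], r_fixed=R_FIXED,
                               weather_params=("a",))
        res = prune_partial_f(design, y, design.all_groups())
        assert res.active == design.all_groups()
        assert len(res.trace) == 0

    def test_remaining_groups_all_significant(self):
        df = simple_data(n_years=60, n_vars=4, seed=9)
        y = response(df, {("a", "W0"): 0.4}, noise=0.3, seed=1009)
        design = build_maximal(df, ["W0", "W1", "W2", "W3"], r_fixed=R_FIXED)
        res = prune_partial_f(design, y, design.all_groups(), alpha=0.05)
        fit = res.fit
        for gid in design.droppable(res.active):
            reduced = fit_linear(design, y, res.active - {gid})
            assert compare_models(fit, reduced).pvalue < 0.05


class TestValidateElimination:
    def test_no_terms_eliminated_edge_case(self):
        df = simple_data(n_years=30, n_vars=1)
        y = response(df, {("a", "W0"): 0.5}, seed=1003)
        design = build_maximal(df, ["W0"], r_fixed=R_FIXED)
        res = validate_elimination(design, y, design.all_groups(),
                                   design.all_groups())
        assert res.comparison.df1 == 0
        assert res.comparison.note == "no terms eliminated"

    def test_null_pvalues_uniform(self):
        from lexpyield.experiments import eliminated_terms_pvalues
        pvals = eliminated_terms_pvalues(n_replicates=500, seed=14)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestOutlierYears:
    def test_empty_list_is_identity(self):
        df = simple_data(n_years=10, n_vars=1)
        out, audit = exclude_outlier_years(df, [])
        pd.testing.assert_frame_equal(out, df)
        assert audit.empty

    def test_explicit_list_counts(self):
        df = simple_data(n_years=49, n_vars=1)
        df["harvest_year"] += 1968
        out, _ = exclude_outlier_years(df, [1993, 1998, 2000, 2012])
        assert out["harvest_year"].nunique() == 45

    def test_excluding_everything_rejected(self):
        df = simple_data(n_years=3, n_vars=1)
        with pytest.raises(ValueError):
            exclude_outlier_years(df, [0, 1, 2])

    def test_injected_extreme_year_flips_quadratic_sign(self):
        rng = np.random.default_rng(15)
        years = np.arange(1968, 2008)
        x = rng.gamma(3.5, 15.0, len(years))
        x[5] = 400.0  # one extreme-rainfall year
        # negative quadratic truth; the extreme year drags the fit positive
        y_year = -0.0004 * (x - 50.0) ** 2 + rng.normal(0, 0.2, len(years))
        y_year[5] = 3.0
        df = pd.DataFrame({"harvest_year": years, "TR April": x,
                           "resp": y_year})

        def quad_coef(sub):
            M = np.column_stack([np.ones(len(sub)), sub["TR April"],
                                 sub["TR April"] ** 2])
            return float(np.linalg.lstsq(M, sub["resp"], rcond=None)[0][2])

        flagged, audit = flag_outlier_years(df, "TR April", quad_coef,
                                            quantile=0.95)
        assert flagged == [1973]
        assert audit.loc[audit["year"] == 1973, "flagged"].item()
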