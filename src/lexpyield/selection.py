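"""Model building and selection for weather-parameterized LEXP curves.

With the nonlinear curvature parameter ``r`` fixed, the LEXP model with
parameters ``a``, ``b``, ``c`` written as linear functions of covariates is
linear in all coefficients: a covariate ``x`` influencing ``a`` enters the
design as ``x``, one influencing ``b`` as ``x * r**N`` and one influencing
``c`` as ``x * N``.  Model selection therefore reduces to stepwise multiple
linear regression on that basis:

1. a *maximal* model includes every screened weather variable in the
   ``a``, ``b`` and ``c`` parameter functions plus cultivar (and mineral
   treatment) factors in a first-level-zero parametrization;
2. backward elimination removes, at each step, the droppable term-group
   whose removal most reduces AIC, until no removal reduces it;
3. marginal partial F-tests (extra sum of squares) then prune any
   remaining term-group whose omission is not significant at ``alpha``.

Droppable groups respect a hierarchy: the second-order "(2)" column of a
quadratic pair leaves before its "(1)" partner, interactions leave before
the main effects they involve, factor dummy blocks move as a unit, and the
three intercepts never leave.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSpec",
    "InteractionSpec",
    "QuadBasis",
    "Design",
    "LinearFitResult",
    "ModelComparison",
    "EliminationResult",
    "ValidationResult",
    "WeatherLEXPModel",
    "aic",
    "build_maximal",
    "fit_linear",
    "compare_models",
    "backward_aic",
    "prune_partial_f",
    "validate_elimination",
    "exclude_outlier_years",
    "flag_outlier_years",
]

PARAMS = ("a", "b", "c")


def aic(n_obs: int, rss: float, k: int) -> float:
    """AIC = n ln(RSS/n) + 2(k+1), counting the residual variance in k+1."""
    if rss <= 0:
        return -math.inf
    return n_obs * math.log(rss / n_obs) + 2 * (k + 1)


# ---------------------------------------------------------------------------
# term specification


@dataclass(frozen=True)
class FactorSpec:
    """A qualitative covariate in first-level-zero parametrization.

    ``baseline`` defines the intercept level; dummies are created for the
    other levels.  ``display`` prefixes exported labels (e.g. ``"Cv."`` or
    ``"Treat."``).
    """

    column: str
    baseline: str
    display: str = ""
    parameters: tuple[str, ...] = PARAMS

    def label(self, level: str) -> str:
        return f"{self.display} {level}".strip()


@dataclass(frozen=True)
class InteractionSpec:
    """factor x covariate interaction (covariate: weather variable or a
    second factor column), entering the listed LEXP parameters."""

    factor: str
    covariate: str
    parameters: tuple[str, ...] = ("a",)


class QuadBasis:
    """Degree-2 polynomial basis for a continuous covariate.

    ``orthogonal`` mode builds orthogonal polynomials over the observed
    values via the Forsythe three-term recurrence (same construction as
    R's ``poly``), which keeps quadratic-term coefficients on an O(1)
    scale; ``raw`` mode uses ``x`` and ``x**2`` directly so coefficients
    are comparable with a raw-polynomial generating truth.
    """

    def __init__(self, x, mode: str = "orthogonal"):
        if mode not in ("orthogonal", "raw"):
            raise ValueError(f"unknown polynomial mode {mode!r}")
        self.mode = mode
        x = np.asarray(x, dtype=float)
        if mode == "orthogonal":
            n = len(x)
            a1 = float(x.mean())
            f1 = x - a1
            n2_0, n2_1 = float(n), float(f1 @ f1)
            if n2_1 <= 0:
                raise ValueError("zero-variance covariate: quadratic basis undefined")
            a2 = float((x * f1 ** 2).sum() / n2_1)
            f2 = (x - a2) * f1 - (n2_1 / n2_0)
            n2_2 = float(f2 @ f2)
            if n2_2 <= 0:
                raise ValueError("degenerate covariate: quadratic basis undefined")
            self._coef = (a1, a2, n2_1, n2_0, n2_2)

    def transform(self, x):
        x = np.asarray(x, dtype=float)
        if self.mode == "raw":
            return x, x ** 2
        a1, a2, n2_1, n2_0, n2_2 = self._coef
        f1 = x - a1
        f2 = (x - a2) * f1 - (n2_1 / n2_0)
        return f1 / math.sqrt(n2_1), f2 / math.sqrt(n2_2)


# ---------------------------------------------------------------------------
# column features (shared by design build and prediction)


class _Intercept:
    label = "Intercept"

    def rows(self, df):
        return np.ones(len(df))

    def value(self, profile):
        return 1.0


class _Dummy:
    def __init__(self, column: str, level, label: str):
        self.column, self.level, self.label = column, level, label

    def rows(self, df):
        return (df[self.column] == self.level).to_numpy(dtype=float)

    def value(self, profile):
        if self.column not in profile:
            raise KeyError(f"profile is missing factor {self.column!r}")
        return 1.0 if profile[self.column] == self.level else 0.0


class _Weather:
    def __init__(self, var: str, part: int | None, basis: QuadBasis | None):
        self.var, self.part, self.basis = var, part, basis
        self.label = var if part is None else f"{var} ({part})"

    def rows(self, df):
        if self.var not in df.columns:
            raise KeyError(f"data is missing weather variable {self.var!r}")
        x = df[self.var].to_numpy(dtype=float)
        if self.part is None:
            return x
        return self.basis.transform(x)[self.part - 1]

    def value(self, profile):
        if self.var not in profile:
            raise KeyError(f"profile is missing weather variable {self.var!r}")
        x = float(profile[self.var])
        if self.part is None:
            return x
        return float(self.basis.transform(np.array([x]))[self.part - 1][0])


class _Product:
    def __init__(self, features, label: str):
        self.features, self.label = features, label

    def rows(self, df):
        out = np.ones(len(df))
        for f in self.features:
            out = out * f.rows(df)
        return out

    def value(self, profile):
        out = 1.0
        for f in self.features:
            out *= f.value(profile)
        return out


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class Group:
    """A droppable (or protected) block of design columns."""

    gid: str
    kind: str  # intercept | factor | weather | interaction
    parameter: str
    cols: tuple[int, ...]
    requires: frozenset[str]  # groups that must be removed before this one


class Design:
    """Numeric expansion of a weather-parameterized LEXP model.

    Holds the full design matrix of the maximal model, column features for
    prediction, and the term-group structure used by backward elimination.
    """

    def __init__(self, X, col_params, col_features, groups, r_fixed, n_col,
                 weather_ranges, factor_specs, index):
        self.X = X
        self.col_params = col_params          # LEXP parameter per column
        self.col_features = col_features      # feature object per column
        self.groups = groups                  # gid -> Group
        self.r_fixed = r_fixed
        self.n_col = n_col
        self.weather_ranges = weather_ranges  # var -> (min, max)
        self.factor_specs = factor_specs      # column name -> FactorSpec
        self.index = index

    @property
    def col_labels(self) -> list[str]:
        return [f"{p}:{f.label}" for p, f in zip(self.col_params, self.col_features)]

    def columns_for(self, active) -> np.ndarray:
        idx: list[int] = []
        for gid in active:
            idx.extend(self.groups[gid].cols)
        return np.array(sorted(idx), dtype=int)

    def droppable(self, active) -> list[str]:
        act = set(active)
        return sorted(
            gid
            for gid in act
            if self.groups[gid].kind != "intercept"
            and not (self.groups[gid].requires & act)
        )

    def all_groups(self) -> frozenset[str]:
        return frozenset(self.groups)


def build_maximal(
    data: pd.DataFrame,
    weather_vars: list[str],
    *,
    r_fixed: float,
    factors: tuple[FactorSpec, ...] = (),
    quadratic: tuple[str, ...] = (),
    interactions: tuple[InteractionSpec, ...] = (),
    weather_params: tuple[str, ...] = PARAMS,
    poly_mode: str = "orthogonal",
    n_col: str = "n_rate",
) -> Design:
    """Expand the maximal model into a design matrix.

    Every entry-ordered weather variable enters the parameter functions in
    ``weather_params`` (default: a, b and c); quadratic variables expand to
    a degree-2 pair labelled "(1)"/"(2)"; factors expand to first-level-zero
    dummies.  Raises on a rank-deficient design, naming offending columns.
    """
    if not (0 < r_fixed < 1):
        raise ValueError(f"r_fixed must be in (0, 1), got {r_fixed}")
    df = data.reset_index(drop=True)
    n = df[n_col].to_numpy(dtype=float)
    basis = {"a": np.ones(len(df)), "b": r_fixed ** n, "c": n}

    quadratic = tuple(quadratic)
    bases: dict[str, QuadBasis] = {}
    for var in quadratic:
        if var not in weather_vars:
            raise ValueError(f"quadratic variable {var!r} is not a model variable")
        bases[var] = QuadBasis(df[var], mode=poly_mode)

    factor_map = {f.column: f for f in factors}
    for f in factors:
        levels = set(df[f.column].unique())
        if f.baseline not in levels:
            raise ValueError(
                f"baseline level {f.baseline!r} absent from factor {f.column!r}"
            )

    cols: list[np.ndarray] = []
    col_params: list[str] = []
    col_features: list = []
    groups: dict[str, Group] = {}

    def add_column(param: str, feature) -> int:
        cols.append(basis[param] * feature.rows(df))
        col_params.append(param)
        col_features.append(feature)
        return len(cols) - 1

    def add_group(gid, kind, param, col_idx, requires=frozenset()):
        groups[gid] = Group(gid, kind, param, tuple(col_idx), frozenset(requires))

    # interactions referencing a covariate protect its main effect
    inter_on: dict[str, list[str]] = {}

    def inter_gids_for(name: str) -> list[str]:
        return inter_on.get(name, [])

    for p in PARAMS:
        j = add_column(p, _Intercept())
        add_group(f"{p}:Intercept", "intercept", p, [j])

    # pre-compute interaction group ids so main effects can reference them
    inter_plan = []
    for ispec in interactions:
        if ispec.factor not in factor_map:
            raise ValueError(f"interaction factor {ispec.factor!r} not a model factor")
        cov_is_factor = ispec.covariate in factor_map
        if not cov_is_factor and ispec.covariate not in weather_vars:
            raise ValueError(
                f"interaction covariate {ispec.covariate!r} not in the model"
            )
        parts = (1, 2) if (not cov_is_factor and ispec.covariate in quadratic) else (None,)
        for p in ispec.parameters:
            for part in parts:
                suffix = "" if part is None else f" ({part})"
                gid = f"{p}:{ispec.factor}×{ispec.covariate}{suffix}"
                inter_plan.append((gid, ispec, p, part, cov_is_factor))
                inter_on.setdefault(ispec.factor, []).append(gid)
                inter_on.setdefault(ispec.covariate, []).append(gid)

    for f in factors:
        levels = [l for l in sorted(df[f.column].unique()) if l != f.baseline]
        for p in f.parameters:
            idx = [add_column(p, _Dummy(f.column, lev, f.label(lev))) for lev in levels]
            add_group(f"{p}:{f.column}", "factor", p, idx,
                      requires=inter_gids_for(f.column))

    for var in weather_vars:
        if var not in df.columns:
            raise ValueError(f"weather variable {var!r} missing from data")
        for p in weather_params:
            if var in quadratic:
                j1 = add_column(p, _Weather(var, 1, bases[var]))
                j2 = add_column(p, _Weather(var, 2, bases[var]))
                gid2 = f"{p}:{var} (2)"
                add_group(gid2, "weather", p, [j2], requires=inter_gids_for(var))
                add_group(f"{p}:{var} (1)", "weather", p, [j1],
                          requires=set(inter_gids_for(var)) | {gid2})
            else:
                j = add_column(p, _Weather(var, None, None))
                add_group(f"{p}:{var}", "weather", p, [j],
                          requires=inter_gids_for(var))

    for gid, ispec, p, part, cov_is_factor in inter_plan:
        f = factor_map[ispec.factor]
        f_levels = [l for l in sorted(df[f.column].unique()) if l != f.baseline]
        idx = []
        if cov_is_factor:
            g = factor_map[ispec.covariate]
            g_levels = [l for l in sorted(df[g.column].unique()) if l != g.baseline]
            for lf in f_levels:
                for lg in g_levels:
                    feat = _Product(
                        [_Dummy(f.column, lf, f.label(lf)),
                         _Dummy(g.column, lg, g.label(lg))],
                        f"{f.label(lf)}: {g.label(lg)}",
                    )
                    idx.append(add_column(p, feat))
            requires: set[str] = set()
        else:
            wfeat_basis = bases.get(ispec.covariate)
            for lf in f_levels:
                w = _Weather(ispec.covariate, part, wfeat_basis)
                feat = _Product(
                    [_Dummy(f.column, lf, f.label(lf)), w],
                    f"{f.label(lf)}: {w.label}",
                )
                idx.append(add_column(p, feat))
            requires = set()
            if part == 1:
                requires.add(f"{p}:{ispec.factor}×{ispec.covariate} (2)")
        add_group(gid, "interaction", p, idx, requires=requires)

    X = np.column_stack(cols)
    _check_rank(X, [f"{p}:{f.label}" for p, f in zip(col_params, col_features)])
    ranges = {v: (float(df[v].min()), float(df[v].max())) for v in weather_vars}
    return Design(X, col_params, col_features, groups, r_fixed, n_col,
                  ranges, factor_map, df.index)


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    norms = np.linalg.norm(X, axis=0)
    zero = [labels[j] for j in np.nonzero(norms == 0)[0]]
    if zero:
        raise ValueError(f"rank-deficient design: all-zero columns {zero}")
    R = np.linalg.qr(X / norms, mode="r")
    diag = np.abs(np.diag(R))
    bad = [labels[j] for j in np.nonzero(diag < 1e-9 * diag.max())[0]]
    if bad:
        raise ValueError(f"rank-deficient design: offending columns {bad}")


# ---------------------------------------------------------------------------
# fitting and nested-model comparison


@dataclass
class LinearFitResult:
    """Exact OLS fit of a (sub)model of a Design."""

    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    rss: float
    df_resid: int
    n_obs: int
    k: int
    aic: float
    active: frozenset[str]
    col_idx: np.ndarray
    design: Design

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.labels, "estimate": self.beta, "se": self.se}
        )


def fit_linear(design: Design, y, active=None) -> LinearFitResult:
    """Ordinary least squares on the active columns of a design."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response")
    active = design.all_groups() if active is None else frozenset(active)
    idx = design.columns_for(active)
    X = design.X[:, idx]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    n_obs, k = X.shape
    if n_obs <= k:
        raise ValueError(f"need n_obs > n_columns ({n_obs} <= {k})")
    res = sm.OLS(y, X).fit()
    labels = [design.col_labels[j] for j in idx]
    return LinearFitResult(
        labels=labels,
        beta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        n_obs=n_obs,
        k=k,
        aic=aic(n_obs, float(res.ssr), k),
        active=active,
        col_idx=idx,
        design=design,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares partial F comparison of nested models."""

    fstat: float
    df1: int
    df2: int
    pvalue: float
    note: str = ""

    def __str__(self) -> str:
        if self.note:
            return self.note
        return f"(F({self.fstat:.3g}, {self.df1}, {self.df2}), P = {self.pvalue:.3f})"


def partial_f(rss_reduced: float, rss_full: float, df_reduced: int,
              df_full: int) -> ModelComparison:
    """F = ((RSS_r - RSS_f)/(df_r - df_f)) / (RSS_f / df_f), upper-tail p."""
    df1 = df_reduced - df_full
    if df1 <= 0 or df_full <= 0:
        raise ValueError("reduced model must have more residual df than full")
    F = max((rss_reduced - rss_full) / df1, 0.0) / (rss_full / df_full)
    p = float(stats.f.sf(F, df1, df_full))
    return ModelComparison(fstat=float(F), df1=int(df1), df2=int(df_full), pvalue=p)


def compare_models(full, reduced) -> ModelComparison:
    """Partial (marginal) F-test of a reduced model nested in a full one."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different data")
    if reduced.df_resid <= full.df_resid:
        raise ValueError("reduced model must be nested in (smaller than) full")
    if reduced.rss < full.rss - 1e-8 * (1.0 + full.rss):
        raise ValueError("non-nested models: reduced RSS below full RSS")
    return partial_f(reduced.rss, full.rss, reduced.df_resid, full.df_resid)


class _GramSolver:
    """Fast RSS for column subsets via the (normalized) Gram matrix.

    Columns are scaled to unit norm before forming X'X, which keeps raw
    polynomial bases well conditioned; a Cholesky failure falls back to a
    least-squares solve on the subset.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        self.Xn = X / norms
        self.y = np.asarray(y, dtype=float)
        self.G = self.Xn.T @ self.Xn
        self.h = self.Xn.T @ self.y
        self.yy = float(self.y @ self.y)

    def rss(self, idx: np.ndarray) -> float:
        G = self.G[np.ix_(idx, idx)]
        h = self.h[idx]
        try:
            cf = sla.cho_factor(G, lower=True, check_finite=False)
            beta = sla.cho_solve(cf, h, check_finite=False)
            rss = self.yy - float(h @ beta)
        except (np.linalg.LinAlgError, sla.LinAlgError, ValueError):
            beta, _, _, _ = np.linalg.lstsq(self.Xn[:, idx], self.y, rcond=None)
            resid = self.y - self.Xn[:, idx] @ beta
            rss = float(resid @ resid)
        return max(rss, 0.0)


@dataclass
class EliminationResult:
    active: frozenset[str]
    trace: pd.DataFrame
    fit: LinearFitResult


def backward_aic(design: Design, y, active=None) -> EliminationResult:
    """Backward elimination: drop the term-group whose removal most reduces
    AIC; stop when no removal reduces it.  The AIC trajectory is strictly
    decreasing by construction (asserted)."""
    y = np.asarray(y, dtype=float)
    solver = _GramSolver(design.X, y)
    act = set(design.all_groups() if active is None else active)
    n = len(y)
    idx = design.columns_for(act)
    aic_cur = aic(n, solver.rss(idx), len(idx))
    rows = []
    step = 0
    while True:
        best = None
        for gid in design.droppable(act):
            sub = design.columns_for(act - {gid})
            a2 = aic(n, solver.rss(sub), len(sub))
            if best is None or a2 < best[1]:
                best = (gid, a2)
        if best is None or best[1] >= aic_cur - 1e-9:
            break
        step += 1
        rows.append({"step": step, "removed": best[0],
                     "aic_before": aic_cur, "aic_after": best[1]})
        act.discard(best[0])
        aic_cur = best[1]
    trace = pd.DataFrame(rows, columns=["step", "removed", "aic_before", "aic_after"])
    if len(trace) > 1:
        assert (trace["aic_after"].to_numpy() < trace["aic_before"].to_numpy()).all()
    return EliminationResult(frozenset(act), trace, fit_linear(design, y, act))


def prune_partial_f(design: Design, y, active, alpha: float = 0.05) -> EliminationResult:
    """Marginal partial-F pruning: repeatedly drop the droppable term-group
    with the largest p-value >= alpha; stop when all droppable groups are
    significant (asserted on exit)."""
    y = np.asarray(y, dtype=float)
    solver = _GramSolver(design.X, y)
    act = set(active)
    n = len(y)
    rows = []
    step = 0
    while True:
        idx_f = design.columns_for(act)
        rss_f = solver.rss(idx_f)
        df_f = n - len(idx_f)
        worst = None
        for gid in design.droppable(act):
            sub = design.columns_for(act - {gid})
            cmp_ = partial_f(solver.rss(sub), rss_f, n - len(sub), df_f)
            if worst is None or cmp_.pvalue > worst[1].pvalue:
                worst = (gid, cmp_)
        if worst is None or worst[1].pvalue < alpha:
            break
        step += 1
        rows.append({"step": step, "removed": worst[0], "fstat": worst[1].fstat,
                     "df1": worst[1].df1, "df2": worst[1].df2,
                     "pvalue": worst[1].pvalue})
        act.discard(worst[0])
    # stopping condition: every remaining droppable group is significant
    idx_f = design.columns_for(act)
    rss_f = solver.rss(idx_f)
    df_f = n - len(idx_f)
    for gid in design.droppable(act):
        sub = design.columns_for(act - {gid})
        assert partial_f(solver.rss(sub), rss_f, n - len(sub), df_f).pvalue < alpha
    trace = pd.DataFrame(
        rows, columns=["step", "removed", "fstat", "df1", "df2", "pvalue"]
    )
    return EliminationResult(frozenset(act), trace, fit_linear(design, y, act))


@dataclass
class ValidationResult:
    comparison: ModelComparison
    aic_maximal: float
    aic_parsimonious: float


def validate_elimination(design: Design, y, maximal_active, parsimonious_active
                         ) -> ValidationResult:
    """Joint F-test of all terms eliminated between the maximal and the
    parsimonious model, reported alongside both AICs."""
    maximal_active = frozenset(maximal_active)
    parsimonious_active = frozenset(parsimonious_active)
    if not parsimonious_active <= maximal_active:
        raise ValueError("parsimonious model is not nested in the maximal model")
    full = fit_linear(design, y, maximal_active)
    if parsimonious_active == maximal_active:
        return ValidationResult(
            ModelComparison(float("nan"), 0, full.df_resid, float("nan"),
                            note="no terms eliminated"),
            full.aic, full.aic,
        )
    reduced = fit_linear(design, y, parsimonious_active)
    return ValidationResult(compare_models(full, reduced), full.aic, reduced.aic)


# ---------------------------------------------------------------------------
# outlier-year handling


def exclude_outlier_years(data: pd.DataFrame, years=None, *,
                          year_col: str = "harvest_year"):
    """Remove listed harvest years, returning (filtered data, audit log)."""
    years = sorted(set(years or []))
    audit = pd.DataFrame({"year": years, "reason": ["excluded by rule/config"] * len(years)})
    if not years:
        return data, audit
    mask = ~data[year_col].isin(years)
    if not mask.any():
        raise ValueError("exclusion would remove all years")
    for yr in years:
        logger.info("excluding harvest year %s", yr)
    return data[mask].reset_index(drop=True), audit


def flag_outlier_years(
    data: pd.DataFrame,
    variable: str,
    quad_coef_fn,
    *,
    quantile: float = 0.98,
    year_col: str = "harvest_year",
):
    """Flag years with extreme values of ``variable`` whose removal flips
    the sign of the fitted quadratic "(2)" coefficient.

    ``quad_coef_fn(data) -> float`` refits the model on a data subset and
    returns the quadratic coefficient of interest.  Returns (flagged years,
    audit table).
    """
    per_year = data.groupby(year_col)[variable].first()
    cutoff = per_year.quantile(quantile)
    candidates = per_year[per_year > cutoff].index.tolist()
    base = quad_coef_fn(data)
    flagged, rows = [], []
    for yr in candidates:
        coef = quad_coef_fn(data[data[year_col] != yr])
        flip = np.sign(coef) != np.sign(base) and coef != 0 and base != 0
        rows.append({"year": yr, "value": float(per_year[yr]),
                     "coef_with": base, "coef_without": coef, "flagged": bool(flip)})
        if flip:
            flagged.append(yr)
            logger.info("outlier year %s: removing it flips quadratic sign "
                        "(%.3g -> %.3g)", yr, base, coef)
    audit = pd.DataFrame(rows, columns=["year", "value", "coef_with",
                                        "coef_without", "flagged"])
    return flagged, audit


# ---------------------------------------------------------------------------
# fitted model bundle


class WeatherLEXPModel:
    """A fitted weather-parameterized LEXP model (sqrt-yield scale).

    Combines a Design with the OLS fit of one of its submodels, and maps a
    covariate profile (factor levels plus weather values) to the implied
    LEXP parameters (a, b, c) with the fixed r.
    """

    def __init__(self, design: Design, fit: LinearFitResult):
        if fit.design is not design:
            raise ValueError("fit does not belong to this design")
        self.design = design
        self.fit = fit

    @property
    def r(self) -> float:
        return self.design.r_fixed

    def weather_variables(self) -> list[str]:
        return sorted(self.design.weather_ranges)

    def parameter_values(self, profile) -> tuple[float, float, float]:
        """Evaluate a, b, c at a covariate profile.

        The profile maps every factor column to a level and every model
        weather variable to a value; a missing entry is an error.
        """
        acc = {"a": 0.0, "b": 0.0, "c": 0.0}
        for beta, j in zip(self.fit.beta, self.fit.col_idx):
            p = self.design.col_params[j]
            acc[p] += float(beta) * self.design.col_features[j].value(profile)
        return acc["a"], acc["b"], acc["c"]
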