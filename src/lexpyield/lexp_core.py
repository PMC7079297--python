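"""Linear-plus-exponential (LEXP) nitrogen-yield response curves.

The LEXP function describes grain yield as a function of applied nitrogen::

    y(N) = a + b * r**N + c * N

on the square-root yield scale, where ``a`` is the asymptote-related
intercept, ``b`` (typically negative) the amplitude of the below-optimum
response, ``c`` the linear supra-optimal slope per kg N ha^-1, and
``r`` (0 < r < 1) the curvature.  At ``N = 0`` the value is exactly
``a + b``; with ``c = 0`` and ``b < 0`` the curve rises monotonically
towards ``a``.

Fitting exploits conditional linearity: for any fixed ``r`` the model is
linear in all ``a``/``b``/``c`` coefficients (including per-group
coefficients), so estimation reduces to an exact least-squares solve.  When
``r`` is free it is profiled by one-dimensional minimization of the inner
residual sum of squares over ``r``, which reaches the same least-squares
optimum as a full joint Gauss-Newton iteration but is far more robust.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "LEXPParams",
    "SharingSpec",
    "FitResult",
    "lexp_eval",
    "optimum_n",
    "sqrt_transform",
    "back_transform",
    "fit_lexp",
]


@dataclass(frozen=True)
class LEXPParams:
    """Parameters of a single LEXP response curve on the sqrt-yield scale.

    a : asymptote-related intercept, sqrt(t ha-1)
    b : N-response amplitude, sqrt(t ha-1), typically negative
    c : supra-optimal slope, sqrt(t ha-1) per kg N ha-1
    r : curvature, dimensionless, 0 < r < 1 for a saturating response
    """

    a: float
    b: float
    c: float
    r: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "r"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"LEXP parameter {name!r} must be finite, got {v!r}")


def lexp_eval(params: LEXPParams, n_rate) -> np.ndarray | float:
    """Evaluate ``a + b * r**N + c * N`` at one or more N rates (kg N ha-1)."""
    if params.r <= 0:
        raise ValueError(f"LEXP parameter 'r' must be positive, got {params.r}")
    n = np.asarray(n_rate, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_rate must be non-negative")
    out = params.a + params.b * params.r ** n + params.c * n
    return float(out) if np.isscalar(n_rate) else out


def optimum_n(params: LEXPParams) -> float | None:
    """N rate maximizing the LEXP curve on [0, inf), or ``None``.

    Returns ``None`` when the curve is nondecreasing (no finite interior
    optimum, e.g. ``c >= 0`` with ``b < 0``).  With ``b < 0`` and ``c < 0``
    the unique stationary point solves ``b*ln(r)*r**N + c = 0``; when the
    derivative is already negative at N=0 the boundary maximum 0 is
    returned.
    """
    b, c, r = params.b, params.c, params.r
    if r >= 1 or r <= 0:
        raise ValueError(f"optimum_n requires 0 < r < 1, got r={r}")
    log_r = math.log(r)
    if b < 0:
        # derivative b*ln(r)*r^N + c decreases from b*ln(r)+c towards c
        if c >= 0:
            return None  # nondecreasing everywhere
        ratio = -c / (b * log_r)  # positive
        if ratio >= 1.0:
            return 0.0  # decreasing already at N=0
        return math.log(ratio) / log_r
    # b >= 0: derivative = b*ln(r)*r^N + c <= c
    if c > 0:
        return None  # grows without bound at large N
    if c == 0 and b == 0:
        return None  # constant curve, no unique maximizer
    return 0.0  # strictly decreasing (or initially flat then decreasing)


def sqrt_transform(y):
    """Square-root transform of yields (t ha-1), the scale used for all fits.

    The transform stabilizes the variance of yields, which increases with N
    rate in field data.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("yields must be non-negative for the sqrt transform")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(y) else out


def back_transform(v):
    """Square a sqrt-scale value back to t ha-1 (nonnegative by construction)."""
    arr = np.asarray(v, dtype=float)
    out = np.square(arr)
    return float(out) if np.isscalar(v) else out


@dataclass(frozen=True)
class SharingSpec:
    """How each LEXP parameter is shared across groups.

    Each of ``a``, ``b``, ``c``, ``r`` is either ``"common"`` (one estimate
    for the whole dataset) or the name of a grouping column in the data
    (one estimate per level, e.g. per harvest year or per mineral
    treatment).
    """

    a: str = "common"
    b: str = "common"
    c: str = "common"
    r: str = "common"

    def factors(self) -> set[str]:
        return {g for g in (self.a, self.b, self.c, self.r) if g != "common"}


@dataclass
class FitResult:
    """Result of a grouped LEXP least-squares fit on the sqrt-yield scale."""

    coefficients: pd.DataFrame  # columns: parameter, group, estimate, se
    r: float
    r_se: float | None
    r_estimated: bool
    rss: float
    df_resid: int
    n_obs: int
    n_params: int
    aic: float
    sharing: SharingSpec
    messages: list[str] = field(default_factory=list)

    def params(self) -> LEXPParams:
        """Return an LEXPParams when all of a, b, c are common."""
        coef = self.coefficients.set_index("parameter")["estimate"]
        if len(self.coefficients) != 3:
            raise ValueError("params() requires a fully common a/b/c fit")
        return LEXPParams(a=coef["a"], b=coef["b"], c=coef["c"], r=self.r)

    def coefficient(self, parameter: str, group: str = "common") -> float:
        sub = self.coefficients
        row = sub[(sub["parameter"] == parameter) & (sub["group"] == group)]
        if row.empty:
            raise KeyError(f"no coefficient for ({parameter}, {group})")
        return float(row["estimate"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        """Flat coefficient table (parameter, group, estimate, se) incl. r."""
        extra = pd.DataFrame(
            [{"parameter": "r", "group": "common" if self.r_estimated else "fixed",
              "estimate": self.r, "se": self.r_se}]
        )
        return pd.concat([self.coefficients, extra], ignore_index=True)


def _aic(n: int, rss: float, k: int) -> float:
    """AIC = n ln(RSS/n) + 2(k+1); the +1 counts the residual variance."""
    if rss <= 0:
        return -np.inf
    return n * math.log(rss / n) + 2 * (k + 1)


def _level_order(values: pd.Series) -> list:
    return sorted(pd.unique(values).tolist())


def _build_design(df: pd.DataFrame, sharing: SharingSpec, r: float,
                  n_col: str, labels_out: list | None = None) -> np.ndarray:
    n = df[n_col].to_numpy(dtype=float)
    basis = {"a": np.ones(len(df)), "b": r ** n, "c": n}
    cols = []
    for p in ("a", "b", "c"):
        grouping = getattr(sharing, p)
        if grouping == "common":
            cols.append(basis[p])
            if labels_out is not None:
                labels_out.append((p, "common"))
        else:
            levels = _level_order(df[grouping])
            for lev in levels:
                ind = (df[grouping] == lev).to_numpy()
                cols.append(basis[p] * ind)
                if labels_out is not None:
                    labels_out.append((p, f"{grouping}={lev}"))
    return np.column_stack(cols)


def _validate_groups(df: pd.DataFrame, sharing: SharingSpec, n_col: str,
                     r_estimated: bool, messages: list[str]) -> None:
    for factor in {getattr(sharing, p) for p in ("a", "b", "c")} - {"common"}:
        if factor not in df.columns:
            raise ValueError(f"grouping factor {factor!r} not present in data")
        varying = sum(getattr(sharing, p) == factor for p in ("a", "b", "c"))
        for lev, sub in df.groupby(factor):
            n_rates = sub[n_col].nunique()
            if n_rates < varying:
                raise ValueError(
                    f"group {factor}={lev} has {n_rates} distinct N rates but "
                    f"{varying} free parameters: singular design"
                )
            if n_rates == varying:
                messages.append(
                    f"group {factor}={lev} fitted with zero residual degrees "
                    f"of freedom ({n_rates} rates, {varying} free parameters)"
                )
    if r_estimated:
        free_common = sum(getattr(sharing, p) == "common" for p in ("a", "b", "c"))
        per_group = 3 - free_common
        total_rates = df[n_col].nunique()
        if total_rates <= max(per_group, free_common):
            raise ValueError(
                f"cannot estimate r: only {total_rates} distinct N rates for "
                f"{max(per_group, free_common)} free per-group parameters"
            )


def fit_lexp(
    data: pd.DataFrame,
    sharing: SharingSpec | None = None,
    r: float | None = None,
    *,
    n_col: str = "n_rate",
    y_col: str = "sqrt_yield",
    r_bounds: tuple[float, float] = (0.5, 0.9999),
    xatol: float = 1e-10,
) -> FitResult:
    """Fit the LEXP response by least squares on the sqrt-yield scale.

    Parameters
    ----------
    data
        Long table with at least ``n_col`` and ``y_col`` plus any grouping
        columns referenced by ``sharing``.
    sharing
        Which parameters are common vs per-group (default: all common).
    r
        Fix the nonlinear parameter at this value; ``None`` profiles it
        over ``r_bounds`` with exact inner linear solves.
    """
    sharing = sharing or SharingSpec()
    df = data.reset_index(drop=True)
    for col in (n_col, y_col):
        if col not in df.columns:
            raise ValueError(f"data is missing required column {col!r}")
    y = df[y_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(df[n_col])):
        raise ValueError("non-finite values in response or N rates")

    messages: list[str] = []
    r_estimated = r is None

    if sharing.r != "common":
        return _fit_r_by_group(df, sharing, r, n_col=n_col, y_col=y_col,
                               r_bounds=r_bounds, xatol=xatol)

    _validate_groups(df, sharing, n_col, r_estimated, messages)

    def solve(r_val: float):
        X = _build_design(df, sharing, r_val, n_col)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError(
                "singular design matrix: a group has too few distinct N rates "
                "for its free parameters"
            )
        resid = y - X @ beta
        return float(resid @ resid), beta, X

    if r_estimated:
        lo, hi = r_bounds
        res = minimize_scalar(lambda rv: solve(rv)[0], bounds=(lo, hi),
                              method="bounded", options={"xatol": xatol})
        r_hat = float(res.x)
    else:
        if not (0 < r):
            raise ValueError(f"fixed r must be positive, got {r}")
        r_hat = float(r)

    rss, beta, X = solve(r_hat)
    labels: list[tuple[str, str]] = []
    _build_design(df, sharing, r_hat, n_col, labels_out=labels)

    k = X.shape[1] + (1 if r_estimated else 0)
    n_obs = len(df)
    if n_obs <= k:
        raise ValueError(f"need more than {k} observations, got {n_obs}")
    df_resid = n_obs - k

    # Jacobian-based covariance sigma^2 (J'J)^-1 at the optimum
    J = X
    if r_estimated:
        n_arr = df[n_col].to_numpy(dtype=float)
        b_part = np.zeros(n_obs)
        for j, (p, _) in enumerate(labels):
            if p == "b":
                b_part += X[:, j] * beta[j]  # = r^N * indicator * b_coef
        with np.errstate(divide="ignore", invalid="ignore"):
            dcol = np.where(n_arr > 0, b_part * n_arr / r_hat, 0.0)
        J = np.column_stack([X, dcol])
    sigma2 = rss / df_resid if df_resid > 0 else 0.0
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = np.full(J.shape[1], np.nan)

    coef_rows = [
        {"parameter": p, "group": g, "estimate": float(beta[j]), "se": float(ses[j])}
        for j, (p, g) in enumerate(labels)
    ]
    r_se = float(ses[-1]) if r_estimated else None

    for m in messages:
        logger.info(m)
    return FitResult(
        coefficients=pd.DataFrame(coef_rows),
        r=r_hat,
        r_se=r_se,
        r_estimated=r_estimated,
        rss=rss,
        df_resid=df_resid,
        n_obs=n_obs,
        n_params=k,
        aic=_aic(n_obs, rss, k),
        sharing=sharing,
        messages=messages,
    )


def _fit_r_by_group(df, sharing, r, *, n_col, y_col, r_bounds, xatol) -> FitResult:
    """Fit with r varying by a factor: independent per-level profile fits.

    Only supported when a, b and c also vary by (at least) the same factor,
    so the levels are statistically independent and the combined fit is the
    concatenation of per-level fits.
    """
    factor = sharing.r
    if factor not in df.columns:
        raise ValueError(f"grouping factor {factor!r} not present in data")
    for p in ("a", "b", "c"):
        if getattr(sharing, p) == "common":
            raise ValueError(
                f"r varying by {factor!r} requires a, b and c to vary too "
                "(independent per-level fits); got a common parameter"
            )
    sub_sharing = SharingSpec(
        a="common" if sharing.a == factor else sharing.a,
        b="common" if sharing.b == factor else sharing.b,
        c="common" if sharing.c == factor else sharing.c,
        r="common",
    )
    frames, messages = [], []
    rss = 0.0
    k = 0
    n_obs = 0
    for lev, sub in df.groupby(factor):
        fit = fit_lexp(sub, sub_sharing, r, n_col=n_col, y_col=y_col,
                       r_bounds=r_bounds, xatol=xatol)
        part = fit.to_frame()
        part["group"] = part["group"].radd(f"{factor}={lev}; ")
        frames.append(part)
        rss += fit.rss
        k += fit.n_params
        n_obs += fit.n_obs
        messages.extend(fit.messages)
    coef = pd.concat(frames, ignore_index=True)
    return FitResult(
        coefficients=coef.reset_index(drop=True),
        r=float("nan"),
        r_se=None,
        r_estimated=r is None,
        rss=rss,
        df_resid=n_obs - k,
        n_obs=n_obs,
        n_params=k,
        aic=_aic(n_obs, rss, k),
        sharing=sharing,
        messages=messages,
    )
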