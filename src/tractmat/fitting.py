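"""Vertexwise linear and exponential age-trajectory fitting.

At every surface vertex, each sex group's FA (or MD) values are regressed
on age with two competing mean models:

* linear:       y = b + a * age
* exponential:  y = C + A * exp(-age / t)

The exponential model captures the canonical maturation shape — rapid
change in childhood levelling off toward an adult asymptote ``C`` with
e-folding time constant ``t`` (years).  ``A < 0`` means the measure rises
with age (FA), ``A > 0`` that it falls (MD).

Each fit carries an F statistic against the constant-mean null, the
correlation-style goodness-of-fit ``r``, and AIC for model comparison.
The exponential model is linear in (C, A) given t, so it is fitted by a
grid over t with conditional linear least squares, then polished by
bounded nonlinear least squares — a scheme that is globally reliable and
easy to cross-check against a fine-grid profile search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LinearFit",
    "ExpFit",
    "fit_linear",
    "fit_exponential",
    "f_test",
    "aic",
    "fit_vertexwise",
]

#: coarse grid over the exponential time constant (years)
T_GRID = np.arange(0.5, 50.0 + 1e-9, 0.5)
T_MAX = 1000.0
REFINE_FTOL = 1e-10
REFINE_MAX_ITER = 500


class DegenerateDesignError(ValueError):
    """Raised when the ages carry no variance."""


def f_test(sse_model: float, sst: float, n_params: int, n: int) -> tuple[float, float]:
    """F test of a fitted mean model against the constant-mean null.

    ``F = ((sst - sse)/(k - 1)) / (sse/(n - k))`` with ``k`` mean-function
    parameters, referred to an F(k-1, n-k) distribution.  Flat data
    (``sst = 0``) gives ``p = 1`` by convention.
    """
    if n <= n_params:
        raise ValueError("need n > n_params for an F test")
    if sst <= 0:
        return 0.0, 1.0
    df1, df2 = n_params - 1, n - n_params
    if sse_model <= 0:
        return np.inf, 0.0
    f = ((sst - sse_model) / df1) / (sse_model / df2)
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, df1, df2))


def aic(sse: float, n: int, k_mean_params: int) -> float:
    """Akaike information criterion ``n ln(sse/n) + 2 (k + 1)``.

    The residual variance counts as one estimated parameter on top of the
    ``k_mean_params`` mean-function parameters (3 total for the linear
    model, 4 for the exponential).  A perfect fit returns ``-inf``, which
    still compares correctly.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse <= 0:
        return -np.inf
    return n * np.log(sse / n) + 2.0 * (k_mean_params + 1)


@dataclass
class LinearFit:
    """OLS fit of y = b + a*age with its test statistics."""

    b: float
    a: float
    se_b: float
    se_a: float
    sse: float
    sst: float
    r: float
    f_stat: float
    p_value: float
    aic: float
    n: int

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return self.b + self.a * np.asarray(ages, dtype=float)


@dataclass
class ExpFit:
    """Nonlinear fit of y = C + A*exp(-age/t) with its test statistics."""

    C: float
    A: float
    t: float
    se_C: float
    se_A: float
    se_t: float
    sse: float
    sst: float
    r: float
    f_stat: float
    p_value: float
    aic: float
    converged: bool
    n: int

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return self.C + self.A * np.exp(-np.asarray(ages, dtype=float) / self.t)


def _clean(ages, y) -> tuple[np.ndarray, np.ndarray]:
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(ages) | np.isnan(y))
    return ages[keep], y[keep]


def fit_linear(ages: np.ndarray, y: np.ndarray) -> LinearFit | None:
    """Ordinary least squares via the normal equations.

    Returns None when fewer than 3 complete pairs remain (the vertex is
    unfit-able); raises :class:`DegenerateDesignError` on zero age variance.
    """
    ages, y = _clean(ages, y)
    n = ages.size
    if n < 3:
        return None
    sxx = np.sum((ages - ages.mean()) ** 2)
    if sxx <= 0:
        raise DegenerateDesignError("ages carry no variance")
    a = np.sum((ages - ages.mean()) * (y - y.mean())) / sxx
    b = y.mean() - a * ages.mean()
    resid = y - (b + a * ages)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = sse / (n - 2)
    se_a = float(np.sqrt(sigma2 / sxx))
    se_b = float(np.sqrt(sigma2 * (1.0 / n + ages.mean() ** 2 / sxx)))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r = float(np.sign(a) * np.sqrt(max(r2, 0.0)))
    f, p = f_test(sse, sst, 2, n)
    return LinearFit(
        b=float(b), a=float(a), se_b=se_b, se_a=se_a, sse=sse, sst=sst,
        r=r, f_stat=f, p_value=p, aic=aic(sse, n, 2), n=n,
    )


def _conditional_linear(ages: np.ndarray, y: np.ndarray, t: float) -> tuple[float, float, float]:
    """Solve min over (C, A) of ||y - C - A exp(-age/t)||²; returns (C, A, sse)."""
    x = np.exp(-ages / t)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def exp_sse_profile(ages: np.ndarray, y: np.ndarray, t_values: np.ndarray) -> np.ndarray:
    """SSE of the conditional-linear exponential fit at each trial ``t``."""
    return np.array([_conditional_linear(ages, y, t)[2] for t in t_values])


def fit_exponential(ages: np.ndarray, y: np.ndarray) -> ExpFit | None:
    """Two-stage exponential fit: coarse grid over t, then bounded polish.

    Stage 1 evaluates the conditional-linear SSE on a t grid (0.5 .. 50 in
    steps of 0.5).  Stage 2 refines (C, A, t) by trust-region nonlinear
    least squares from the best grid point, with t bounded in (0, 1000] and
    a relative-SSE tolerance of 1e-10.  ``converged=False`` flags fits that
    ran into the t bound or exhausted the iteration budget — typically
    near-linear data, where the caller falls back to the linear model.

    Standard errors come from the Gauss–Newton covariance
    ``sse/(n-3) * (JᵀJ)⁻¹``.  Returns None for fewer than 4 complete pairs
    or a singular conditional system.
    """
    ages, y = _clean(ages, y)
    n = ages.size
    if n < 4:
        return None
    if np.sum((ages - ages.mean()) ** 2) <= 0:
        raise DegenerateDesignError("ages carry no variance")
    sse_grid = exp_sse_profile(ages, y, T_GRID)
    t0 = float(T_GRID[int(np.argmin(sse_grid))])
    c0, a0, _ = _conditional_linear(ages, y, t0)

    def resid(theta):
        c, a, t = theta
        return y - (c + a * np.exp(-ages / t))

    sol = optimize.least_squares(
        resid,
        x0=[c0, a0, t0],
        bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, T_MAX]),
        method="trf",
        ftol=REFINE_FTOL,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=REFINE_MAX_ITER,
    )
    c, a, t = (float(v) for v in sol.x)
    sse = float(2.0 * sol.cost)
    converged = bool(sol.status > 0 and sol.status != 0) and t < T_MAX * (1 - 1e-6)
    sst = float(np.sum((y - y.mean()) ** 2))
    # Gauss-Newton covariance
    x = np.exp(-ages / t)
    jac = np.column_stack([np.ones(n), x, a * x * ages / t**2])
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (sse / (n - 3) if n > 3 else np.nan)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    f, p = f_test(sse, sst, 3, n)
    return ExpFit(
        C=c, A=a, t=t, se_C=float(ses[0]), se_A=float(ses[1]), se_t=float(ses[2]),
        sse=sse, sst=sst, r=float(np.sqrt(max(r2, 0.0))), f_stat=f, p_value=p,
        aic=aic(sse, n, 3), converged=converged, n=n,
    )


def fit_vertexwise(
    measures,
    subjects: pd.DataFrame,
    measure: str = "fa",
    min_group_fraction: float = 0.8,
) -> pd.DataFrame:
    """Fit both models at every vertex, separately for each sex group.

    ``measures`` is a :class:`~tractmat.projection.VertexMeasureSet`;
    ``subjects`` needs ``id``, ``age`` and ``sex`` columns aligned with the
    measure rows.  Missing subjects are dropped listwise per vertex;
    vertices retaining fewer than ``min_group_fraction`` of a sex group are
    flagged ``low_n`` in the output (fits are still attempted).

    Returns one row per (vertex, sex) with linear (``lin_*``) and
    exponential (``exp_*``) columns; unfit-able vertices carry NaN.
    """
    values = getattr(measures, measure)
    subjects = subjects.copy()
    subjects["id"] = subjects["id"].astype(str)
    order = {s: k for k, s in enumerate(measures.subject_ids)}
    if not set(subjects["id"]) <= set(order):
        raise ValueError("subject table contains ids without measures")
    rows = []
    for sex, grp in subjects.groupby("sex", sort=True):
        idx = grp["id"].map(order).to_numpy()
        ages = grp["age"].to_numpy(dtype=float)
        group_n = len(grp)
        for v in range(measures.n_vertices):
            y = values[idx, v]
            n_used = int(np.isfinite(y).sum())
            rec = {
                "vertex_id": v, "sex": sex, "measure": measure,
                "n_group": group_n, "low_n": n_used < min_group_fraction * group_n,
            }
            lin = fit_linear(ages, y) if n_used >= 3 else None
            exp = fit_exponential(ages, y) if n_used >= 4 else None
            if lin is not None:
                rec.update(
                    lin_b=lin.b, lin_a=lin.a, lin_se_a=lin.se_a, lin_sse=lin.sse,
                    lin_r=lin.r, lin_f=lin.f_stat, lin_p=lin.p_value,
                    lin_aic=lin.aic, lin_n=lin.n,
                )
            if exp is not None:
                rec.update(
                    exp_C=exp.C, exp_A=exp.A, exp_t=exp.t, exp_se_C=exp.se_C,
                    exp_se_A=exp.se_A, exp_se_t=exp.se_t, exp_sse=exp.sse,
                    exp_r=exp.r, exp_f=exp.f_stat, exp_p=exp.p_value,
                    exp_aic=exp.aic, exp_converged=exp.converged, exp_n=exp.n,
                )
            rows.append(rec)
    return pd.DataFrame(rows)
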