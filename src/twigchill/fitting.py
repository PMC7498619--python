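"""Model fitting: the exponential chilling-forcing law and the logarithmic
critical-forcing (GDDcrit) model.

The central relationship is

    forcing = a + b * exp(c * chilling) + eps,    b >= 0, c < 0

i.e. the forcing needed to reach a developmental stage decays exponentially
toward the asymptote ``a`` as chilling accumulates.  The nonlinear fit is
made robust by profiling: for each candidate ``c`` on a log-spaced negative
grid the conditionally linear pair (a, b) has a closed-form least-squares
solution, and the best grid point seeds a full Levenberg-Marquardt
refinement.

The simulator's model is linear in ln(chilling):

    GDDcrit = a_log + b_log * ln(CD)

fit by ordinary least squares (zero-chill rows must be dropped first).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

from .types import ExpFit, LogFit

__all__ = ["fit_exponential", "fit_table", "predict_forcing", "fit_log_model"]

#: Default profiling grid for c: 40 log-spaced values in [-1, -1e-4]
#: (chilling measured in days).
DEFAULT_C_GRID: np.ndarray = -np.logspace(0, -4, 40)


def _profile_ab(chill: np.ndarray, forcing: np.ndarray, c_grid: np.ndarray):
    """Closed-form (a, b) and SSE for every candidate c.  Vectorised.

    For fixed c the model is linear: f = a + b * e, e = exp(c * x).  The
    2x2 normal equations are solved for all grid points at once.
    """
    n = len(chill)
    E = np.exp(np.outer(c_grid, chill))  # (g, n)
    Se = E.sum(axis=1)
    See = (E * E).sum(axis=1)
    Sf = forcing.sum()
    Sef = E @ forcing
    det = n * See - Se**2
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    a = (See * Sf - Se * Sef) / det
    b = (n * Sef - Se * Sf) / det
    resid = forcing[None, :] - a[:, None] - b[:, None] * E
    sse = np.einsum("ij,ij->i", resid, resid)
    return a, b, sse


def fit_exponential(
    chilling: Sequence[float],
    forcing: Sequence[float],
    c_grid: Optional[np.ndarray] = None,
    ftol: float = 1e-10,
    max_nfev: int = 200,
    refine: bool = True,
) -> ExpFit:
    """Nonlinear least-squares fit of forcing = a + b*exp(c*chilling).

    Requires at least 4 distinct chilling values (three parameters plus one
    residual degree of freedom).  Non-convergence is reported on the
    returned :class:`ExpFit`, never silently accepted.
    """
    x = np.asarray(chilling, dtype=float)
    y = np.asarray(forcing, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("chilling and forcing must be 1-D and equal length")
    if len(np.unique(x)) < 4:
        raise ValueError(
            f"need >= 4 distinct chilling values, got {len(np.unique(x))}"
        )
    grid = DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid)

    a_g, b_g, sse_g = _profile_ab(x, y, grid)
    ok = ~np.isnan(sse_g)
    if not ok.any():
        return ExpFit(np.nan, np.nan, np.nan, np.nan, len(x), False,
                      message="singular profiling design")
    best = np.flatnonzero(ok)[np.argmin(sse_g[ok])]
    a0, b0, c0 = a_g[best], b_g[best], grid[best]

    if not refine:
        dof = max(len(x) - 3, 1)
        return ExpFit(float(a0), float(b0), float(c0),
                      float(np.sqrt(sse_g[best] / dof)), len(x), True,
                      message="grid-profile fit (no refinement)")

    def resid(p):
        return p[0] + p[1] * np.exp(p[2] * x) - y

    def jac(p):
        e = np.exp(p[2] * x)
        return np.column_stack([np.ones_like(x), e, p[1] * x * e])

    sol = scipy.optimize.least_squares(
        resid, x0=[a0, b0, c0], jac=jac, method="lm", ftol=ftol, xtol=ftol,
        gtol=ftol, max_nfev=max_nfev,
    )
    converged = bool(sol.status > 0) and np.all(np.isfinite(sol.x))
    dof = max(len(x) - 3, 1)
    sse = float(2 * sol.cost)
    residual_sd = float(np.sqrt(sse / dof))
    cov = None
    if converged:
        J = jac(sol.x)
        JtJ = J.T @ J
        try:
            cov = np.linalg.inv(JtJ) * (sse / dof)
        except np.linalg.LinAlgError:
            cov = None
    return ExpFit(
        float(sol.x[0]), float(sol.x[1]), float(sol.x[2]), residual_sd,
        len(x), converged, covariance=cov, message=sol.message,
    )


def fit_table(
    table: pd.DataFrame,
    endpoint: str = "bbch7",
    treatment: Optional[str] = "S",
    definition: str = "calendar",
    exclude_outliers: bool = True,
    **kwargs,
) -> ExpFit:
    """Fit the exponential law to one (endpoint, treatment, definition) slice.

    ``treatment=None`` pools S and C rows.  Rows flagged ``excluded`` are
    dropped when ``exclude_outliers`` is on.
    """
    sel = table["endpoint"] == endpoint
    if treatment is not None:
        sel &= table["treatment"] == treatment
    if exclude_outliers:
        sel &= ~table["excluded"]
    sub = table.loc[sel]
    return fit_exponential(sub[f"chill_{definition}"], sub[f"force_{definition}"], **kwargs)


def predict_forcing(fit: ExpFit, chilling) -> np.ndarray:
    """Evaluate a + b*exp(c*chilling) on a value or grid."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    x = np.asarray(chilling, dtype=float)
    return fit.a + fit.b * np.exp(fit.c * x)


def fit_log_model(
    cd: Sequence[float],
    gdd: Sequence[float],
    cd_threshold: float = 5.0,
    gdd_threshold: float = 5.0,
) -> LogFit:
    """OLS fit of the critical-forcing model GDDcrit = a + b * ln(CD)."""
    x = np.asarray(cd, dtype=float)
    y = np.asarray(gdd, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "all CD values must be > 0 for the log model; "
            "drop zero-chill rows before fitting"
        )
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct CD values")
    X = sm.add_constant(np.log(x))
    res = sm.OLS(y, X).fit()
    return LogFit(
        a_log=float(res.params[0]),
        b_log=float(res.params[1]),
        cd_threshold=cd_threshold,
        gdd_threshold=gdd_threshold,
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        n_rows=len(x),
    )
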