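"""Cubic time-course modelling of per-well object trajectories.

Each well contributes one series per object: the mean over its available
technical replicates (imaged quadrants) at every timepoint.  The series,
or the pool of all series of a cell line, is fitted with the third-degree
polynomial

    y_i = b0 + b1 t_i + b2 t_i^2 + b3 t_i^3 + e_i

under three estimators of increasing outlier resistance:

* ``ols``      — ordinary least squares (conditional mean);
* ``robust``   — bisquare M-estimation tuned to 90% efficiency at the
  normal model (tuning constant c = 3.8827), started from the median
  regression with a MAD residual scale held fixed;
* ``quantile`` — median (tau = 0.5) regression, solved as a linear
  program (conditional median).

A cubic keeps the parameter count low while following the one-peak or
one-trough shapes that transient network formation produces; the three
estimators agree on clean data and diverge only under outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

#: Bisquare tuning constant giving 90% asymptotic efficiency under
#: Gaussian errors.
BISQUARE_C90 = 3.8827

ESTIMATORS = ("ols", "robust", "quantile")


class FitError(ValueError):
    """Raised for rank-deficient designs or unusable inputs."""


class ConvergenceError(RuntimeError):
    """Robust IRLS failed to converge; carries the iteration count."""

    def __init__(self, n_iter: int):
        super().__init__(f"robust IRLS did not converge after {n_iter} iterations")
        self.n_iter = n_iter


@dataclass
class PolynomialFit:
    """A fitted cubic with estimator provenance."""

    beta: np.ndarray                  # (b0, b1, b2, b3)
    estimator: str
    window: tuple[float, float]
    residual_scale: float
    n: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,) or not np.all(np.isfinite(self.beta)):
            raise FitError("beta must be four finite coefficients")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to well-level series.

    Returns one row per (cell_line, well, object, time_h) holding the
    arithmetic mean over whatever quadrants are present; timepoints with
    no quadrant at all are simply absent.
    """
    required = {"cell_line", "well", "quadrant", "time_h", "object", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    out = (table.groupby(["cell_line", "well", "object", "time_h"], sort=True)["value"]
           .mean().reset_index())
    return out


def _design(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.vander(t, 4, increasing=True)


def _check_series(t: np.ndarray, y: np.ndarray, estimator: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitError("t and y must be 1D arrays of equal length")
    if np.unique(t).size < 4:
        raise FitError("a cubic fit needs at least 4 distinct timepoints")
    return t, y


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _quantile_lp(X: np.ndarray, y: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Quantile regression as the standard LP: split residuals into
    positive/negative parts, minimise their tau-weighted sum."""
    n, p = X.shape
    c = np.concatenate([np.zeros(2 * p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    bounds = [(0, None)] * (2 * p + 2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is reliable on these LPs
        raise FitError(f"quantile LP failed: {res.message}")
    return res.x[:p] - res.x[p:2 * p]


def _bisquare_weights(u: np.ndarray, c: float) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < c
    w[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return w


def _robust_mm(X: np.ndarray, y: np.ndarray, c: float = BISQUARE_C90,
               max_iter: int = 500, tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Bisquare IRLS with a high-breakdown start.

    The initial fit is the median regression; the residual scale is the
    normalised MAD of its residuals and is held fixed during the
    M-iterations (redescending psi with an estimated scale can otherwise
    implode on leverage points).
    """
    beta = _quantile_lp(X, y)
    resid = y - X @ beta
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale <= 1e-12 * max(1.0, float(np.max(np.abs(y), initial=0.0))):
        return beta, 0.0  # (near-)exact fit already
    for _ in range(max_iter):
        w = _bisquare_weights(resid / scale, c)
        if np.count_nonzero(w) < X.shape[1]:
            w = np.maximum(w, 1e-8)  # tie-break: keep the system determined
        sw = np.sqrt(w)
        beta_new = _ols(X * sw[:, None], y * sw)
        if np.max(np.abs(beta_new - beta)) <= tol * (1.0 + np.max(np.abs(beta))):
            return beta_new, scale
        beta = beta_new
        resid = y - X @ beta
    raise ConvergenceError(max_iter)


def fit_cubic(t: np.ndarray, y: np.ndarray, estimator: str = "ols",
              max_iter: int = 500) -> PolynomialFit:
    """Fit the cubic trajectory model to one series.

    ``t`` need not be sorted; duplicated timepoints are allowed as long as
    at least four distinct values support the cubic design.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    t, y = _check_series(t, y, estimator)
    X = _design(t)
    if np.linalg.matrix_rank(X) < 4:
        raise FitError("rank-deficient cubic design")
    if estimator == "ols":
        beta = _ols(X, y)
        scale = float(np.sqrt(np.mean((y - X @ beta) ** 2)))
    elif estimator == "quantile":
        beta = _quantile_lp(X, y)
        resid = y - X @ beta
        scale = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    else:
        beta, scale = _robust_mm(X, y, max_iter=max_iter)
    return PolynomialFit(beta=beta, estimator=estimator,
                         window=(float(np.min(t)), float(np.max(t))),
                         residual_scale=float(scale), n=len(t))


def evaluate(fit: PolynomialFit, t) -> np.ndarray:
    """Evaluate the fitted cubic at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    b = fit.beta
    return b[0] + b[1] * t + b[2] * t**2 + b[3] * t**3


def extrema(fit: PolynomialFit, window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Attained (max, min) of the fitted cubic on a closed window.

    Exact: candidates are the window endpoints plus the real roots of the
    derivative quadratic inside the window.
    """
    lo, hi = window if window is not None else fit.window
    if not lo <= hi:
        raise ValueError("window must satisfy lo <= hi")
    b = fit.beta
    candidates = [lo, hi]
    # g'(t) = b1 + 2 b2 t + 3 b3 t^2; a relative threshold keeps a floating-
    # point-zero leading coefficient from swamping the lower-degree roots
    a2, a1, a0 = 3.0 * b[3], 2.0 * b[2], b[1]
    scale = max(abs(a2), abs(a1), abs(a0))
    if scale > 0 and abs(a2) > 1e-12 * scale:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc >= 0:
            # cancellation-stable quadratic roots
            q = -0.5 * (a1 + math.copysign(math.sqrt(disc), a1 if a1 != 0 else 1.0))
            roots = [q / a2] + ([a0 / q] if q != 0 else [-a1 / a2])
            for r in roots:
                if lo < r < hi:
                    candidates.append(r)
    elif scale > 0 and abs(a1) > 1e-12 * scale:
        r = -a0 / a1
        if lo < r < hi:
            candidates.append(r)
    vals = evaluate(fit, np.asarray(candidates))
    return float(np.max(vals)), float(np.min(vals))


def pooled_fits(well_table: pd.DataFrame, estimator: str = "ols",
                time_col: str = "time_h", value_col: str = "value",
                ) -> dict[tuple[str, str], PolynomialFit]:
    """One pooled cubic per (cell_line, object) over all wells.

    Pooling wells into a single fit follows the scoring model, where one
    curve per cell line enters the discrepancy integral; per-well fits
    remain available through :func:`fit_cubic` for diagnostics.
    """
    fits: dict[tuple[str, str], PolynomialFit] = {}
    for (line, obj), grp in well_table.groupby(["cell_line", "object"], sort=True):
        fits[(line, obj)] = fit_cubic(grp[time_col].to_numpy(),
                                      grp[value_col].to_numpy(), estimator=estimator)
    return fits
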