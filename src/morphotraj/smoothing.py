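"""Penalized cubic B-spline smoother with GCV smoothing selection.

Stand-in for a generalized additive model with a single smooth term:
the basis is cubic B-splines on quantile knots, the penalty is a
second-order difference on the coefficients (null space = linear
functions), the smoothing parameter minimises generalized
cross-validation, and significance of the smooth is a Wald/F-type test
against the constant fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import f as f_dist


@dataclass
class SmoothFit:
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    lam: float
    edf: float  # trace(hat) - 1: degrees of freedom beyond the intercept
    p_value: float  # approximate significance of the smooth vs constant
    _knots: np.ndarray = None
    _coef: np.ndarray = None

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        if self._knots is None:  # degenerate linear fit
            return self._coef[0] + self._coef[1] * x_new
        B = _design(x_new, self._knots)
        return B @ self._coef


def _knot_vector(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Cubic B-spline knot vector with interior knots at quantiles of x."""
    degree = 3
    n_interior = n_basis - degree - 1
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    degree = 3
    n_basis = len(knots) - degree - 1
    xc = np.clip(x, knots[0], knots[-1])
    cols = [
        BSpline.basis_element(knots[j : j + degree + 2], extrapolate=False)(xc)
        for j in range(n_basis)
    ]
    B = np.nan_to_num(np.asarray(cols).T)
    # basis_element drops the right endpoint of the last interval
    at_end = xc == knots[-1]
    if np.any(at_end):
        B[at_end, -1] = 1.0
    return B


def smooth_trend(
    x: np.ndarray,
    y: np.ndarray,
    n_basis: int = 10,
    lambdas: np.ndarray | None = None,
) -> SmoothFit:
    """Fit a penalized spline trend to (x, y) with GCV-selected smoothing.

    Returns fitted values, a 95% confidence band and an approximate
    F-test of the smooth against the constant fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if n_basis > n - 2:
        warnings.warn(
            f"reducing basis from {n_basis} to {max(4, n - 2)} for n={n}", stacklevel=2
        )
        n_basis = max(4, n - 2)
    n_unique = len(np.unique(x))
    if n_basis > n_unique:
        n_basis = max(4, n_unique)

    # A (numerically) exact linear fit is the infinite-smoothing limit of the
    # second-difference penalty; short-circuit to it rather than chasing the
    # ill-conditioned large-lambda regime.
    tss = float(((y - y.mean()) ** 2).sum())
    A_lin = np.column_stack([np.ones(n), x])
    beta_lin, *_ = np.linalg.lstsq(A_lin, y, rcond=None)
    fit_lin = A_lin @ beta_lin
    rss_lin = float(((y - fit_lin) ** 2).sum())
    if rss_lin <= 1e-12 * max(tss, 1e-300) or tss == 0.0:
        df2 = max(n - 2.0, 1e-6)
        if tss <= 1e-300 or rss_lin >= tss:
            p = 1.0
        elif rss_lin <= 1e-300:
            p = 0.0
        else:
            p = float(f_dist.sf((tss - rss_lin) / (rss_lin / df2), 1.0, df2))
        cov = rss_lin / df2 * np.linalg.inv(A_lin.T @ A_lin)
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A_lin, cov, A_lin), 0.0))
        return SmoothFit(
            x=x, y=y, fitted=fit_lin,
            band_lower=fit_lin - 1.96 * se, band_upper=fit_lin + 1.96 * se,
            lam=np.inf, edf=1.0, p_value=p, _knots=None, _coef=beta_lin,
        )

    knots = _knot_vector(x, n_basis)
    B = _design(x, knots)
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y

    if lambdas is None:
        lambdas = np.logspace(-8, 10, 55)

    best = None
    for lam in lambdas:
        try:
            A = np.linalg.solve(BtB + lam * P, np.column_stack([Bty, B.T]))
        except np.linalg.LinAlgError:
            continue
        coef = A[:, 0]
        fitted = B @ coef
        tr = float(np.einsum("ij,ji->", B, A[:, 1:]))
        rss = float(((y - fitted) ** 2).sum())
        denom = max(n - tr, 1e-8)
        gcv = n * rss / denom**2
        if rss <= 1e-14 * max(tss, 1e-300):  # numerically exact fit
            gcv = 0.0
        # ties (e.g. an exact fit at every lambda) resolve to the smoothest fit
        if best is None or gcv <= best[0] * (1.0 + 1e-9) + 1e-300:
            best = (gcv, lam, coef, fitted, tr, rss)

    if best is None:
        raise np.linalg.LinAlgError("penalized system singular for all lambdas")
    _, lam, coef, fitted, tr, rss1 = best

    # F-type test of the smooth against the constant fit.
    rss0 = float(((y - y.mean()) ** 2).sum())
    df1 = max(tr - 1.0, 1e-6)
    df2 = max(n - tr, 1e-6)
    if rss1 <= 1e-300 * max(rss0, 1.0):
        p = 1.0 if rss0 <= 1e-300 else 0.0
    else:
        F = max(rss0 - rss1, 0.0) / df1 / (rss1 / df2)
        p = float(f_dist.sf(F, df1, df2))

    # 95% band from the sandwich covariance of the penalized estimator.
    sigma2 = rss1 / df2
    Ainv = np.linalg.solve(BtB + lam * P, np.eye(B.shape[1]))
    cov = sigma2 * (Ainv @ BtB @ Ainv)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov, B), 0.0))

    return SmoothFit(
        x=x,
        y=y,
        fitted=fitted,
        band_lower=fitted - 1.96 * se,
        band_upper=fitted + 1.96 * se,
        lam=float(lam),
        edf=tr - 1.0,
        p_value=p,
        _knots=knots,
        _coef=coef,
    )
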