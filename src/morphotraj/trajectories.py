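"""Kernel-weighted PLS trajectories of size and shape, rate vectors, and the
sexual-dimorphism permutation test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from morphotraj.smoothing import SmoothFit, smooth_trend  # re-exported  # noqa: F401

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: minimum kernel-effective sample size for a grid point to be reported
MIN_EFFECTIVE_N = 5.0


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel bandwidth and evaluation-age grid."""

    sigma: float
    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @classmethod
    def from_range(cls, lo: float, hi: float, sigma: float, step: float = 0.5) -> "KernelSpec":
        n = int(round((hi - lo) / step))
        return cls(sigma=sigma, grid=lo + step * np.arange(n + 1))


def default_cs_kernel(sigma: float = 2.25) -> KernelSpec:
    """Centroid-size kernel: ages 4-38, half-year steps."""
    return KernelSpec.from_range(4.0, 38.0, sigma=sigma)


def default_shape_kernel(sigma: float = 3.0) -> KernelSpec:
    """Shape kernel: ages 5-37, half-year steps."""
    return KernelSpec.from_range(5.0, 37.0, sigma=sigma)


def gaussian_weights(ages: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """w_i = (1/sqrt(2*pi)) * exp(-(x_i - x_m)^2 / (2*sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ages = np.asarray(ages, dtype=float)
    return np.exp(-((ages - center) ** 2) / (2.0 * sigma**2)) / _SQRT2PI


@dataclass
class WPLSFit:
    """Weighted PLS fit of a response block on a predictor block."""

    intercept: np.ndarray  # (K,)
    coef: np.ndarray  # (p, K): rate of change of each response per predictor unit
    x_mean: np.ndarray  # (p,) weighted predictor mean
    flat: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + (X - self.x_mean) @ self.coef


def wpls_fit(X: np.ndarray, Y: np.ndarray, weights: np.ndarray, n_components: int | None = None) -> WPLSFit:
    """Weighted partial least-squares regression of Y (n x K) on X (n x p).

    Observations are weighted-centred and scaled by sqrt(w), then a SIMPLS
    loop extracts ``n_components`` latent directions (default: one for a
    univariate predictor, else p). With one univariate predictor this is
    exactly per-response weighted least squares. Weights are scale
    invariant: multiplying all weights by a constant leaves the fit
    unchanged.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if n_components is None:
        n_components = 1 if p == 1 else p
    n_components = min(n_components, p)

    wsum = w.sum()
    x_mean = (w @ X) / wsum
    y_mean = (w @ Y) / wsum
    sw = np.sqrt(w)
    Xc = sw[:, None] * (X - x_mean)
    Yc = sw[:, None] * (Y - y_mean)

    if float((Xc**2).sum()) < 1e-28:
        warnings.warn("zero predictor variance under the weights; flat fit", stacklevel=2)
        return WPLSFit(intercept=y_mean, coef=np.zeros((p, Y.shape[1])), x_mean=x_mean, flat=True)

    # SIMPLS with deflation of the cross-product matrix.
    S = Xc.T @ Yc  # (p, K)
    B = np.zeros((p, Y.shape[1]))
    V = np.zeros((p, 0))
    for _ in range(n_components):
        # dominant left singular vector of S
        u, s, _ = np.linalg.svd(S, full_matrices=False)
        if s[0] < 1e-14:
            break
        r = u[:, 0]
        t = Xc @ r
        tt = float(t @ t)
        if tt < 1e-28:
            break
        q = (Yc.T @ t) / tt
        B += np.outer(r, q)
        v = Xc.T @ t
        if V.shape[1]:
            v = v - V @ (V.T @ v)
        v = v / np.linalg.norm(v)
        V = np.column_stack([V, v])
        S = S - np.outer(v, v @ S)

    return WPLSFit(intercept=y_mean, coef=B, x_mean=x_mean)


@dataclass
class TrajectoryModel:
    """Predicted response and instantaneous rate per evaluation age."""

    grid: np.ndarray  # (G,) ages
    predicted: np.ndarray  # (G, K)
    rates: np.ndarray  # (G, K) regression coefficients, per-year units
    effective_n: np.ndarray  # (G,) kernel-effective sample sizes
    valid: np.ndarray  # (G,) bool mask, effective_n >= MIN_EFFECTIVE_N
    sigma: float
    sex: str | None = None

    @property
    def rate_magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.rates, axis=1)

    def predicted_at(self, age: float) -> np.ndarray:
        """Prediction at the grid point nearest ``age``."""
        return self.predicted[int(np.argmin(np.abs(self.grid - age)))]


def rate_magnitude(rate_vector: np.ndarray) -> float:
    """Euclidean norm of a rate vector (identical in score or landmark space)."""
    return float(np.linalg.norm(np.asarray(rate_vector, dtype=float)))


def _linear_trajectory(ages: np.ndarray, Y: np.ndarray, kernel: KernelSpec):
    """Vectorized per-grid-age weighted linear fit (the p=1, 1-component path)."""
    grid = kernel.grid
    W = np.exp(-((ages[None, :] - grid[:, None]) ** 2) / (2.0 * kernel.sigma**2))  # (G, n)
    eff_n = W.sum(axis=1)
    sw = np.maximum(eff_n, 1e-300)
    xbar = (W @ ages) / sw
    ybar = (W @ Y) / sw[:, None]
    A = ages[None, :] - xbar[:, None]
    varx = (W * A**2).sum(axis=1) / sw
    cov = ((W * A) @ Y) / sw[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(varx[:, None] > 1e-28, cov / np.maximum(varx, 1e-300)[:, None], 0.0)
    pred = ybar + slope * (grid - xbar)[:, None]
    return pred, slope, eff_n


def fit_trajectory(
    responses: np.ndarray,
    ages: np.ndarray,
    kernel: KernelSpec,
    sex: str | None = None,
    min_n: int = 3,
) -> TrajectoryModel:
    """Kernel-weighted PLS trajectory of ``responses`` (CS or PC scores) on age.

    At every grid age a weighted PLS is fitted with Gaussian weights
    centred there; the prediction is the fit evaluated at the grid age and
    the rate vector is the coefficient vector. Grid points whose
    kernel-effective sample size falls below :data:`MIN_EFFECTIVE_N` are
    masked (reported, not interpolated).
    """
    ages = np.asarray(ages, dtype=float)
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(ages) != len(Y):
        raise ValueError("responses and ages length mismatch")
    if len(ages) < min_n:
        raise ValueError(f"need at least {min_n} individuals")

    pred, slope, eff_n = _linear_trajectory(ages, Y, kernel)
    valid = eff_n >= MIN_EFFECTIVE_N
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} grid point(s) masked: effective n < {MIN_EFFECTIVE_N}",
            stacklevel=2,
        )
    return TrajectoryModel(
        grid=kernel.grid,
        predicted=pred,
        rates=slope,
        effective_n=eff_n,
        valid=valid,
        sigma=kernel.sigma,
        sex=sex,
    )


@dataclass
class DimorphismProfile:
    """Procrustes distance between sex-specific predicted shapes per grid age."""

    grid: np.ndarray
    distance: np.ndarray  # (G,)
    p_values: np.ndarray  # (G,) add-one permutation p-values
    n_permutations: int
    valid: np.ndarray = field(default=None)


def _sex_distance(Y, ages, labels, kernel):
    m = labels == "M"
    pm, _, em = _linear_trajectory(ages[m], Y[m], kernel)
    pf, _, ef = _linear_trajectory(ages[~m], Y[~m], kernel)
    return np.linalg.norm(pm - pf, axis=1), (em >= MIN_EFFECTIVE_N) & (ef >= MIN_EFFECTIVE_N)


def dimorphism_profile(
    scores: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    kernel: KernelSpec,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> DimorphismProfile:
    """Observed male-female predicted-shape distance per grid age, with a
    sex-label permutation test.

    One permuted label vector is used across all grid ages within a
    permutation round, preserving the across-age dependence of the
    profile. p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    if not (np.any(sexes == "M") and np.any(sexes == "F")):
        raise ValueError("both sexes must be present")

    obs, valid = _sex_distance(scores, ages, sexes, kernel)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(len(sexes))
        null, _ = _sex_distance(scores, ages, sexes[perm], kernel)
        exceed += null >= obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return DimorphismProfile(
        grid=kernel.grid, distance=obs, p_values=p, n_permutations=n_perm, valid=valid
    )
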