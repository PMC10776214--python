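"""Procrustes variance (morphological disparity) per age group, for shapes
modelled by the group mean or by a nonlinear trajectory model, with pairwise
permutation tests and a nonlinear trend fit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from morphotraj.smoothing import SmoothFit, smooth_trend
from morphotraj.trajectories import TrajectoryModel

#: groups smaller than this are computed but flagged unstable
MIN_STABLE_N = 5


def _flatten(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X.reshape(X.shape[0], -1)


def procrustes_variance(
    X: np.ndarray, groups: np.ndarray, mode: str = "mean"
) -> dict[object, tuple[float, int]]:
    """Procrustes variance per group: sum of squared distances from the
    reference divided by the group size.

    ``mode='mean'``: the reference is the group mean (``X`` holds shapes or
    score vectors). ``mode='residual'``: ``X`` already holds residuals from
    a model prediction and the variance is the mean squared residual norm.
    Returns ``{group: (variance, n)}``.
    """
    if mode not in ("mean", "residual"):
        raise ValueError("mode must be 'mean' or 'residual'")
    flat = _flatten(X)
    groups = np.asarray(groups)
    if len(groups) != len(flat):
        raise ValueError("groups length mismatch")
    out: dict[object, tuple[float, int]] = {}
    for g in pd.unique(groups):
        sel = flat[groups == g]
        n = len(sel)
        if n == 0:
            raise ValueError(f"empty group {g!r}")
        if mode == "mean":
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2 for mean-reference variance")
            sel = sel - sel.mean(axis=0)
        out[g] = (float((sel**2).sum() / n), n)
    return out


def model_residuals(
    scores: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    models: dict[str, TrajectoryModel],
) -> np.ndarray:
    """Residual score vectors against sex-specific trajectory predictions.

    The prediction is taken at the grid age nearest each individual's age
    (half-year grid bounds the discretization error).
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    res = np.empty_like(scores)
    for sex, model in models.items():
        sel = sexes == sex
        idx = np.argmin(np.abs(model.grid[None, :] - ages[sel][:, None]), axis=1)
        res[sel] = scores[sel] - model.predicted[idx]
    return res


def pairwise_variance_test(
    residuals: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
    mode: str = "residual",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise |variance_g - variance_h| with two-sample permutation p-values.

    The statistic depends only on the squared norms of the residual
    vectors, which are permuted between the two groups under test
    (two-sample exchange). p-values use the add-one convention. Returns
    (absolute-difference matrix, p-value matrix) as DataFrames; the p
    matrix carries 1.0 on the diagonal.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    flat = _flatten(residuals)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if mode == "mean":
        flat = flat.copy()
        for g in labels:
            sel = groups == g
            flat[sel] -= flat[sel].mean(axis=0)
    sq = (flat**2).sum(axis=1)

    k = len(labels)
    diff = np.zeros((k, k))
    pmat = np.eye(k) * 1.0
    np.fill_diagonal(pmat, 1.0)
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            sa = sq[groups == labels[a]]
            sb = sq[groups == labels[b]]
            na, nb = len(sa), len(sb)
            obs = abs(sa.mean() - sb.mean())
            pool = np.concatenate([sa, sb])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                stat = abs(perm[:na].mean() - perm[na:].mean())
                if stat >= obs - 1e-15:
                    count += 1
            p = (1.0 + count) / (n_perm + 1.0)
            diff[a, b] = diff[b, a] = obs
            pmat[a, b] = pmat[b, a] = p
    return (
        pd.DataFrame(diff, index=labels, columns=labels),
        pd.DataFrame(pmat, index=labels, columns=labels),
    )


@dataclass
class VarianceProfile:
    """Per-age-bin Procrustes variance with pairwise permutation tests."""

    table: pd.DataFrame  # columns: bin, sex, n, variance, stable
    pairwise_diff: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None

    def combined_matrix(self) -> pd.DataFrame:
        """Differences in the upper/right triangle, p-values lower/left."""
        if self.pairwise_diff is None:
            raise ValueError("no pairwise results attached")
        d = self.pairwise_diff.to_numpy()
        p = self.pairwise_p.to_numpy()
        out = np.where(np.triu(np.ones_like(d, bool), 1), d, p)
        return pd.DataFrame(out, index=self.pairwise_diff.index, columns=self.pairwise_diff.columns)


def age_bins(ages: np.ndarray, lo: float = 5.0, hi: float = 37.0, width: float = 1.0) -> np.ndarray:
    """Assign each age to a bin labelled by its midpoint; out-of-range -> NaN."""
    ages = np.asarray(ages, dtype=float)
    edges = np.arange(lo, hi + width, width)
    idx = np.digitize(ages, edges) - 1
    mids = edges[:-1] + width / 2.0
    out = np.full(len(ages), np.nan)
    ok = (ages >= lo) & (ages < edges[-1]) & (idx >= 0) & (idx < len(mids))
    out[ok] = mids[idx[ok]]
    return out


def variance_profile(
    residuals: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    lo: float = 5.0,
    hi: float = 37.0,
    width: float = 1.0,
    n_perm: int = 0,
    seed: int | None = 0,
    min_n: int = 2,
) -> VarianceProfile:
    """Procrustes variance (residual mode) per 1-year age bin, by sex and pooled.

    When ``n_perm > 0`` pairwise permutation tests across pooled bins are
    attached.
    """
    bins = age_bins(ages, lo, hi, width)
    ok = ~np.isnan(bins)
    flat = _flatten(residuals)[ok]
    bins = bins[ok]
    sexes = np.asarray(sexes)[ok]

    rows = []
    for label, sel in [("pooled", np.ones(len(bins), bool)), ("F", sexes == "F"), ("M", sexes == "M")]:
        b = bins[sel]
        f = flat[sel]
        for mid in np.unique(b):
            grp = f[b == mid]
            if len(grp) < min_n:
                continue
            rows.append(
                {
                    "bin": float(mid),
                    "sex": label,
                    "n": len(grp),
                    "variance": float((grp**2).sum() / len(grp)),
                    "stable": len(grp) >= MIN_STABLE_N,
                }
            )
    table = pd.DataFrame(rows).sort_values(["sex", "bin"]).reset_index(drop=True)
    profile = VarianceProfile(table=table)
    if n_perm > 0:
        keep = np.isin(bins, table.loc[table.sex == "pooled", "bin"].to_numpy())
        diff, p = pairwise_variance_test(flat[keep], bins[keep], n_perm=n_perm, seed=seed)
        order = np.argsort(diff.index.to_numpy())
        profile.pairwise_diff = diff.iloc[order, order]
        profile.pairwise_p = p.iloc[order, order]
    return profile


def variance_trend(profile: VarianceProfile, sex: str = "pooled") -> SmoothFit:
    """Nonlinear trend of per-bin Procrustes variance against bin midpoint."""
    sub = profile.table[profile.table.sex == sex]
    if len(sub) < 10:
        raise ValueError("need at least 10 bins for a trend fit")
    return smooth_trend(sub["bin"].to_numpy(), sub["variance"].to_numpy())
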