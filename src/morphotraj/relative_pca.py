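"""Relative eigenanalysis of two groups' shape covariance structure:
relative eigenvalues/eigenvectors, generalized-variance ratio,
proportionality likelihood-ratio test and successive-eigenvalue tests with
FDR adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass
class GroupCovariances:
    """Within-group covariances in the leading-p PC subspace of the pooled groups."""

    S1: np.ndarray  # (p, p)
    S2: np.ndarray
    n1: int
    n2: int
    basis: np.ndarray  # (K, p) subspace loadings within the input score space
    explained: float  # variance fraction of the pooled scores captured by the subspace


def _cov(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / (len(X) - 1)


def group_covariance(
    scores: np.ndarray, groups: np.ndarray, group_a, group_b, p: int = 5
) -> GroupCovariances:
    """Covariance of two groups in the leading-p PC subspace of their pooled scores.

    Each group is mean-centred within itself; covariances are unbiased
    (n - 1). Requires group sizes strictly greater than p.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    Xa = scores[groups == group_a]
    Xb = scores[groups == group_b]
    if len(Xa) <= p or len(Xb) <= p:
        raise ValueError(f"both groups need n > p={p} (got {len(Xa)}, {len(Xb)})")
    pool = np.concatenate([Xa, Xb])
    pool_c = pool - pool.mean(axis=0)
    _, s, Vt = np.linalg.svd(pool_c, full_matrices=False)
    if p > Vt.shape[0]:
        raise ValueError("subspace dimension exceeds pooled rank")
    basis = Vt[:p].T
    explained = float((s[:p] ** 2).sum() / (s**2).sum())
    return GroupCovariances(
        S1=_cov(Xa @ basis),
        S2=_cov(Xb @ basis),
        n1=len(Xa),
        n2=len(Xb),
        basis=basis,
        explained=explained,
    )


def relative_eigen(S1: np.ndarray, S2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve S1 v = lambda S2 v by symmetric whitening.

    Returns eigenvalues sorted descending and S2-orthonormal eigenvectors
    (columns) with the sign fixed so the largest-magnitude loading is
    positive.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    try:
        L = np.linalg.cholesky(S2)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "S2 is not positive definite on the subspace; reduce p"
        ) from err
    Linv = np.linalg.solve(L, np.eye(len(L)))
    M = Linv @ S1 @ Linv.T
    vals, U = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = Linv.T @ U[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def generalized_variance_ratio(eigenvalues: np.ndarray) -> float:
    """Product of the relative eigenvalues = det(S1)/det(S2) on the subspace."""
    vals = np.asarray(eigenvalues, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all relative eigenvalues must be > 0")
    return float(np.prod(vals))


def _n_eff(n1: int, n2: int) -> float:
    return n1 * n2 / (n1 + n2)


def _prop_stat(vals: np.ndarray) -> float:
    """p * log(arithmetic mean / geometric mean) of the relative eigenvalues."""
    vals = np.asarray(vals, dtype=float)
    p = len(vals)
    return float(p * (np.log(vals.mean()) - np.log(vals).mean()))


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


def proportionality_test(eigenvalues: np.ndarray, n1: int, n2: int) -> TestResult:
    """Likelihood-ratio test of H0: S1 = c * S2 (all relative eigenvalues equal).

    Statistic n_eff * p * log(arith/geo mean of the relative eigenvalues),
    n_eff = n1*n2/(n1+n2), referred to chi-square with p(p+1)/2 - 1 df.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    p = len(vals)
    df = p * (p + 1) / 2.0 - 1.0
    if df < 1:
        raise ValueError("need p >= 2")
    stat = _n_eff(n1, n2) * _prop_stat(vals)
    return TestResult(stat, df, float(chi2.sf(stat, df)), "chi2")


def proportionality_permutation_test(
    scores: np.ndarray,
    groups: np.ndarray,
    group_a,
    group_b,
    p: int = 5,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> TestResult:
    """Permutation version of the proportionality test.

    Individuals are exchanged between the two groups; the eigenvalue
    dispersion statistic p*log(arith/geo) is recomputed per permutation
    (the pooled subspace is permutation invariant). Add-one p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    sel = (groups == group_a) | (groups == group_b)
    X = scores[sel]
    g = groups[sel]
    gc = group_covariance(X, g, group_a, group_b, p=p)
    Z = X @ gc.basis
    na = gc.n1

    def stat_for(Za, Zb):
        vals, _ = relative_eigen(_cov(Za), _cov(Zb))
        return _prop_stat(vals)

    obs = stat_for(Z[g == group_a], Z[g == group_b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Z))
        s = stat_for(Z[perm[:na]], Z[perm[na:]])
        if s >= obs - 1e-15:
            count += 1
    return TestResult(obs, float("nan"), (1.0 + count) / (n_perm + 1.0), "permutation")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def successive_eigenvalue_tests(eigenvalues: np.ndarray, n_eff: float) -> pd.DataFrame:
    """LR tests of equality of each adjacent pair of relative eigenvalues.

    Each pair uses the two-value version of the proportionality statistic
    (p = 2, chi-square df 2); raw p-values are Benjamini-Hochberg adjusted
    across the pairs.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 eigenvalues")
    rows = []
    for i in range(len(vals) - 1):
        pair = vals[i : i + 2]
        stat = n_eff * _prop_stat(pair)
        df = 2.0  # p(p+1)/2 - 1 with p = 2
        rows.append(
            {
                "pair": f"{i + 1}-{i + 2}",
                "lambda_i": pair[0],
                "lambda_j": pair[1],
                "statistic": stat,
                "df": df,
                "p_raw": float(chi2.sf(stat, df)),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def relative_feature_shape(
    eigenvector: np.ndarray,
    subspace_basis: np.ndarray,
    shape_eigenbasis: np.ndarray,
    consensus: np.ndarray,
    amplitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct source/target shapes +- amplitude along a relative eigenvector.

    The p-subspace vector is expanded through the subspace loadings into
    the retained shape eigenbasis and then into landmark space:
    source = consensus - amplitude * direction, target = consensus + it.
    """
    v = np.asarray(eigenvector, dtype=float)
    if v.shape[0] != subspace_basis.shape[1]:
        raise ValueError("eigenvector does not match subspace dimension")
    score_dir = subspace_basis @ v  # (K,)
    flat = shape_eigenbasis[:, : score_dir.shape[0]] @ score_dir
    direction = flat.reshape(-1, 3)
    consensus = np.asarray(consensus, dtype=float)
    return consensus - amplitude * direction, consensus + amplitude * direction


@dataclass
class RelativePCAResult:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    subspace_basis: np.ndarray
    generalized_variance_ratio: float
    proportionality: TestResult
    successive: pd.DataFrame
    n1: int
    n2: int
    p: int


def run_relative_pca(
    scores: np.ndarray,
    groups: np.ndarray,
    group_a,
    group_b,
    p: int = 5,
    mode: str = "lr",
    n_perm: int = 1000,
    seed: int | None = 0,
) -> RelativePCAResult:
    """End-to-end relative PCA of group_a's covariance relative to group_b's."""
    gc = group_covariance(scores, groups, group_a, group_b, p=p)
    vals, vecs = relative_eigen(gc.S1, gc.S2)
    if mode == "perm":
        prop = proportionality_permutation_test(
            scores, groups, group_a, group_b, p=p, n_perm=n_perm, seed=seed
        )
    elif mode == "lr":
        prop = proportionality_test(vals, gc.n1, gc.n2)
    else:
        raise ValueError("mode must be 'lr' or 'perm'")
    succ = successive_eigenvalue_tests(vals, _n_eff(gc.n1, gc.n2))
    return RelativePCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        subspace_basis=gc.basis,
        generalized_variance_ratio=generalized_variance_ratio(vals),
        proportionality=prop,
        successive=succ,
        n1=gc.n1,
        n2=gc.n2,
        p=p,
    )
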