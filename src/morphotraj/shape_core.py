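"""Procrustes superimposition, symmetrization, size and the retained eigenbasis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from morphotraj.topology import TemplateTopology, TopologyError


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide (or fewer than two landmarks)."""


class GPAConvergenceError(RuntimeError):
    def __init__(self, trace):
        self.trace = trace
        super().__init__(
            f"GPA did not converge in {len(trace)} iterations; last change {trace[-1]:.3e}"
        )


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One individual's raw landmark coordinates plus metadata."""

    id: str
    coords: np.ndarray  # (L, 3), millimetres
    age: float
    sex: str  # "F" or "M"
    height: float | None = None  # cm
    weight: float | None = None  # kg

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"configuration {self.id!r} has non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise DegenerateConfigurationError("need at least 2 landmarks")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


def optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||moving @ R.T - target||_F.

    Both inputs are assumed centred. Mirror solutions are rejected by
    flipping the sign of the smallest singular direction.
    """
    H = target.T @ moving
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


@dataclass
class GPAResult:
    aligned: np.ndarray  # (n, L, 3), unit centroid size
    consensus: np.ndarray  # (L, 3), unit centroid size
    centroid_sizes: np.ndarray  # (n,) of the raw inputs
    n_iterations: int
    trace: list = field(default_factory=list, repr=False)


def gpa(coords: np.ndarray | list, tol: float = 1e-10, max_iter: int = 200) -> GPAResult:
    """Generalized Procrustes analysis (partial Procrustes, unit-CS scaling).

    Each configuration is centred, scaled to unit centroid size and
    iteratively rotated to the running consensus (SVD orthogonal solution,
    det +1 enforced) until the consensus RMS change falls below ``tol``.
    """
    X = np.asarray([np.asarray(c, dtype=float) for c in coords])
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need at least 2 configurations of equal landmark count")
    n = X.shape[0]
    sizes = np.empty(n)
    aligned = np.empty_like(X)
    for i in range(n):
        c = X[i] - X[i].mean(axis=0)
        sizes[i] = centroid_size(X[i])
        aligned[i] = c / sizes[i]

    consensus = aligned.mean(axis=0)
    consensus /= np.linalg.norm(consensus)
    trace = []
    for it in range(max_iter):
        for i in range(n):
            R = optimal_rotation(aligned[i], consensus)
            aligned[i] = aligned[i] @ R.T
        new = aligned.mean(axis=0)
        new /= np.linalg.norm(new)
        change = float(np.sqrt(((new - consensus) ** 2).mean()))
        trace.append(change)
        consensus = new
        if change < tol:
            return GPAResult(aligned, consensus, sizes, it + 1, trace)
    raise GPAConvergenceError(trace)


def symmetrize(
    coords: np.ndarray | list, topology: TemplateTopology, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, GPAResult]:
    """Object-symmetry decomposition of a set of configurations.

    Builds each configuration's mirror (negate x, relabel via the pairing
    map), superimposes originals and mirrors jointly, and returns

    - symmetric components: average of each original with its own aligned
      mirror;
    - asymmetric components: half the difference;
    - the joint GPA result.
    """
    X = np.asarray([np.asarray(c, dtype=float) for c in coords])
    if X.shape[1] != topology.n_landmarks:
        raise TopologyError("landmark count does not match topology")
    mirrors = topology.mirror(X)
    res = gpa(np.concatenate([X, mirrors], axis=0), tol=tol)
    n = X.shape[0]
    orig, mirr = res.aligned[:n], res.aligned[n:]
    sym = 0.5 * (orig + mirr)
    asym = 0.5 * (orig - mirr)
    return sym, asym, res


@dataclass
class ShapePCA:
    """Eigenbasis of the aligned (symmetric) shape coordinates."""

    consensus: np.ndarray  # (L, 3)
    eigenvectors: np.ndarray  # (3L, K), columns orthonormal
    eigenvalues: np.ndarray  # (K,) retained eigenvalues
    all_eigenvalues: np.ndarray  # all nonzero eigenvalues
    explained: np.ndarray  # (K,) fractions of total variance
    scores: np.ndarray  # (n, K)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained.sum())

    def transform(self, coords: np.ndarray) -> np.ndarray:
        flat = (np.asarray(coords) - self.consensus).reshape(*coords.shape[:-2], -1)
        return flat @ self.eigenvectors


def shape_pca(sym_coords: np.ndarray, retention: float = 0.99) -> ShapePCA:
    """PCA of flattened aligned coordinates about their mean.

    K is the smallest component count whose cumulative explained-variance
    fraction reaches ``retention``.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    X = np.asarray(sym_coords, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 configurations for PCA")
    consensus = X.mean(axis=0)
    flat = (X - consensus).reshape(n, -1)
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = s**2 / (n - 1)
    nz = eigvals > eigvals[0] * 1e-14 if eigvals[0] > 0 else np.zeros_like(eigvals, bool)
    eigvals = eigvals[nz]
    Vt = Vt[nz]
    frac = eigvals / eigvals.sum()
    K = int(np.searchsorted(np.cumsum(frac), retention - 1e-12) + 1)
    K = min(K, len(eigvals))
    basis = Vt[:K].T
    scores = flat @ basis
    return ShapePCA(
        consensus=consensus,
        eigenvectors=basis,
        eigenvalues=eigvals[:K],
        all_eigenvalues=eigvals,
        explained=frac[:K],
        scores=scores,
    )


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray, align: bool = False) -> float:
    """Euclidean norm of the coordinate difference of two co-aligned shapes.

    With ``align=True`` the pair is re-superimposed first (centred, scaled
    to unit centroid size, optimally rotated).
    """
    a = np.asarray(shape_a, dtype=float)
    b = np.asarray(shape_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape arrays must have identical dimensions")
    if align:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a / np.linalg.norm(a)
        b = b / np.linalg.norm(b)
        b = b @ optimal_rotation(b, a).T
    return float(np.linalg.norm(a - b))


def scores_to_shape(
    scores: np.ndarray, eigenbasis: np.ndarray, consensus: np.ndarray
) -> np.ndarray:
    """Reconstruct landmark coordinates from PC scores: consensus + basis @ scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.shape[0] > eigenbasis.shape[1]:
        raise ValueError("score vector length exceeds eigenbasis size")
    flat = eigenbasis[:, : scores.shape[0]] @ scores
    return np.asarray(consensus) + flat.reshape(-1, 3)


@dataclass
class AlignedCohort:
    """Procrustes-aligned, symmetrized cohort with its retained eigenbasis."""

    ids: np.ndarray
    ages: np.ndarray
    sexes: np.ndarray
    sym_coords: np.ndarray  # (n, L, 3)
    asym_coords: np.ndarray  # (n, L, 3)
    centroid_sizes: np.ndarray  # (n,)
    pca: ShapePCA
    topology: TemplateTopology

    @property
    def consensus(self) -> np.ndarray:
        return self.pca.consensus

    @property
    def scores(self) -> np.ndarray:
        return self.pca.scores

    @property
    def n_individuals(self) -> int:
        return len(self.ids)


def align_cohort(
    configs: list[LandmarkConfiguration],
    topology: TemplateTopology,
    retention: float = 0.99,
) -> AlignedCohort:
    """GPA + symmetrization + PCA: the full alignment stage on a cohort."""
    if len(configs) < 3:
        raise ValueError("need at least 3 configurations")
    coords = np.asarray([c.coords for c in configs])
    if coords.shape[1] != topology.n_landmarks:
        raise TopologyError("cohort landmark count does not match topology")
    sizes = np.asarray([centroid_size(c.coords) for c in configs])
    sym, asym, _ = symmetrize(coords, topology)
    pca = shape_pca(sym, retention=retention)
    return AlignedCohort(
        ids=np.asarray([c.id for c in configs]),
        ages=np.asarray([c.age for c in configs], dtype=float),
        sexes=np.asarray([c.sex for c in configs]),
        sym_coords=sym,
        asym_coords=asym,
        centroid_sizes=sizes,
        pca=pca,
        topology=topology,
    )
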