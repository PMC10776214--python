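"""Synthetic landmark cohorts with known ground truth.

Generates bilaterally symmetric, face-like template meshes and cohorts of
3D landmark configurations whose mean shape, centroid size, sexual
dimorphism and among-individual variance follow configurable age curves,
so every downstream analysis stage can be validated against an analytic
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from morphotraj.topology import TemplateTopology


class SpecValidationError(ValueError):
    """Raised when a :class:`CohortSpec` field is invalid; names the field."""


# ---------------------------------------------------------------------------
# Age curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Constant:
    """Constant amplitude curve."""

    value: float = 0.0

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value) if np.ndim(t) else self.value

    def derivative(self, t):
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0


@dataclass(frozen=True)
class Linear:
    """a(t) = intercept + slope * t."""

    slope: float
    intercept: float = 0.0

    def __call__(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        return np.broadcast_to(self.slope, t.shape).copy() if t.ndim else self.slope


@dataclass(frozen=True)
class Logistic:
    """a(t) = baseline + scale / (1 + exp(-rate * (t - midpoint)))."""

    scale: float
    midpoint: float
    rate: float
    baseline: float = 0.0

    def _sigmoid(self, t):
        return 1.0 / (1.0 + np.exp(-self.rate * (np.asarray(t, dtype=float) - self.midpoint)))

    def __call__(self, t):
        return self.baseline + self.scale * self._sigmoid(t)

    def derivative(self, t):
        s = self._sigmoid(t)
        return self.scale * self.rate * s * (1.0 - s)


@dataclass(frozen=True)
class Ramp:
    """a(t) = slope * max(t - onset, 0): amplitude switching on at an onset age."""

    onset: float
    slope: float

    def __call__(self, t):
        return self.slope * np.maximum(np.asarray(t, dtype=float) - self.onset, 0.0)

    def derivative(self, t):
        return self.slope * (np.asarray(t, dtype=float) > self.onset).astype(float)


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


def make_template(resolution: int = 11) -> TemplateTopology:
    """Build a bilaterally symmetric, face-like triangulated open surface.

    The surface is a dome (half-ellipsoid patch) with a nose-like central
    protrusion, sampled on a ``(resolution + 2) x (2 * resolution + 1)``
    grid so a midline column exists. ``paired_map`` is consistent with the
    reflection x -> -x; coordinates satisfy reflect-and-relabel symmetry
    exactly.

    The default resolution gives L = 299 landmarks.
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    ncol = 2 * resolution + 1
    nrow = resolution + 2

    # Build u antisymmetric exactly: u[j] = -u[ncol-1-j], u[mid] = 0.
    half = np.linspace(0.0, 1.0, resolution + 1)
    u = np.concatenate([-half[::-1], half[1:]])
    v = np.linspace(0.0, 1.0, nrow)
    uu, vv = np.meshgrid(u, v)  # (nrow, ncol)

    # Face-scale millimetres: half-width ~60, height ~90, depth ~40.
    x = 60.0 * uu
    y = 90.0 * (vv - 0.5)
    dome = 1.0 - uu**2 - (2.0 * vv - 1.0) ** 2
    z = 40.0 * np.sqrt(np.clip(dome, 0.0, None))
    # Nose-like bump: even function of u, centred below mid-height.
    z = z + 16.0 * np.exp(-((uu / 0.18) ** 2) - (((vv - 0.38) / 0.10) ** 2))

    coords = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    paired = np.empty(nrow * ncol, dtype=int)
    paired[idx] = idx[:, ::-1]

    facets = []
    for i in range(nrow - 1):
        for j in range(ncol - 1):
            a, b = idx[i, j], idx[i, j + 1]
            c, d = idx[i + 1, j], idx[i + 1, j + 1]
            facets.append((a, b, d))
            facets.append((a, d, c))
    facets = np.asarray(facets, dtype=int)

    return TemplateTopology(
        n_landmarks=nrow * ncol,
        facets=facets,
        paired_map=paired,
        template_coords=coords,
    )


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


def _default_cs_curves() -> dict:
    # Size growth peaking near age 10, plateauing towards 18, males larger.
    return {
        "F": Logistic(scale=90.0, midpoint=10.0, rate=0.45, baseline=280.0),
        "M": Logistic(scale=115.0, midpoint=10.0, rate=0.45, baseline=285.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a synthetic landmark cohort.

    Amplitudes are expressed in the unit-centroid-size shape frame; the
    final configuration is scaled by the sex- and age-specific centroid
    size curve and given a random rigid nuisance motion.
    """

    n_female: int = 150
    n_male: int = 150
    age_range: tuple[float, float] = (3.0, 40.0)
    cs_growth: dict = field(default_factory=_default_cs_curves)
    #: age curve of the mean-shape trend amplitude (along a fixed direction)
    shape_trend: object = Logistic(scale=0.08, midpoint=9.0, rate=0.40)
    #: age curve of the male-minus-female shape distance
    dimorphism: object = Logistic(scale=0.05, midpoint=13.0, rate=0.50)
    #: onset age used when building a default ramp-type dimorphism curve
    dimorphism_onset: float = 6.0
    #: per-coordinate sd of isotropic tangent-space noise at the youngest age
    baseline_sd: float = 0.003
    #: multiplier of baseline_sd as a function of age (>= 0)
    sd_age_curve: object = Linear(slope=0.03, intercept=1.0)
    #: age curve of the sd of the single "diversifying direction" component
    diversify_curve: object = Linear(slope=0.0012, intercept=0.0)
    #: per-coordinate sd of the bilateral-asymmetry perturbation
    asymmetry_sd: float = 0.001
    age_distribution: str = "skewed"  # or "uniform"
    #: nuisance similarity motion applied to each configuration
    rotate: bool = True
    translation_box: float = 50.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise SpecValidationError("n_female/n_male must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise SpecValidationError("age_range must be increasing")
        for name in ("baseline_sd", "asymmetry_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        if self.age_distribution not in ("skewed", "uniform"):
            raise SpecValidationError("age_distribution must be 'skewed' or 'uniform'")
        for sex in ("F", "M"):
            if sex not in self.cs_growth:
                raise SpecValidationError(f"cs_growth missing curve for sex {sex!r}")
        s0, s1 = self.scale_range
        if not 0 < s0 <= s1:
            raise SpecValidationError("scale_range must satisfy 0 < lo <= hi")
        ages = np.linspace(lo, hi, 32)
        if np.any(np.asarray(self.sd_age_curve(ages)) < 0):
            raise SpecValidationError("sd_age_curve must be >= 0 over age_range")
        if np.any(np.asarray(self.diversify_curve(ages)) < 0):
            raise SpecValidationError("diversify_curve must be >= 0 over age_range")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Ground truth machinery
# ---------------------------------------------------------------------------


def _similarity_modes(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the translation/rotation/scale modes at ``base``.

    ``base`` is a centred (L, 3) configuration. The 7 modes span the
    directions along which a small perturbation is absorbed by a similarity
    transform rather than changing shape.
    """
    L = base.shape[0]
    modes = []
    for k in range(3):
        m = np.zeros((L, 3))
        m[:, k] = 1.0
        modes.append(m.ravel())
    for axis in np.eye(3):
        modes.append(np.cross(np.broadcast_to(axis, (L, 3)), base).ravel())
    modes.append(base.ravel())
    M = np.asarray(modes)
    # Gram-Schmidt; rotation modes of a degenerate base may vanish.
    Q = []
    for row in M:
        for q in Q:
            row = row - (row @ q) * q
        n = np.linalg.norm(row)
        if n > 1e-12:
            Q.append(row / n)
    return np.asarray(Q)


def _project_tangent(vec: np.ndarray, modes: np.ndarray) -> np.ndarray:
    flat = vec.ravel().copy()
    flat -= modes.T @ (modes @ flat)
    return flat.reshape(vec.shape)


class GroundTruth:
    """Deterministic generative directions and curves derived from a spec.

    Directions are bilaterally symmetric unit fields in the tangent space
    of the unit-size template, mutually orthogonal, drawn reproducibly from
    ``spec.seed``.
    """

    def __init__(self, spec: CohortSpec, topology: TemplateTopology):
        spec.validate()
        if topology.template_coords is None:
            raise ValueError("topology must carry template_coords")
        self.spec = spec
        self.topology = topology
        tmpl = topology.template_coords - topology.template_coords.mean(axis=0)
        self.template_unit = tmpl / np.linalg.norm(tmpl)
        self._modes = _similarity_modes(self.template_unit)
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x7E3A]))
        dirs = []
        for _ in range(3):  # trend, dimorphism, diversifying
            d = rng.standard_normal((topology.n_landmarks, 3))
            d = 0.5 * (d + topology.mirror(d))  # symmetric field
            d = _project_tangent(d, self._modes)
            flat = d.ravel()
            for prev in dirs:
                flat = flat - (flat @ prev.ravel()) * prev.ravel()
            flat /= np.linalg.norm(flat)
            dirs.append(flat.reshape(-1, 3))
        self.trend_direction, self.dimorphism_direction, self.diversify_direction = dirs

    # -- mean structure ----------------------------------------------------

    def _check_age(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        lo, hi = self.spec.age_range
        if np.any(age < lo) or np.any(age > hi):
            raise ValueError(f"age outside spec range [{lo}, {hi}]")
        return age

    def mean_shape(self, age: float, sex: str) -> np.ndarray:
        """Unit-frame mean configuration at (age, sex): template + trend + dimorphism."""
        age = self._check_age(age)
        sign = {"M": 0.5, "F": -0.5}[sex]
        a = float(self.spec.shape_trend(age))
        d = float(self.spec.dimorphism(age))
        return self.template_unit + a * self.trend_direction + sign * d * self.dimorphism_direction

    def rate(self, age: float, sex: str) -> np.ndarray:
        """Analytic d(mean shape)/d(age): per-landmark displacement per year."""
        age = self._check_age(age)
        sign = {"M": 0.5, "F": -0.5}[sex]
        da = float(self.spec.shape_trend.derivative(age))
        dd = float(self.spec.dimorphism.derivative(age))
        return da * self.trend_direction + sign * dd * self.dimorphism_direction

    def centroid_size(self, age: float, sex: str) -> float:
        return float(self.spec.cs_growth[sex](age))

    def dimorphism_distance(self, age: float) -> float:
        """Procrustes distance between male and female unit-frame mean shapes."""
        self._check_age(age)
        return float(self.spec.dimorphism(age))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Simulated configurations plus the generative ground truth."""

    configs: list  # of LandmarkConfiguration
    spec: CohortSpec
    topology: TemplateTopology
    ground_truth: GroundTruth
    #: (n, L, 3) per-individual deterministic mean shapes in the unit frame
    mean_shapes: np.ndarray

    def __len__(self) -> int:
        return len(self.configs)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via the quaternion method."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _draw_ages(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        u = rng.uniform(size=n)
    else:
        # Right-shifted mass: proportionally fewer young individuals.
        u = rng.beta(3.0, 1.6, size=n)
    return lo + (hi - lo) * u


def simulate_cohort(spec: CohortSpec, topology: TemplateTopology) -> SyntheticCohort:
    """Simulate a cohort of landmark configurations from ``spec``.

    Each individual is the unit-frame mean shape at its (age, sex) plus
    tangent-space noise (isotropic + one diversifying direction) and a
    small bilateral-asymmetry field, scaled to the ground-truth centroid
    size and subjected to a random similarity nuisance motion.
    Bit-for-bit reproducible from (spec, seed).
    """
    from morphotraj.shape_core import LandmarkConfiguration

    gt = GroundTruth(spec, topology)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x51C0]))
    L = topology.n_landmarks

    sexes = ["F"] * spec.n_female + ["M"] * spec.n_male
    n = len(sexes)
    ages = _draw_ages(rng, n, spec)

    configs = []
    means = np.empty((n, L, 3))
    for i, (age, sex) in enumerate(zip(ages, sexes)):
        mu = gt.mean_shape(age, sex)
        means[i] = mu

        sd = spec.baseline_sd * float(spec.sd_age_curve(age))
        noise = rng.standard_normal((L, 3))
        eps = sd * _project_tangent(noise, gt._modes)
        eps += float(spec.diversify_curve(age)) * rng.standard_normal() * gt.diversify_direction
        asym_field = rng.standard_normal((L, 3))
        asym_field = 0.5 * (asym_field - topology.mirror(asym_field))
        asym_field -= asym_field.mean(axis=0)
        eps += spec.asymmetry_sd * asym_field

        # Normalize by ||mu|| so a noise-free configuration has centroid size
        # exactly equal to the growth curve (trend/dimorphism displacements
        # inflate ||mu|| slightly above 1).
        shape = (mu + eps) / np.linalg.norm(mu)
        cs = gt.centroid_size(age, sex)
        s0, s1 = spec.scale_range
        nuis = np.exp(rng.uniform(np.log(s0), np.log(s1)))
        R = _random_rotation(rng) if spec.rotate else np.eye(3)
        t = rng.uniform(-spec.translation_box, spec.translation_box, size=3)
        coords = cs * nuis * (shape @ R.T) + t

        # Anthropometrics loosely tied to age/sex, for exclusion-filter plumbing.
        h_age = min(age, 18.0)
        height = 82.0 + 5.2 * h_age + (4.0 if sex == "M" else 0.0) + rng.normal(0.0, 5.0)
        bmi = rng.normal(21.0 if age > 18 else 18.0, 2.5)
        weight = bmi * (height / 100.0) ** 2

        configs.append(
            LandmarkConfiguration(
                id=f"{sex}{i:05d}",
                coords=coords,
                age=float(age),
                sex=sex,
                height=float(height),
                weight=float(weight),
            )
        )

    return SyntheticCohort(
        configs=configs, spec=spec, topology=topology, ground_truth=gt, mean_shapes=means
    )


def ground_truth_rate(spec: CohortSpec, topology: TemplateTopology, age: float, sex: str) -> np.ndarray:
    """Analytic per-landmark displacement-per-year of the mean-shape curve."""
    return GroundTruth(spec, topology).rate(age, sex)
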