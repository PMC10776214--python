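import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphotraj.shape_core import (
    DegenerateConfigurationError,
    align_cohort,
    centroid_size,
    gpa,
    procrustes_distance,
    scores_to_shape,
    shape_pca,
    symmetrize,
)
from morphotraj.synthetic_data import CohortSpec, simulate_cohort, _random_rotation

from conftest import noise_free_spec


def random_rigid(rng, scale=True):
    R = _random_rotation(rng)
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    t = rng.uniform(-10, 10, 3)
    return lambda X: s * (X @ R.T) + t


class TestCentroidSize:
    def test_square_closed_form(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8.0))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_homogeneity(self, c):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3))
        assert centroid_size(c * X) == pytest.approx(c * centroid_size(X), rel=1e-10)

    def test_matches_brute_force_sum(self, small_topology):
        # oracle: direct per-landmark summation
        X = small_topology.template_coords
        mean = X.mean(axis=0)
        brute = np.sqrt(sum(float((p - mean) @ (p - mean)) for p in X))
        assert centroid_size(X) == pytest.approx(brute, rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.zeros((5, 3)))
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.array([[1.0, 2.0, 3.0]]))


class TestGPA:
    def test_identical_shapes_under_rigid_motion(self, small_topology, rng):
        base = small_topology.template_coords
        motions = [random_rigid(rng) for _ in range(4)]
        res = gpa([m(base) for m in motions])
        for i in range(1, 4):
            assert np.abs(res.aligned[i] - res.aligned[0]).max() < 1e-8
        assert procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-8

    def test_invariance_under_common_rotation(self, rng):
        base = rng.standard_normal((12, 3))
        shapes = [base + 0.4 * rng.standard_normal((12, 3)) for _ in range(5)]
        res1 = gpa(shapes)
        R = _random_rotation(rng)
        res2 = gpa([s @ R.T for s in shapes])
        d1 = [procrustes_distance(a, b) for a in res1.aligned for b in res1.aligned]
        d2 = [procrustes_distance(a, b) for a in res2.aligned for b in res2.aligned]
        assert np.abs(np.array(d1) - np.array(d2)).max() < 1e-8

    def test_three_point_grid_search_oracle(self, rng):
        # planar triangles: exhaustive search over in-plane rotation angle
        tri_a = np.array([[0, 0, 0], [4, 0, 0], [1, 3, 0]], dtype=float)
        tri_b = np.array([[0, 0, 0], [5, 0.5, 0], [0.5, 2.5, 0]], dtype=float)

        def unit(X):
            X = X - X.mean(axis=0)
            return X / centroid_size(X)

        a, b = unit(tri_a), unit(tri_b)
        best = (np.inf, None)
        thetas = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        for _ in range(3):  # coarse-to-fine refinement
            for th in thetas:
                R = np.array(
                    [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
                )
                d = np.linalg.norm(b @ R.T - a)
                if d < best[0]:
                    best = (d, th)
            span = thetas[1] - thetas[0]
            thetas = np.linspace(best[1] - 2 * span, best[1] + 2 * span, 2000)
        assert procrustes_distance(a, b, align=True) == pytest.approx(best[0], abs=1e-4)

    def test_centering_invariant(self, noisy_cohort):
        _, aligned = noisy_cohort
        dev = (aligned.sym_coords - aligned.consensus).sum(axis=0)
        assert np.abs(dev).max() < 1e-9


class TestSymmetrize:
    def test_symmetric_input_zero_asym(self, small_topology, rng):
        base = small_topology.template_coords  # exactly symmetric
        shapes = [random_rigid(rng)(base) for _ in range(4)]
        sym, asym, _ = symmetrize(shapes, small_topology)
        assert np.abs(asym).max() < 1e-9

    def test_idempotence(self, small_topology, rng):
        shapes = small_topology.template_coords + 0.5 * rng.standard_normal(
            (5, small_topology.n_landmarks, 3)
        )
        sym1, _, _ = symmetrize(shapes, small_topology)
        sym2, asym2, _ = symmetrize(sym1, small_topology)
        assert np.abs(asym2).max() < 1e-9
        # compare as shapes (the second GPA may re-orient the frame)
        for a, b in zip(sym1, sym2):
            assert procrustes_distance(a, b, align=True) < 1e-9

    def test_invariant_under_pre_mirroring(self, small_topology, rng):
        shapes = small_topology.template_coords + 0.3 * rng.standard_normal(
            (6, small_topology.n_landmarks, 3)
        )
        sym1, _, _ = symmetrize(shapes, small_topology)
        sym2, _, _ = symmetrize(small_topology.mirror(shapes), small_topology)
        for a, b in zip(sym1, sym2):
            assert procrustes_distance(a, b, align=True) < 1e-8

    def test_components_orthogonal(self, noisy_cohort):
        _, aligned = noisy_cohort
        n = aligned.n_individuals
        dots = np.einsum(
            "ni,ni->n", aligned.sym_coords.reshape(n, -1), aligned.asym_coords.reshape(n, -1)
        )
        assert np.abs(dots).max() < 1e-8


class TestShapePCA:
    def test_rank_two_data(self, rng):
        L = 10
        base = rng.standard_normal((L, 3))
        d1 = rng.standard_normal((L, 3))
        d2 = rng.standard_normal((L, 3))
        shapes = np.array(
            [base + a * d1 + b * d2 for a, b in rng.standard_normal((20, 2)) * 0.1]
        )
        pca = shape_pca(shapes, retention=0.99)
        assert pca.n_components == 2
        assert pca.cumulative_explained == pytest.approx(1.0)

    def test_full_roundtrip(self, rng):
        shapes = rng.standard_normal((8, 6, 3))
        pca = shape_pca(shapes, retention=1.0)
        for s in shapes:
            rec = scores_to_shape(pca.transform(s), pca.eigenvectors, pca.consensus)
            assert np.abs(rec - s).max() < 1e-10

    def test_eigenvalues_against_covariance_oracle(self, rng):
        shapes = rng.standard_normal((10, 5, 3))
        pca = shape_pca(shapes, retention=1.0)
        flat = shapes.reshape(10, -1)
        cov = np.cov(flat, rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1][: len(pca.all_eigenvalues)]
        assert np.allclose(pca.all_eigenvalues, oracle, atol=1e-10)

    def test_orthonormal_basis_and_explained_sums_to_one(self, noisy_cohort):
        _, aligned = noisy_cohort
        B = aligned.pca.eigenvectors
        assert np.abs(B.T @ B - np.eye(B.shape[1])).max() < 1e-10
        ev = aligned.pca.all_eigenvalues
        assert (ev / ev.sum()).sum() == pytest.approx(1.0)
        assert aligned.pca.cumulative_explained >= 0.99

    def test_invalid_retention(self, rng):
        with pytest.raises(ValueError):
            shape_pca(rng.standard_normal((5, 4, 3)), retention=1.5)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a = rng.standard_normal((7, 3))
        b = rng.standard_normal((7, 3))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = rng.standard_normal((3, 6, 3))
            assert procrustes_distance(a, c) <= (
                procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12
            )

    def test_equals_score_space_distance(self, noisy_cohort):
        _, aligned = noisy_cohort
        pca = shape_pca(aligned.sym_coords, retention=1.0)
        i, j = 3, 11
        d_coord = procrustes_distance(aligned.sym_coords[i], aligned.sym_coords[j])
        d_score = np.linalg.norm(pca.scores[i] - pca.scores[j])
        assert d_coord == pytest.approx(d_score, abs=1e-10)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_distance(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))


class TestScoresToShape:
    def test_zero_scores_give_consensus(self, noisy_cohort):
        _, aligned = noisy_cohort
        rec = scores_to_shape(
            np.zeros(aligned.pca.n_components), aligned.pca.eigenvectors, aligned.consensus
        )
        assert np.array_equal(rec, aligned.consensus)

    def test_two_sd_shape_along_pc1(self, noisy_cohort):
        _, aligned = noisy_cohort
        lam1 = aligned.pca.eigenvalues[0]
        v1 = aligned.pca.eigenvectors[:, 0]
        scores = np.zeros(aligned.pca.n_components)
        scores[0] = 2.0 * np.sqrt(lam1)
        rec = scores_to_shape(scores, aligned.pca.eigenvectors, aligned.consensus)
        expected = aligned.consensus + (2.0 * np.sqrt(lam1) * v1).reshape(-1, 3)
        assert np.abs(rec - expected).max() < 1e-12

    def test_dimension_mismatch(self, noisy_cohort):
        _, aligned = noisy_cohort
        with pytest.raises(ValueError):
            scores_to_shape(
                np.zeros(aligned.pca.n_components + 5),
                aligned.pca.eigenvectors,
                aligned.consensus,
            )


class TestAlignCohort:
    def test_unit_centroid_size(self, noisy_cohort):
        _, aligned = noisy_cohort
        # symmetric + asymmetric components recompose the aligned shape of
        # unit centroid size
        total = aligned.sym_coords + aligned.asym_coords
        norms = np.linalg.norm(total.reshape(len(total), -1), axis=1)
        assert np.abs(norms - 1.0).max() < 1e-10

    def test_noise_free_cohort_dimorphism_recovered(self, small_topology):
        spec = noise_free_spec(n_female=8, n_male=8)
        cohort = simulate_cohort(spec, small_topology)
        aligned = align_cohort(cohort.configs, small_topology, retention=1.0)
        # pick closest-aged F/M pair and compare to the generative distance
        gt = cohort.ground_truth
        ages = aligned.ages
        f = np.flatnonzero(aligned.sexes == "F")
        m = np.flatnonzero(aligned.sexes == "M")
        i = f[0]
        j = m[np.argmin(np.abs(ages[m] - ages[i]))]
        mu_f = gt.mean_shape(ages[i], "F")
        mu_m_at_same_ages = gt.mean_shape(ages[i], "M")
        expected = np.linalg.norm(mu_m_at_same_ages - mu_f)
        got = procrustes_distance(
            gt.mean_shape(ages[i], "M"), gt.mean_shape(ages[i], "F")
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(spec.dimorphism(ages[i]), abs=1e-9)
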