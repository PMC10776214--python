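import numpy as np
import pytest

from morphotraj import trajectories as tj
from morphotraj.shape_core import align_cohort
from morphotraj.smoothing import smooth_trend
from morphotraj.synthetic_data import CohortSpec, Constant, Logistic, simulate_cohort

SQRT2PI = np.sqrt(2 * np.pi)


class TestGaussianWeights:
    def test_printed_formula_at_center(self):
        w = tj.gaussian_weights(np.array([7.0]), center=7.0, sigma=2.25)
        assert w[0] == pytest.approx(1.0 / SQRT2PI, rel=1e-15)

    def test_symmetry_about_center(self):
        for d in (0.5, 1.7, 4.0):
            wl = tj.gaussian_weights(np.array([10 - d]), 10.0, 3.0)
            wr = tj.gaussian_weights(np.array([10 + d]), 10.0, 3.0)
            assert wl[0] == pytest.approx(wr[0], rel=1e-15)

    def test_one_sigma_offset(self):
        # direct evaluation of the printed formula at |x - xm| = sigma
        sigma = 3.0
        w = tj.gaussian_weights(np.array([12.0 + sigma]), 12.0, sigma)
        assert w[0] == pytest.approx(np.exp(-0.5) / SQRT2PI, rel=1e-14)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            tj.gaussian_weights(np.arange(3.0), 1.0, 0.0)


class TestWPLS:
    def test_exact_linear_any_weights(self, rng):
        x = rng.uniform(0, 20, 40)
        slopes = np.array([1.5, -0.3, 0.0])
        Y = np.outer(x, slopes) + np.array([2.0, 1.0, -4.0])
        w = rng.uniform(0.01, 5.0, 40)
        fit = tj.wpls_fit(x, Y, w)
        assert np.abs(fit.coef[0] - slopes).max() < 1e-8
        assert np.abs(fit.predict(x[:, None]) - Y).max() < 1e-8

    def test_equal_weights_match_ols_oracle(self, rng):
        x = rng.uniform(0, 10, 30)
        Y = rng.standard_normal((30, 4))
        fit = tj.wpls_fit(x, Y, np.full(30, 0.37))
        A = np.column_stack([np.ones(30), x])
        beta = np.linalg.lstsq(A, Y, rcond=None)[0]
        assert np.abs(fit.coef[0] - beta[1]).max() < 1e-8

    def test_weight_scale_invariance(self, rng):
        x = rng.uniform(0, 10, 25)
        Y = rng.standard_normal((25, 3))
        w = rng.uniform(0.1, 1.0, 25)
        f1 = tj.wpls_fit(x, Y, w)
        f2 = tj.wpls_fit(x, Y, 123.456 * w)
        assert np.abs(f1.coef - f2.coef).max() < 1e-10
        assert np.abs(f1.intercept - f2.intercept).max() < 1e-10

    def test_zero_predictor_variance_flat_fit(self, rng):
        Y = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning, match="flat fit"):
            fit = tj.wpls_fit(np.full(10, 5.0), Y, np.ones(10))
        assert fit.flat
        assert np.all(fit.coef == 0.0)

    def test_multivariate_predictors_reduce_residual(self, rng):
        X = rng.standard_normal((60, 2))
        B = np.array([[1.0, 0.5], [-2.0, 1.0]])
        Y = X @ B + 0.01 * rng.standard_normal((60, 2))
        fit = tj.wpls_fit(X, Y, np.ones(60), n_components=2)
        assert np.abs(fit.coef - B).max() < 0.02


class TestFitTrajectory:
    def test_linear_cs_reproduced(self):
        ages = np.linspace(4, 38, 120)
        cs = 100.0 + 3.0 * ages
        model = tj.fit_trajectory(cs, ages, tj.default_cs_kernel())
        assert np.abs(model.predicted[:, 0] - (100.0 + 3.0 * model.grid)).max() < 1e-8
        assert np.abs(model.rates[:, 0] - 3.0).max() < 1e-8

    def test_rate_magnitude_consistency(self, rng):
        ages = rng.uniform(5, 37, 200)
        Y = rng.standard_normal((200, 6))
        model = tj.fit_trajectory(Y, ages, tj.default_shape_kernel())
        for g in range(0, len(model.grid), 10):
            assert model.rate_magnitudes[g] == pytest.approx(
                tj.rate_magnitude(model.rates[g]), rel=1e-12
            )

    def test_sigma_to_infinity_gives_global_fit(self, rng):
        ages = rng.uniform(5, 37, 100)
        Y = rng.standard_normal((100, 3))
        kern = tj.KernelSpec(sigma=1e6, grid=tj.default_shape_kernel().grid)
        model = tj.fit_trajectory(Y, ages, kern)
        A = np.column_stack([np.ones(100), ages])
        beta = np.linalg.lstsq(A, Y, rcond=None)[0]
        global_pred = beta[0] + np.outer(model.grid, beta[1])
        assert np.abs(model.predicted - global_pred).max() < 1e-6

    def test_logistic_cs_peak_recovery(self, default_topology):
        spec = CohortSpec(
            n_female=400,
            n_male=400,
            age_distribution="uniform",
            scale_range=(0.97, 1.03),
            seed=21,
        )
        cohort = simulate_cohort(spec, default_topology)
        ages = np.array([c.age for c in cohort.configs])
        sexes = np.array([c.sex for c in cohort.configs])
        from morphotraj.shape_core import centroid_size

        cs = np.array([centroid_size(c.coords) for c in cohort.configs])
        for sex in ("F", "M"):
            model = tj.fit_trajectory(cs[sexes == sex], ages[sexes == sex], tj.default_cs_kernel())
            rate = np.where(model.valid, model.rates[:, 0], -np.inf)
            peak = model.grid[np.argmax(rate)]
            assert abs(peak - spec.cs_growth[sex].midpoint) <= 1.0

    def test_masked_points_reported(self):
        ages = np.concatenate([np.full(30, 20.0), np.full(30, 21.0)])
        with pytest.warns(UserWarning, match="masked"):
            model = tj.fit_trajectory(np.ones(60), ages, tj.default_cs_kernel(sigma=1.0))
        assert not model.valid.all()
        assert model.valid[np.argmin(np.abs(model.grid - 20.5))]

    @pytest.mark.filterwarnings("ignore:.*masked.*")
    def test_rate_score_vs_landmark_space(self, noisy_cohort):
        _, aligned = noisy_cohort
        sel = aligned.sexes == "F"
        model = tj.fit_trajectory(
            aligned.scores[sel], aligned.ages[sel], tj.default_shape_kernel()
        )
        g = len(model.grid) // 2
        landmark_rate = aligned.pca.eigenvectors @ model.rates[g]
        assert tj.rate_magnitude(model.rates[g]) == pytest.approx(
            float(np.linalg.norm(landmark_rate)), abs=1e-10
        )


class TestDimorphismProfile:
    def test_power_after_onset(self, mid_topology):
        spec = CohortSpec(
            n_female=300,
            n_male=300,
            dimorphism=Logistic(scale=0.08, midpoint=12.0, rate=0.8),
            age_distribution="uniform",
            seed=31,
        )
        cohort = simulate_cohort(spec, mid_topology)
        aligned = align_cohort(cohort.configs, mid_topology)
        profile = tj.dimorphism_profile(
            aligned.scores, aligned.ages, aligned.sexes,
            tj.default_shape_kernel(), n_perm=199, seed=5,
        )
        late = profile.grid >= 20
        early = profile.grid <= 6
        assert np.all(profile.p_values[late] <= 0.01)
        assert profile.p_values[early].min() > 0.05

    def test_null_is_exchangeable(self, rng):
        # same generative model for both sexes: observed distance is a draw
        # from the permutation null (two-sided KS sanity at tiny scale)
        from scipy.stats import kstest

        kern = tj.KernelSpec(sigma=3.0, grid=np.array([10.0]))
        pvals = []
        for rep in range(60):
            ages = rng.uniform(5, 15, 50)
            scores = rng.standard_normal((50, 2))
            sexes = np.array(["F", "M"])[rng.integers(0, 2, 50)]
            if len(np.unique(sexes)) < 2:
                continue
            prof = tj.dimorphism_profile(scores, ages, sexes, kern, n_perm=99, seed=rep)
            pvals.append(prof.p_values[0])
        # p-values approximately uniform under the null
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_requires_both_sexes(self, rng):
        with pytest.raises(ValueError, match="both sexes"):
            tj.dimorphism_profile(
                rng.standard_normal((10, 2)),
                rng.uniform(5, 15, 10),
                np.array(["F"] * 10),
                tj.default_shape_kernel(),
                n_perm=9,
            )

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            tj.dimorphism_profile(
                rng.standard_normal((10, 2)),
                rng.uniform(5, 15, 10),
                np.array(["F", "M"] * 5),
                tj.default_shape_kernel(),
                n_perm=0,
            )


class TestSmoothTrend:
    def test_exact_linear(self):
        x = np.linspace(0, 10, 50)
        fit = smooth_trend(x, 3.0 * x - 1.0)
        assert np.abs(fit.fitted - (3.0 * x - 1.0)).max() < 1e-6
        assert fit.edf == pytest.approx(1.0, abs=0.1)

    def test_sine_recovery(self, rng):
        x = np.linspace(0, 9, 150)
        noise_sd = 0.25
        y = np.sin(x) + rng.normal(0, noise_sd, 150)
        fit = smooth_trend(x, y)
        rmse = float(np.sqrt(np.mean((fit.fitted - np.sin(x)) ** 2)))
        assert rmse < noise_sd

    def test_constant_flat_fit(self):
        x = np.linspace(0, 5, 30)
        fit = smooth_trend(x, np.full(30, 2.5))
        assert np.abs(fit.fitted - 2.5).max() < 1e-9
        assert fit.p_value > 0.9

    def test_small_n_reduces_basis_with_warning(self, rng):
        x = np.linspace(0, 1, 11)
        y = x + 0.01 * rng.standard_normal(11)
        with pytest.warns(UserWarning, match="reducing basis"):
            smooth_trend(x, y, n_basis=25)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_trend(np.arange(5.0), np.arange(5.0))


class TestKernelSpec:
    def test_default_ranges(self):
        cs = tj.default_cs_kernel()
        sh = tj.default_shape_kernel()
        assert cs.sigma == 2.25 and sh.sigma == 3.0
        assert cs.grid[0] == 4.0 and cs.grid[-1] == 38.0
        assert sh.grid[0] == 5.0 and sh.grid[-1] == 37.0
        assert np.allclose(np.diff(cs.grid), 0.5)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            tj.KernelSpec(sigma=1.0, grid=np.array([3.0, 2.0]))
        with pytest.raises(ValueError):
            tj.KernelSpec(sigma=-1.0, grid=np.array([1.0, 2.0]))
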