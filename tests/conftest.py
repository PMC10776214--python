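import numpy as np
import pytest

from morphotraj.synthetic_data import CohortSpec, Constant, make_template, simulate_cohort


@pytest.fixture(scope="session")
def small_topology():
    """Tiny template (resolution 3, L = 35) for fast tests."""
    return make_template(3)


@pytest.fixture(scope="session")
def mid_topology():
    """Moderate template (resolution 4, L = 54)."""
    return make_template(4)


@pytest.fixture(scope="session")
def default_topology():
    """Default desk-scale template (L = 299)."""
    return make_template(11)


def noise_free_spec(**overrides) -> CohortSpec:
    base = dict(
        n_female=6,
        n_male=6,
        baseline_sd=0.0,
        diversify_curve=Constant(0.0),
        asymmetry_sd=0.0,
        seed=11,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def noisy_cohort(mid_topology):
    """A small noisy cohort plus its alignment, shared across tests."""
    from morphotraj.shape_core import align_cohort

    spec = CohortSpec(n_female=40, n_male=40, seed=7)
    cohort = simulate_cohort(spec, mid_topology)
    aligned = align_cohort(cohort.configs, mid_topology)
    return cohort, aligned


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
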