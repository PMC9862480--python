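import numpy as np
import pytest

from walppo import CohortSpec, PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def mixed_phantom():
    """One 32^3 phantom with all three compartments present in every lobe."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), seed=11).with_uniform_fractions(
        0.15, 0.75, 0.10
    )
    ct, lobes, truth = make_phantom(spec)
    return spec, ct, lobes, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    """sigma = 0 cohort: measured post-op values equal the WAL prediction."""
    return make_cohort(CohortSpec(n_patients=40, sigma=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
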