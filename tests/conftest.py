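import numpy as np
import pytest

from somatomap import synth, travelwave as tw
from somatomap.design import DesignSpec

SMALL_GRID = (10, 8, 4)


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def bank(design):
    return tw.build_reference_models(design)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return synth.CohortConfig(
        grid_shape=SMALL_GRID,
        noise=synth.NoiseParams(sigma=0.0),
        scatter_preferences=False,
    )


@pytest.fixture(scope="session")
def noisy_cfg():
    return synth.CohortConfig(grid_shape=SMALL_GRID, noise=synth.NoiseParams(sigma=0.5))


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_cfg):
    """One noiseless control with all runs, plus its ground truth."""
    ds = synth.generate_cohort(1, 0, 0, noiseless_cfg, seed=11)
    s = ds.subjects[0]
    return ds, s, ds.truths[s.subject_id]


@pytest.fixture(scope="session")
def noisy_cohort(noisy_cfg):
    """Small mixed cohort with noise, shared across RSA/stats tests."""
    return synth.generate_cohort(3, 3, 2, noisy_cfg, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
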