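import numpy as np
import pytest

from epitraject.quantify import build_density_matrix
from epitraject.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 31-sample, 2000-region synthetic cohort (seed 1)."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_density(default_cohort):
    """Density matrix of the default cohort over its planted regions."""
    cfg = default_cohort.config
    chip = {
        s.sample_id: default_cohort.readsets[s.sample_id]
        for s in cfg.chip_samples
    }
    return build_density_matrix(chip, default_cohort.regions,
                                default_cohort.promoters())


@pytest.fixture(scope="session")
def default_ages(default_cohort):
    return default_cohort.config.ages


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
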