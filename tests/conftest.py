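import numpy as np
import pytest

from callothick.masks import make_arch_mask, make_band_mask
from callothick.simulate import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def band_mask():
    return make_band_mask(6.0, 60.0, 0.25)


@pytest.fixture(scope="session")
def arch_mask():
    return make_arch_mask(10.0, 14.0, 0.25)


@pytest.fixture(scope="session")
def small_cohort():
    """200 + 200 subjects with the default planted crossover at 25 years."""
    cfg = SyntheticCohortConfig(n_patients=200, n_controls=200, seed=11)
    cohort, profiles, symptoms, truth = simulate_cohort(cfg)
    return cfg, cohort, profiles, symptoms, truth


@pytest.fixture(scope="session")
def plsc_cohort():
    """Patient-heavy cohort with a strong planted brain-symptom latent."""
    cfg = SyntheticCohortConfig(
        n_patients=137, n_controls=10, symptom_latent_strength=0.8, seed=5
    )
    cohort, profiles, symptoms, truth = simulate_cohort(cfg)
    return cfg, cohort, profiles, symptoms, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
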