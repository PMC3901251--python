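import numpy as np
import pytest

from specnet import CohortConfig, fit_dataset, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort that keeps the full hub/partner structure."""
    return CohortConfig(
        n_bins=60,
        m_control=10,
        m_disease=10,
        n_hubs=2,
        partners_per_hub=8,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return fit_dataset(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
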