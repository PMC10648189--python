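import numpy as np
import pytest

from fedlnm import cohort as ch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact seeded cohort with full modality coverage."""
    cfg = ch.CohortConfig(n_cc=60, n_ec=20, prevalence_cc=0.3, prevalence_ec=0.2,
                          modality_coverage={m: 1.0 for m in ch.MODALITIES}, seed=7)
    return ch.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-signal cohort used by the federated experiments."""
    return ch.generate_cohort(ch.federated_config(seed=3))
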