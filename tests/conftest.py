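import pytest

from metabosem.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig.default()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Default 137-subject cohort at a fixed seed, shared across tests."""
    return generate_cohort(default_config, seed=1)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """The same calibration scaled ~7.3x (n = 999) for large-n checks."""
    return generate_cohort(default_config.scaled(7.3), seed=2)
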