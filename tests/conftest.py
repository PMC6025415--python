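import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdompae import synthetic
from cdompae.dataio import EEMGrid, default_eem_axes

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_axes():
    return default_eem_axes()


@pytest.fixture
def uniform_eem(default_axes):
    ex, em = default_axes
    return EEMGrid(ex, em, np.ones((ex.size, em.size)), sample_id="uniform")


@pytest.fixture(scope="session")
def cohort_seed1():
    """One default 45-sample cohort, shared across tests."""
    return synthetic.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def fri_table_seed1(cohort_seed1):
    """Preprocessed FRI + PAE table of the shared cohort."""
    return synthetic.cohort_fri_table(cohort_seed1)
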