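import numpy as np
import pytest

from digibrain import CohortConfig, run_qc, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully realistic cohort: 8 subjects, 7 tests per type."""
    cohort = simulate_cohort(CohortConfig(n_subjects=8, seed=11))
    run_qc(cohort.records)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
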