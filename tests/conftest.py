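import numpy as np
import pytest

from gatsurv.cohort import CohortConfig, generate_cohort


SMALL_CONFIG = CohortConfig(
    n_samples=150,
    block_sizes={"mrna": 60, "mirna": 20, "meth": 40, "clinical": 11},
    n_informative={"mrna": 5, "mirna": 3, "meth": 4},
    seed=3,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample, 131-feature cohort shared across tests (read-only)."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference-design cohort: n=600, 2000 features, 50 informative."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
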