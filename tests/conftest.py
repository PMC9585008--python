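import numpy as np
import pytest

from oliguard import amsterdam_like, generate_cohort, prepare_cohort


@pytest.fixture(scope="session")
def cohort_2000():
    """One 2,000-patient high-frequency-regime cohort shared across tests."""
    return generate_cohort(amsterdam_like(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def prepared_2000(cohort_2000):
    """The shared cohort carried through preprocessing, labeling, windowing."""
    return prepare_cohort(cohort_2000, "shared")


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
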