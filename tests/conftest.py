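import numpy as np
import pytest

from tfscan.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A 500-genome cohort under the generator's default conditions."""
    return generate_cohort(CohortSpec(n_genomes=500, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 60-genome cohort for I/O and CLI tests."""
    return generate_cohort(CohortSpec(n_genomes=60, seed=5, n_background=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
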