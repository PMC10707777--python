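import numpy as np
import pytest

from chronoprof import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 60-patient cohort plus its truth records."""
    return generate_cohort(GeneratorConfig(n=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
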