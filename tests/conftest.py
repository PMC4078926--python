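import numpy as np
import pytest

import audlex


@pytest.fixture
def rng():
    return np.random.default_rng(20140702)


@pytest.fixture(scope="session")
def default_spec():
    return audlex.default_cohort_spec()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """One study-sized cohort (54 NR / 36 DYS) from the shipped spec."""
    return audlex.generate_cohort(default_spec, seed=11)
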