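import numpy as np
import pytest

from lesionfield import make_cohort, make_toy_atlas


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(seed=5)


@pytest.fixture(scope="session")
def cohort35():
    """One default synthetic study cohort, shared across test modules."""
    return make_cohort(n=35, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
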