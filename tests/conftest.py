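import numpy as np
import pytest
from hypothesis import settings

from lvcoupling import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.SyntheticSpec(n_entities=16, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return synthetic.generate_province_panel(small_spec)


@pytest.fixture(scope="session")
def small_adjacency(small_spec):
    return synthetic.generate_adjacency(small_spec)
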