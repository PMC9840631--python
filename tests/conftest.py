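import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arena():
    from chemonav.behavior import ArenaGeometry

    return ArenaGeometry()
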