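import numpy as np
import pytest

from afloc.atrial_sim import build_synthetic_atria


@pytest.fixture(scope="session")
def small_mesh():
    """256-node mesh shared by fast unit tests."""
    return build_synthetic_atria(256, rng_seed=7)


@pytest.fixture(scope="session")
def mesh2048():
    """Default-sized mesh (built once; several tests assert on it)."""
    return build_synthetic_atria(2048, rng_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
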