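import numpy as np
import pytest

from spatialforces.simulate import make_fixture_slide, random_forces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_slide():
    """16-cell, 4-gene grid slide."""
    return make_fixture_slide(16, 4, geometry="grid", seed=7)


@pytest.fixture
def forces4():
    return random_forces(4, scale=1.0, seed=3)


@pytest.fixture
def random_state_5x3(rng):
    S = rng.uniform(0.0, 1.0, (5, 3))
    return S / np.linalg.norm(S, axis=1, keepdims=True)
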