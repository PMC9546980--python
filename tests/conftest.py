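import numpy as np
import pytest

from mitoseg.synthetic import FixtureSpec, make_volume


@pytest.fixture(scope="session")
def em_fixture():
    """One deterministic synthetic EM volume with labels, shared by tests."""
    return make_volume(FixtureSpec(shape=(12, 96, 96), n_organelles=6, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
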