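import numpy as np
import pytest

import limbscale as ls


@pytest.fixture(scope="session")
def fixture_data():
    """Bundled 44-species table + synthetic composite tree."""
    return ls.bundled_fixture()


@pytest.fixture(scope="session")
def yule44():
    """A 44-tip Yule tree shared across statistical tests."""
    return ls.simulate_tree(44, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
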