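import numpy as np
import pytest

import moodchoice as mc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid():
    return mc.build_grids()


@pytest.fixture(scope="session")
def linear_model():
    """Indifference model whose curve is exactly r* = 1 - C."""
    return mc.IndifferenceModel(b0=0.0, k=np.ones(5))
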