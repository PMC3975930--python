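import numpy as np
import pytest

from sffalign.models import (MotifLibrary, SffModel, SunflowerParams,
                             ThreeStateParams, build_three_state)


@pytest.fixture(scope="session")
def three_state_model():
    return build_three_state(ThreeStateParams())


@pytest.fixture(scope="session")
def tiny_library():
    return MotifLibrary([("AC", 0.75), ("G", 0.25)])


@pytest.fixture(scope="session")
def tiny_sff(tiny_library):
    return SffModel(tiny_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
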