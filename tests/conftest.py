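import numpy as np
import pytest

from tectomap.stimulus import build_protocol, build_regressors


@pytest.fixture(scope="session")
def protocol():
    return build_protocol(frame_rate=5.0)


@pytest.fixture(scope="session")
def regressors(protocol):
    return build_regressors(protocol, frame_rate=5.0, tau=7.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
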