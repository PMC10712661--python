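import numpy as np
import pytest

from emophys import protocol as proto


@pytest.fixture
def default_schedule():
    return proto.build_schedule()


@pytest.fixture
def small_protocol_config():
    """Reduced timeline for fast end-to-end tests."""
    return proto.ProtocolConfig(initial_rest_s=30.0, neutral_s=30.0,
                                n_arousal_sessions=2, interphase_rest_s=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
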