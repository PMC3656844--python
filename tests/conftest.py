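import numpy as np
import pytest

from thetaflow.presets import TWO_NODE_PRESETS, two_node_preset


@pytest.fixture(params=sorted(TWO_NODE_PRESETS))
def two_node_name(request):
    return request.param


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def preset_pair(name):
    """(RateSystem, input) for a canonical two-node flow."""
    return two_node_preset(name)
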