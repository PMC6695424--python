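import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twitchindex import FrameStack, GateConfig
from twitchindex.simkit import GATE_MARKERS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def gate_thresholds():
    return {m: 100.0 for m in GATE_MARKERS}


@pytest.fixture
def gate_config(gate_thresholds):
    return GateConfig(thresholds=gate_thresholds)


@pytest.fixture
def static_stack():
    """A noiseless, perfectly static stack."""
    return FrameStack(np.full((40, 16, 16), 0.3), fps=10.0)
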