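"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# one deterministic profile for the whole suite: bounded examples, no
# wall-clock deadline (FFT-heavy properties), fully derandomized
settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
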