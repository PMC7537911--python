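import numpy as np
import pytest

from caosc import CONTROL, integrate


@pytest.fixture(scope="session")
def control():
    return CONTROL


@pytest.fixture(scope="session")
def oscillating_trace():
    """One deterministic oscillation at mid load, shared across tests."""
    return integrate("fast_ryr", 54.0, t_end_ms=4000.0, kick=5.0,
                     sample_ms=0.25)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
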