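import numpy as np
import pytest

from metaspe import DesignParams, ObserverParams, simulate_subject


@pytest.fixture
def design():
    return DesignParams()


@pytest.fixture
def observer():
    """Noise-free-metacognition observer with no lapses or misses."""
    return ObserverParams(sigma_p=12.0, lapse=0.0, sigma_m=0.0, miss_rate=0.0)


@pytest.fixture
def default_observer():
    return ObserverParams()


@pytest.fixture(scope="session")
def subject_data():
    """One fully simulated subject (all three sessions), shared read-only."""
    rng = np.random.default_rng(42)
    params = ObserverParams(sigma_p=12.0, lapse=0.0, miss_rate=0.02)
    return simulate_subject(params, DesignParams(), rng, subject="s01")
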