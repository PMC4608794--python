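import numpy as np
import pytest

import eodloop as el


@pytest.fixture(scope="session")
def default_params():
    return el.FishParams()


@pytest.fixture(scope="session")
def short_pair(default_params):
    """One 2-minute closed-loop experiment at a short delay (strong effect)."""
    proto = el.ProtocolConfig(delay_ms=22, control_min=2, stim_min=2, seed=11)
    return el.simulate_closed_loop(default_params, proto)


@pytest.fixture(scope="session")
def long_pair(default_params):
    """One 2-minute closed-loop experiment at a long delay (weak effect)."""
    proto = el.ProtocolConfig(delay_ms=202, control_min=2, stim_min=2, seed=12)
    return el.simulate_closed_loop(default_params, proto)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def nearest_distance(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distance from each query time to the nearest reference time."""
    if ref.size == 0:
        return np.full(query.size, np.inf)
    idx = np.clip(np.searchsorted(ref, query), 1, ref.size - 1)
    return np.minimum(np.abs(ref[idx] - query), np.abs(ref[idx - 1] - query))
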