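import numpy as np
import pytest

from hybrot import (
    CultureConfig,
    ElectrodeLayout,
    build_culture,
    simulate_window,
)


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout.mea_8x8(modular=True)


@pytest.fixture(scope="session")
def make_culture(layout):
    """Factory for settled cultures (10 s transient discarded)."""

    def _make(topology="modular", seed=0, settle=10.0, **overrides):
        config = CultureConfig(seed=seed, topology=topology, **overrides)
        state = build_culture(config, layout)
        if settle:
            simulate_window(state, settle)
        return state

    return _make


@pytest.fixture(scope="session")
def spont_modular(make_culture):
    """300 s of spontaneous modular-culture activity (shared, read-only)."""
    culture = make_culture(topology="modular", seed=3)
    return simulate_window(culture, 300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
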