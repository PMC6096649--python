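import numpy as np
import pytest

from deltabeta.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def base_cfg():
    """Study-sized configuration: 8-s epochs at 512 Hz."""
    return SimulationConfig(seed=11)


@pytest.fixture
def fast_cfg():
    """Short epochs (2 s, five delta cycles) for structural tests."""
    return SimulationConfig(epoch_duration=2.0, seed=11)
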