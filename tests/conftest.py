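import numpy as np
import pytest

from yapkmc import LatticeGeometry, SimulationConfig


@pytest.fixture
def geom():
    return LatticeGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline():
    """Baseline parameter set with a short desk budget."""
    return SimulationConfig(steps=50_000, record_every=1000, seed=7)
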