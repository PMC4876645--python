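import numpy as np
import pytest

import spikepert as sp
from spikepert.simulate import AreaSpec, SimConfig


@pytest.fixture(scope="session")
def kernel():
    return sp.make_kernel()


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-area dataset shared by structural tests."""
    areas = [
        AreaSpec("early", 8, 15.0, 20.0, 150.0),
        AreaSpec("late", 8, 15.0, 60.0, 150.0),
    ]
    sim = SimConfig(areas=areas, seed=5)
    return sp.simulate_population(sim, tasks=("posture", "movie"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
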