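import numpy as np
import pytest
from hypothesis import settings

import minipsc as mp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

FS = 40_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    """The standard analysis template: 0.44 / 6.12 ms at 40 kHz."""
    return mp.build_kernel(0.44, 6.12, FS)


@pytest.fixture(scope="session")
def sim_wave():
    """One default simulated wave (40 events, 9.9 s) with its ground truth."""
    spec = mp.SimulationSpec(seed=7)
    trace, truth = mp.synthesize(spec)
    return trace, truth


@pytest.fixture(scope="session")
def detected_wave(sim_wave):
    """Detection chain run once on the simulated wave: (trace, truth, result)."""
    from minipsc.pipeline import RunConfig, detect_wave

    trace, truth = sim_wave
    result = detect_wave(trace, RunConfig(criterion="none"))
    return trace, truth, result
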