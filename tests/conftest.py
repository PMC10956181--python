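import numpy as np
import pytest

from bppvnet.simulate import SimulatorConfig, generate_case


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small frames, deterministic rendering (no fixation jitter)."""
    return SimulatorConfig(frame_size=(16, 16), jitter_sigma_px=0.0)


@pytest.fixture(scope="session")
def rendered_case(tiny_sim_config):
    return generate_case("left-posterior", seed=7, config=tiny_sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
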