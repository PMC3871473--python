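import numpy as np
import pytest

from cardiopower.hemo_sim import SimConfig, default_animal, simulate_record


@pytest.fixture(scope="session")
def base_animal():
    return default_animal()


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noise-free simulation config with a fixed seed."""
    return SimConfig(seed=42).noise_free()


@pytest.fixture(scope="session")
def baseline_sim(base_animal, quiet_cfg):
    """Noise-free baseline record with internal signals, simulated once."""
    record, internals = simulate_record(base_animal, None, quiet_cfg, full_output=True)
    return record, internals


@pytest.fixture(scope="session")
def baseline_record(baseline_sim):
    return baseline_sim[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
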