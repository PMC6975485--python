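import numpy as np
import pytest

from epsckit import synthgen as sg


@pytest.fixture
def default_config():
    return sg.SimulationConfig(seed=42)


@pytest.fixture
def clean_config():
    """Noiseless, artifact-free configuration for deterministic fixtures."""
    return sg.SimulationConfig(seed=7, noise_sd=0.0, artifact_amplitude=0.0,
                               amplitude_floor=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
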