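import numpy as np
import pytest

from anfsim.config import ExperimentConfig
from anfsim.experiment import setup_for_electrode
from anfsim.membrane import build_fiber
from anfsim.stimulus_field import make_waveform


@pytest.fixture(scope="session")
def config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def cable(config):
    return build_fiber(config.morphology, config.membrane)


@pytest.fixture(scope="session")
def single_pulse_waveform(config):
    return make_waveform(
        "single_pulse", 1.0, config.protocol.phase_us,
        duration=2.5, sample_step=config.protocol.dt_us,
    )


@pytest.fixture(scope="session")
def electrode_setups(config):
    """(cable, profile) per electrode label, built once per session."""
    return {el: setup_for_electrode(config, el) for el in "ABCD"}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150210)
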