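import numpy as np
import pytest

from cartt2.phantom import PhantomConfig, build_true_t2, synthesize_echoes
from cartt2.protocol import EchoSchedule


@pytest.fixture
def schedule():
    return EchoSchedule()


@pytest.fixture
def noiseless_config():
    """Flat-surface, noise-free control phantom with zero drift."""
    return PhantomConfig(group="CONT", noise_model="none",
                         undulation_amplitude_px=0, drift=(0.0, 0.0, 0.0, 0.0))


@pytest.fixture
def noiseless_sample(noiseless_config, schedule):
    truth = build_true_t2(noiseless_config, "t0")
    series = synthesize_echoes(truth, schedule, sample_id="S01")
    return truth, series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
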