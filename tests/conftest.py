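import numpy as np
import pytest

from apneamap import BreathModelParams, ScoringConfig, StimEpoch


@pytest.fixture
def clean_params():
    """Noiseless, drift-free breathing model (period 4 s, unit amplitude)."""
    return BreathModelParams(noise_sd=0.0, drift_sd=0.0)


@pytest.fixture
def noisy_params():
    """Default realistic breathing model (5% amplitude noise, slow drift)."""
    return BreathModelParams()


@pytest.fixture
def config():
    return ScoringConfig()


@pytest.fixture
def epoch():
    """A 30 s stimulation epoch after a 60 s baseline."""
    return StimEpoch(start=60.0, end=90.0)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
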