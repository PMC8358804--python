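import numpy as np
import pytest

from efferentquant.abr import Waveform
from efferentquant.synthetic import ABRSimConfig, CochleaSimConfig, simulate_abr_series


@pytest.fixture
def flat_waveform():
    """10 ms of exact zeros at the default 24.4 kHz sampling rate."""
    t = np.arange(245) / 24.4
    return Waveform(time_ms=t, voltage_uv=np.zeros_like(t), level_db=50.0)


@pytest.fixture
def noisy_series():
    """Default simulated series (true threshold 30 dB), deterministic."""
    series, truth = simulate_abr_series(ABRSimConfig(seed=7))
    return series, truth


@pytest.fixture
def sham_frame():
    """One deterministic sham-condition OHC field with ground truth."""
    from efferentquant.synthetic import simulate_cochlea_image

    return simulate_cochlea_image(CochleaSimConfig(seed=11), 11.3)
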