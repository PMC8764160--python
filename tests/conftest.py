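import math

import numpy as np
import pytest

from mstates import (
    SimulationConfig,
    simulate_recording,
)
from mstates.preprocess import average_reference, bandpass_filter


def true_mean_run_ms(labels: np.ndarray, fs: float) -> float:
    """Oracle: mean constant-label run length in ms by direct RLE."""
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return float(np.diff(bounds).mean() / fs * 1000.0)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic recording (32 ch, 250 Hz, 30 s, snr 4)."""
    cfg = SimulationConfig(n_channels=32, sampling_rate_hz=250,
                           duration_s=30, snr=4.0, seed=101)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimulationConfig(n_channels=32, sampling_rate_hz=250,
                           duration_s=20, snr=math.inf, seed=102)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_prepped(small_sim):
    """Band-passed, average-referenced view of the small recording."""
    return average_reference(bandpass_filter(small_sim.recording))
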