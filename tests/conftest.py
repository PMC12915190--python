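import numpy as np
import pytest

from photomics.photometry import CorrectedTrace, PhotometryRecording
from photomics.synthgen import (
    GroundTruthEvents,
    PhotometrySimParams,
    simulate_photometry,
)


@pytest.fixture
def flat_recording() -> PhotometryRecording:
    """Noiseless recording with a sloped control channel and no transients."""
    fs = 20.0
    t = np.arange(int(60 * fs)) / fs
    control = 100.0 - 0.01 * t
    return PhotometryRecording(time=t, f_signal=control.copy(),
                               f_control=control, sampling_rate=fs)


@pytest.fixture
def clean_sim():
    """Noiseless 600 s simulation with 3 well-separated planted transients."""
    params = PhotometrySimParams(
        duration=600.0, sampling_rate=20.0, event_rate=0.0,
        noise_sd=0.0, artifact_sd=0.0,
        bleach_tau_signal=3000.0, bleach_tau_control=3000.0, seed=1,
    )
    truth = GroundTruthEvents(
        onset_times=[100.0, 300.0, 500.0],
        amplitudes=[0.05, 0.05, 0.05],
        decay_tau=1.0,
    )
    rec, truth = simulate_photometry(params, events=truth)
    return params, rec, truth


def make_trace(dff, fs=20.0) -> CorrectedTrace:
    dff = np.asarray(dff, dtype=float)
    t = np.arange(len(dff)) / fs
    return CorrectedTrace(dff=dff, time=t, sampling_rate=fs)
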