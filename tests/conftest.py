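import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from thetaload import (
    CognitiveLoadDetector,
    DetectorConfig,
    PeriodFrame,
    RawRecording,
    SyntheticSpec,
    synthesize,
)

# frozen study conditions for the synthetic-recovery fixtures
STUDY_SEED = 2025


def make_frame(samples, prev_last=None, channel=0, index=1, start_s=0.0):
    samples = np.asarray(samples, dtype=float)
    if prev_last is None:
        prev_last = samples[0]
    return PeriodFrame(channel=channel, index=index, samples=samples,
                       prev_last=float(prev_last), start_s=start_s)


@pytest.fixture(scope="session")
def study_recording():
    """The frozen intermittent-load study recording: 8 channels at 1024 Hz,
    three responsive, bursts in (10,30),(40,60),(70,90), no spikes."""
    spec = SyntheticSpec(seed=STUDY_SEED, spike_rate_per_min=0.0)
    return synthesize(spec)


@pytest.fixture(scope="session")
def study_detection(study_recording):
    rec, profile, ann = study_recording
    det = CognitiveLoadDetector(t_start_s=0.0)
    trace = det.fit_predict(rec)
    return det, trace, profile, ann


@pytest.fixture(scope="session")
def background_recording():
    """Background-only recording (no bursts, no spikes): 4 channels, 40 s."""
    spec = SyntheticSpec(seed=STUDY_SEED + 500, n_channels=4, duration_s=40.0,
                         intervals=[], responsive_channels=[],
                         spike_rate_per_min=0.0)
    rec, profile, ann = synthesize(spec)
    return rec


def pink_recording(seed=0, n_channels=2, duration_s=20.0, fs=512.0):
    """Small pink-noise recording for unit tests."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    data = np.empty((n_channels, n))
    f = np.fft.rfftfreq(n, 1 / fs)
    f[0] = f[1]
    for i in range(n_channels):
        spec = np.fft.rfft(rng.standard_normal(n)) * f**-0.5
        data[i] = np.fft.irfft(spec, n)
    labels = [f"C{i}" for i in range(n_channels)]
    return RawRecording(samples=data, fs=fs, labels=labels)
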