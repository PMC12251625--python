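"""Synthetic multichannel EEG with ground-truth task structure.

Each channel is a sum of independent components:

* 1/f^beta background noise (beta = 1, pink, by default) scaled to a target
  RMS — the stand-in for ongoing broadband cortical activity;
* a slow sinusoidal drift below 2 Hz, emulating electrode/baseline wander;
* on responsive channels only, a theta oscillation (default 4.5 Hz) whose
  amplitude rises from zero with cosine ramps inside each load interval —
  the load response the detector is meant to find.  The burst is scaled
  against the background's own 4-5 Hz content: its amplitude is
  ``burst_ratio`` times the background's in-band RMS, elevating the band
  energy during load by the factor 1 + burst_ratio^2 / 2.  Scaling against
  the broadband RMS instead would make the burst tens of times the resting
  in-band peak, which the spike guard would (correctly) treat as an
  artifact rather than a load response;
* sporadic brief spike transients at random times — the artifact class the
  spike guard targets.

The generator is fully determined by ``seed``; identical specs produce
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import write_recording, write_task_profile
from .types import RawRecording, TaskProfile

#: 10-10 montage labels used for generated channels (first 64 positions)
MONTAGE_1010 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults reproduce the intermittent-task
    study layout (10 s initial rest, three 20 s rounds with 10 s breaks)."""

    n_channels: int = 8
    fs: float = 1024.0
    duration_s: float = 95.0
    intervals: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 30.0), (40.0, 60.0), (70.0, 90.0)]
    )
    responsive_channels: list[int] = field(default_factory=lambda: [0, 1, 2])
    background_beta: float = 1.0
    background_rms: float = 20.0      # uV
    burst_freq_hz: float = 4.5
    burst_ratio: float = 3.0          # burst amplitude / background in-band RMS
    ramp_s: float = 0.5
    drift_amp: float = 30.0           # uV
    drift_freq_hz: float = 0.3
    spike_rate_per_min: float = 2.0
    spike_ratio: float = 10.0         # spike amplitude / background RMS
    spike_width_s: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValidationError("need at least one channel")
        if not 0 < self.burst_freq_hz < self.fs / 2:
            raise ValidationError("burst frequency must lie in (0, fs/2)")
        if self.drift_freq_hz >= 2.0:
            raise ValidationError("drift frequency must stay below 2 Hz")
        if any(c < 0 or c >= self.n_channels for c in self.responsive_channels):
            raise ValidationError("responsive_channels outside the channel range")
        for a, b in self.intervals:
            if not 0 <= a < b <= self.duration_s:
                raise ValidationError(
                    f"interval [{a}, {b}) outside the {self.duration_s} s recording"
                )


def _pink_noise(n: int, fs: float, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, unit RMS."""
    white = rng.standard_normal(n)
    if beta == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        f[0] = f[1] if n > 1 else 1.0  # avoid the DC pole
        spec *= f ** (-beta / 2.0)
        x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_rms(x: np.ndarray, fs: float, low: float = 4.0, high: float = 5.0) -> float:
    """RMS of the component of ``x`` inside [low, high] Hz (FFT mask)."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    power = np.abs(spec) ** 2
    band = (f >= low) & (f <= high)
    return float(np.sqrt(power[band].sum() / power.sum()) * x.std())


def _burst_envelope(t: np.ndarray, intervals, ramp_s: float) -> np.ndarray:
    """Trapezoidal 0..1 envelope: cosine ramps of ramp_s inside each interval."""
    env = np.zeros_like(t)
    for a, b in intervals:
        ramp = min(ramp_s, (b - a) / 2.0)
        inside = (t >= a) & (t < b)
        e = np.ones(inside.sum())
        ti = t[inside]
        if ramp > 0:
            up = ti < a + ramp
            down = ti >= b - ramp
            e[up] = 0.5 * (1 - np.cos(np.pi * (ti[up] - a) / ramp))
            e[down] = 0.5 * (1 - np.cos(np.pi * (b - ti[down]) / ramp))
        env[inside] = np.maximum(env[inside], e)
    return env


def synthesize(spec: SyntheticSpec) -> tuple[RawRecording, TaskProfile, dict]:
    """Generate a recording, its task profile, and ground-truth annotations.

    Annotations hold the burst spans per responsive channel and the injected
    spike times per channel.  With ``background_rms == 0`` the burst amplitude
    is ``burst_ratio`` absolutely (pure-tone construction) and spikes use a
    reference RMS of 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    ref_rms = spec.background_rms if spec.background_rms > 0 else 1.0
    data = np.zeros((spec.n_channels, n))
    env = _burst_envelope(t, spec.intervals, spec.ramp_s)
    spike_times: dict[int, list[float]] = {}

    for ch in range(spec.n_channels):
        x = np.zeros(n)
        sigma_band = 0.0
        if spec.background_rms > 0:
            bg = spec.background_rms * _pink_noise(n, spec.fs, spec.background_beta, rng)
            sigma_band = _band_rms(bg, spec.fs)
            x += bg
        if spec.drift_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += spec.drift_amp * np.sin(2 * np.pi * spec.drift_freq_hz * t + phase)
        if ch in spec.responsive_channels and spec.burst_ratio > 0:
            phase = rng.uniform(0, 2 * np.pi)
            amp = spec.burst_ratio * (sigma_band if sigma_band > 0 else 1.0)
            x += amp * env * np.sin(2 * np.pi * spec.burst_freq_hz * t + phase)
        times: list[float] = []
        if spec.spike_rate_per_min > 0:
            n_spikes = rng.poisson(spec.spike_rate_per_min * spec.duration_s / 60.0)
            width = max(spec.spike_width_s, 2.0 / spec.fs)
            for _ in range(n_spikes):
                t0 = rng.uniform(0, spec.duration_s)
                amp = spec.spike_ratio * ref_rms * rng.choice([-1.0, 1.0])
                x += amp * np.exp(-0.5 * ((t - t0) / (width / 2.0)) ** 2)
                times.append(t0)
        spike_times[ch] = sorted(times)
        data[ch] = x

    labels = [MONTAGE_1010[i % len(MONTAGE_1010)] +
              ("" if i < len(MONTAGE_1010) else f"_{i // len(MONTAGE_1010)}")
              for i in range(spec.n_channels)]
    rec = RawRecording(samples=data, fs=spec.fs, labels=labels)
    profile = TaskProfile(intervals=list(spec.intervals))
    annotations = {
        "burst_spans": {ch: list(spec.intervals) for ch in spec.responsive_channels},
        "spike_times": spike_times,
        "responsive_labels": [labels[c] for c in spec.responsive_channels],
        "seed": spec.seed,
        "noise_algorithm": "numpy-PCG64/rfft-1-over-f",
    }
    return rec, profile, annotations


def make_fixture_suite(out_dir: str | Path, base: SyntheticSpec | None = None) -> dict:
    """Write the three canonical test recordings with their profiles.

    * ``no_load`` — rest only, no intervals (reference/background run);
    * ``continuous`` — five back-to-back rounds, one merged 50 s interval;
    * ``intermittent`` — three 20 s rounds separated by 10 s breaks.

    All begin with the 10 s initial rest span used for calibration.  Returns a
    mapping of fixture name to its file paths and annotations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base or SyntheticSpec()
    layouts = {
        "no_load": ([], 65.0, 0),
        "continuous": ([(10.0, 60.0)], 65.0, 1),
        "intermittent": ([(10.0, 30.0), (40.0, 60.0), (70.0, 90.0)], 95.0, 2),
    }
    suite: dict[str, dict] = {}
    for name, (intervals, dur, offset) in layouts.items():
        spec = replace(base, intervals=intervals, duration_s=dur,
                       seed=base.seed + offset)
        rec, profile, ann = synthesize(spec)
        rec_path = write_recording(out_dir / f"{name}.edf", rec)
        prof_path = write_task_profile(out_dir / f"{name}_profile.csv", profile)
        suite[name] = {"recording": rec_path, "profile": prof_path,
                       "annotations": ann}
    return suite
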