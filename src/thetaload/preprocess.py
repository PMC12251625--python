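"""Signal conditioning: normalization, drift removal, narrowband filtering,
and segmentation into nominal periods.

The pipeline order is fixed: z-score + max-abs normalization, subtraction of
the sub-2-Hz slow component, causal FIR bandpass into the analysis band, then
segmentation of the group-delay-corrected signal into frames of one nominal
period each.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ConfigurationError, TooShortError
from .types import BandSpec, PeriodFrame, RawRecording

#: sampling rate at which the reference FIR order is specified
_REFERENCE_FS = 8192.0


def normalize(rec: RawRecording) -> RawRecording:
    """Per-channel z-score followed by max-abs rescaling into [-1, 1].

    A constant channel has zero variance and maps to all zeros.
    """
    out = np.empty_like(rec.samples)
    for i, ch in enumerate(rec.samples):
        sd = ch.std()
        if sd == 0:
            out[i] = 0.0
            continue
        z = (ch - ch.mean()) / sd
        out[i] = z / np.abs(z).max()
    return rec.copy_with(out)


def design_drift_filter(fs: float, lpf_pass_hz: float = 2.0, lpf_cut_hz: float = 2.25):
    """Butterworth lowpass (SOS) that isolates the slow drift component.

    The order is chosen so the passband ripple is at most 1 dB up to
    ``lpf_pass_hz`` and the attenuation at ``lpf_cut_hz`` is at least 40 dB;
    for the default 2 / 2.25 Hz edges this gives order 45.
    """
    if fs <= 2 * lpf_cut_hz:
        raise ConfigurationError(
            f"fs={fs} Hz too low for a {lpf_cut_hz} Hz drift filter"
        )
    if lpf_cut_hz <= lpf_pass_hz:
        raise ConfigurationError("lpf_cut_hz must exceed lpf_pass_hz")
    order, wn = signal.buttord(lpf_pass_hz, lpf_cut_hz, gpass=1.0, gstop=40.0, fs=fs)
    return signal.butter(order, wn, btype="low", output="sos", fs=fs)


def remove_drift(
    rec: RawRecording, lpf_pass_hz: float = 2.0, lpf_cut_hz: float = 2.25
) -> RawRecording:
    """Subtract the slow (< ~2 Hz) component, removing DC offset and drift.

    The slow estimate is obtained zero-phase so the analysis band is passed
    without amplitude or phase distortion.
    """
    sos = design_drift_filter(rec.fs, lpf_pass_hz, lpf_cut_hz)
    slow = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.copy_with(rec.samples - slow)


def effective_fir_order(fir_order: int, fs: float) -> int:
    """FIR order rescaled to the recording's sampling rate.

    ``fir_order`` is specified at the 8192 Hz reference rate; at other rates it
    is scaled proportionally so the transition width in Hz stays comparable.
    The result is forced even so the group delay is an integer sample count.
    """
    order = int(round(fir_order * fs / _REFERENCE_FS))
    if order % 2:
        order += 1
    return max(order, 2)


def design_bandpass(band: BandSpec, fs: float, fir_order: int = 4000) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR bandpass taps for the analysis band."""
    order = effective_fir_order(fir_order, fs)
    if fs <= 2 * band.high_hz:
        raise ConfigurationError(f"fs={fs} Hz cannot represent {band.high_hz} Hz")
    return signal.firwin(
        order + 1, [band.low_hz, band.high_hz], pass_zero=False, fs=fs,
        window="hamming",
    )


def bandpass_theta(
    rec: RawRecording,
    band: BandSpec | None = None,
    fir_order: int = 4000,
    retention_s: float = 1.0,
) -> RawRecording:
    """Causal FIR bandpass with group-delay-corrected alignment.

    The filter is applied causally (real-time semantics); the output is then
    shifted back by the group delay (order/2 samples) so sample k of the result
    is the band content at time k/fs on the original clock.  The first
    ``retention_s`` seconds remain contaminated by the filter transient and
    must be discarded by the caller (the pipeline skips them via its
    segmentation start offset).
    """
    band = band or BandSpec()
    taps = design_bandpass(band, rec.fs, fir_order)
    gd = (taps.size - 1) // 2
    min_len = taps.size + int(round(retention_s * rec.fs))
    if rec.n_samples < min_len:
        raise TooShortError(
            f"recording has {rec.n_samples} samples; need at least {min_len} "
            f"for a {taps.size - 1}-order FIR plus {retention_s} s retention"
        )
    y = signal.lfilter(taps, 1.0, rec.samples, axis=1)[:, gd:]
    return rec.copy_with(y)


def segment(
    rec: RawRecording,
    band: BandSpec | None = None,
    start_s: float = 0.0,
    end_s: float | None = None,
) -> list[list[PeriodFrame]]:
    """Cut each channel into consecutive non-overlapping nominal-period frames.

    Frames hold n = round(fs * tmed) samples; the trailing partial frame is
    dropped.  Each frame carries the last sample of its predecessor
    (``prev_last``); the first frame carries its own first sample so its first
    elementary distance degenerates to the flat time step.  Returns one frame
    list per channel; a recording shorter than one period yields empty lists.
    """
    band = band or BandSpec()
    n = band.period_samples(rec.fs)
    if n < 2:
        raise ConfigurationError(f"period of {n} sample(s); fs too low for the band")
    k0 = int(round(start_s * rec.fs))
    k1 = rec.n_samples if end_s is None else min(int(round(end_s * rec.fs)),
                                                 rec.n_samples)
    usable = k1 - k0
    n_frames = max(usable // n, 0)
    out: list[list[PeriodFrame]] = []
    for ch in range(rec.n_channels):
        x = rec.samples[ch, k0 : k0 + n_frames * n]
        frames: list[PeriodFrame] = []
        for p in range(n_frames):
            seg = x[p * n : (p + 1) * n]
            prev_last = seg[0] if p == 0 else x[p * n - 1]
            frames.append(
                PeriodFrame(
                    channel=ch,
                    index=p + 1,
                    samples=seg,
                    prev_last=float(prev_last),
                    start_s=(k0 + p * n) / rec.fs,
                )
            )
        out.append(frames)
    return out
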