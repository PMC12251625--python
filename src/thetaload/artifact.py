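"""Spike-artifact detection and replacement on segmented narrowband signals.

A period is flagged as a spike when its peak magnitude exceeds the mean of the
peaks in the preceding clean window by more than a relative threshold (the
signal peak criterion).  The flagged period and its neighbors p-1, p+1, p+2
are replaced — not dropped — by the sample-wise mean waveform of the clean
periods preceding the artifact, which keeps the frame grid intact and avoids
injecting step discontinuities into a narrowband signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import PeriodFrame

#: period offsets replaced around a detected spike
REPLACE_SPAN = (-1, 0, 1, 2)


@dataclass(frozen=True)
class SpikeConfig:
    np_periods: int = 10
    tresh: float = 3.0

    def __post_init__(self):
        if self.np_periods < 1:
            raise ValidationError("np_periods must be >= 1")
        if self.tresh <= 0:
            raise ValidationError("tresh must be > 0")


def peak_of(frame: PeriodFrame) -> float:
    """Peak magnitude of the period, max_k |S_k|."""
    if frame.n < 1:
        raise ValidationError("empty frame has no peak")
    return float(np.abs(frame.samples).max())


def spike_score(current_peak: float, prior_peaks: np.ndarray) -> float:
    """Relative excess of the current peak over the mean of the prior peaks.

    Undefined (raises) when the prior mean is zero; the caller must skip
    detection for that period.
    """
    m = float(np.mean(prior_peaks))
    if m == 0.0:
        raise ValidationError("prior peaks average to zero; spike score undefined")
    return (current_peak - m) / m


def sanitize(
    frames: list[PeriodFrame], cfg: SpikeConfig | None = None
) -> tuple[list[PeriodFrame], np.ndarray]:
    """Scan one channel's frames for spikes and replace flagged neighborhoods.

    Scanning runs in period order.  A frame is scored once ``np_periods`` clean
    (never-replaced) frames precede it; on detection, existing frames at
    offsets p-1..p+2 are replaced by the mean waveform of the clean frames
    preceding p-1, the scan resumes at p+3, and replaced frames are excluded
    from all later prior-peak windows.  ``prev_last`` links are rebuilt so the
    curve-length path stays consistent across replacements.
    """
    cfg = cfg or SpikeConfig()
    n_frames = len(frames)
    flags = np.zeros(n_frames, dtype=bool)
    if n_frames <= cfg.np_periods:
        return list(frames), flags

    out = [f.samples.copy() for f in frames]
    peaks = np.array([np.abs(s).max() for s in out])
    clean: list[int] = []  # indices of scanned, never-replaced frames, in order

    p = 0
    while p < n_frames:
        if flags[p]:
            p += 1
            continue
        if len(clean) >= cfg.np_periods:
            prior = clean[-cfg.np_periods :]
            prior_mean = peaks[prior].mean()
            if prior_mean > 0.0 and (peaks[p] - prior_mean) / prior_mean > cfg.tresh:
                # mean waveform of the clean window preceding the p-1 neighbor
                donors = [i for i in clean if i < p - 1][-cfg.np_periods:] or prior
                fill = np.mean([out[i] for i in donors], axis=0)
                for off in REPLACE_SPAN:
                    q = p + off
                    if 0 <= q < n_frames and not flags[q]:
                        out[q] = fill.copy()
                        peaks[q] = np.abs(fill).max()
                        flags[q] = True
                        if q in clean:
                            clean.remove(q)
                p += 3
                continue
        clean.append(p)
        p += 1

    result: list[PeriodFrame] = []
    for i, f in enumerate(frames):
        prev_last = out[i][0] if i == 0 else float(out[i - 1][-1])
        result.append(
            PeriodFrame(channel=f.channel, index=f.index, samples=out[i],
                        prev_last=float(prev_last), start_s=f.start_s)
        )
    return result, flags
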