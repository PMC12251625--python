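"""Per-period signal measures and their sliding-window means.

The primary discriminator is the curve length of the signal over one nominal
period: the sum of elementary Euclidean distances traced in the signal-time
plane,

    Lsc(p)  = sum_k sqrt((Delta_k S)^2 + (1/Fs)^2),          k = 1..n
    Lscn(p) = (1/n) sum_k sqrt((Delta_k S / Delta_t)^2 + 1),

with Delta_k S = S_k - S_{k-1} and S_0 the previous frame's last sample.  Lscn
is dimensionless, reaches its minimum of exactly 1 on a constant signal, grows
with amplitude and dynamics, and is immune to the signal's bias.  The energy
measures are the plain sum of squares (Ea) and the variance-like relative
energy about the period mean (Er), which shares the bias immunity.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .types import MetricSeries, PeriodFrame, WindowSeries


def _deltas(frame: PeriodFrame) -> np.ndarray:
    """The n elementary differences of a frame, the first one taken against
    the previous frame's last sample."""
    if frame.n < 2:
        raise ValidationError(f"degenerate frame with n={frame.n} < 2 samples")
    s = frame.samples
    return np.diff(s, prepend=frame.prev_last)


def curve_length_raw(frame: PeriodFrame, fs: float) -> float:
    """Curve length of one period: the path traveled in the signal-time plane."""
    d = _deltas(frame)
    return float(np.sum(np.sqrt(d * d + 1.0 / fs**2)))


def curve_length_norm(frame: PeriodFrame, fs: float) -> float:
    """Normalized curve length Lscn; >= 1, equal to 1 iff the period is constant."""
    d = _deltas(frame) * fs  # Delta_k S / Delta_t
    return float(np.mean(np.sqrt(d * d + 1.0)))


def energy_abs(frame: PeriodFrame) -> float:
    """Absolute energy of the period: sum of squared samples."""
    return float(np.sum(frame.samples**2))


def energy_rel(frame: PeriodFrame) -> float:
    """Relative energy: sum of squared deviations from the period mean."""
    s = frame.samples
    return float(np.sum((s - s.mean()) ** 2))


# vectorized series builders ------------------------------------------------

_METRICS = ("curve-length", "relative-energy", "raw-curve-length", "absolute-energy")


def _frame_matrix(frames: list[PeriodFrame]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.stack([f.samples for f in frames])
    prev = np.array([f.prev_last for f in frames])
    return mat, prev


def metric_series(
    frames: list[PeriodFrame], fs: float, metric: str = "curve-length"
) -> MetricSeries:
    """Evaluate one metric over a channel's frame sequence."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; one of {_METRICS}")
    if not frames:
        return MetricSeries(channel=-1, metric=metric, values=np.empty(0),
                            period_end_s=np.empty(0))
    mat, prev = _frame_matrix(frames)
    if metric in ("curve-length", "raw-curve-length"):
        d = np.diff(np.column_stack([prev, mat]), axis=1)
        if metric == "curve-length":
            values = np.mean(np.sqrt((d * fs) ** 2 + 1.0), axis=1)
        else:
            values = np.sum(np.sqrt(d**2 + 1.0 / fs**2), axis=1)
    elif metric == "absolute-energy":
        values = np.sum(mat**2, axis=1)
    else:  # relative-energy
        values = np.sum((mat - mat.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ends = np.array([f.end_s(fs) for f in frames])
    return MetricSeries(channel=frames[0].channel, metric=metric,
                        values=values, period_end_s=ends)


def sliding_mean(series: MetricSeries, w_periods: int) -> WindowSeries:
    """Arithmetic mean over a window of w consecutive periods, sliding by one
    period; window j is stamped with the end time of its final period."""
    if w_periods < 1:
        raise ValidationError("w_periods must be >= 1")
    np_ = series.values.size
    if np_ < w_periods:
        raise InsufficientDataError(
            f"{np_} periods available but the averaging window needs {w_periods}"
        )
    kernel = np.full(w_periods, 1.0 / w_periods)
    means = np.convolve(series.values, kernel, mode="valid")
    ends = series.period_end_s[w_periods - 1 :]
    return WindowSeries(channel=series.channel, metric=series.metric,
                        values=means, w_periods=w_periods, window_end_s=ends)
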