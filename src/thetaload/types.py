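"""Core domain containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class RawRecording:
    """A multichannel EEG recording: ``samples`` is (n_channels, n_samples).

    ``fs`` is the sampling frequency in Hz and ``labels`` the ordered channel
    names (10-10 / 10-20 montage strings, or anything unique).
    """

    samples: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        if len(self.labels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "RawRecording":
        return RawRecording(samples=samples, fs=self.fs, labels=list(self.labels))


@dataclass
class TaskProfile:
    """Ordered, non-overlapping [start_s, end_s) cognitive-load intervals."""

    intervals: list[tuple[float, float]]
    accepted_latency_s: float = 3.0

    def __post_init__(self):
        if self.accepted_latency_s < 0:
            raise ValidationError("accepted_latency_s must be >= 0")
        ivs = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if a < 0 or b <= a:
                raise ValidationError(f"degenerate interval [{a}, {b})")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValidationError(
                    f"overlapping intervals [{a0}, {b0}) and [{a1}, {b1})"
                )
        self.intervals = ivs

    def in_task(self, t: float) -> bool:
        """True if ``t`` lies inside a load interval or within the accepted
        latency after one."""
        for a, b in self.intervals:
            if a <= t < b + self.accepted_latency_s:
                return True
        return False


@dataclass(frozen=True)
class BandSpec:
    """Analysis passband; the nominal period is the reciprocal of the band's
    median (midpoint) frequency."""

    low_hz: float = 4.0
    high_hz: float = 5.0

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"need 0 < low < high, got [{self.low_hz}, {self.high_hz}]"
            )

    @property
    def fmed_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    @property
    def tmed_s(self) -> float:
        return 1.0 / self.fmed_hz

    def period_samples(self, fs: float) -> int:
        """Number of samples in one nominal period, n = round(fs * tmed)."""
        return int(round(fs * self.tmed_s))


@dataclass
class PeriodFrame:
    """One nominal-period segment of one channel's narrowband signal.

    ``prev_last`` is the last sample of the preceding frame; the first frame of
    a run carries its own first sample there, so its first elementary distance
    is the flat time step.
    """

    channel: int
    index: int  # 1-based period index p
    samples: np.ndarray
    prev_last: float
    start_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("frame samples must be 1-D")

    @property
    def n(self) -> int:
        return self.samples.size

    def end_s(self, fs: float) -> float:
        return self.start_s + self.n / fs


@dataclass
class MetricSeries:
    """Per-channel sequence of per-period metric values."""

    channel: int
    metric: str
    values: np.ndarray
    period_end_s: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.period_end_s = np.asarray(self.period_end_s, dtype=np.float64)
        if self.values.shape != self.period_end_s.shape:
            raise ValidationError("values and period_end_s must align")


@dataclass
class WindowSeries:
    """Sliding-window means of a metric series; one value per window position,
    stamped with the end time of the window's final period."""

    channel: int
    metric: str
    values: np.ndarray
    w_periods: int
    window_end_s: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.window_end_s = np.asarray(self.window_end_s, dtype=np.float64)
        if self.values.shape != self.window_end_s.shape:
            raise ValidationError("values and window_end_s must align")


@dataclass
class CalibrationResult:
    """Per-channel detection thresholds from the initial rest span."""

    labels: list[str]
    tresh1: np.ndarray  # curve-length thresholds, one per channel
    tresh2: np.ndarray  # relative-energy thresholds, one per channel
    tcalib_s: float
    w_periods: int
    n_calib_windows: int


@dataclass
class DetectionTrace:
    """Per-channel boolean activations over post-calibration window positions."""

    labels: list[str]
    active: np.ndarray  # (n_channels, n_windows) bool
    window_end_s: np.ndarray  # (n_windows,)
    artifact_flags: np.ndarray | None = None  # (n_channels, n_periods) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        self.window_end_s = np.asarray(self.window_end_s, dtype=np.float64)
        if self.active.ndim != 2 or self.active.shape[1] != self.window_end_s.size:
            raise ValidationError("active matrix must be (channels x windows)")
        if self.active.shape[0] != len(self.labels):
            raise ValidationError("one label per channel required")

    @property
    def n_windows(self) -> int:
        return self.active.shape[1]

    @property
    def activation_counts(self) -> np.ndarray:
        return self.active.sum(axis=1).astype(int)
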