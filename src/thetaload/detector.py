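"""Calibration-threshold detection of cognitive load.

During an initial rest span of ``tcalib_s`` seconds the per-channel threshold
is set to the maximum sliding-window mean of the chosen metric; afterwards a
window is an activation whenever its mean strictly exceeds that threshold.
The estimator :class:`CognitiveLoadDetector` packages the whole pipeline
(normalize -> drift removal -> narrowband FIR -> segmentation -> spike guard
-> metrics -> sliding means -> calibration -> detection) behind the familiar
fit/predict surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .artifact import SpikeConfig, sanitize
from .errors import (
    CalibrationError,
    ConfigurationError,
    PipelineError,
    ThetaLoadError,
    ValidationError,
)
from .metrics import metric_series, sliding_mean
from .preprocess import bandpass_theta, normalize, remove_drift, segment
from .types import (
    BandSpec,
    CalibrationResult,
    DetectionTrace,
    RawRecording,
    WindowSeries,
)

METRIC_CHOICES = ("curve-length", "relative-energy", "either")


@dataclass
class DetectorConfig:
    """Detector parameters; defaults are the reference operating point
    (4-5 Hz band, order-4000 FIR at 8192 Hz, w=10 periods, 10 s calibration)."""

    band_low_hz: float = 4.0
    band_high_hz: float = 5.0
    fir_order: int = 4000
    lpf_pass_hz: float = 2.0
    lpf_cut_hz: float = 2.25
    w_periods: int = 10
    tcalib_s: float = 10.0
    t_start_s: float = 2.0
    retention_s: float = 1.0
    metric_choice: str = "curve-length"
    spike_tresh: float = 3.0
    spike_np: int = 10
    seed: int | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError(
                f"band edges must satisfy 0 < low < high, got "
                f"[{self.band_low_hz}, {self.band_high_hz}]"
            )
        if not 3 <= self.w_periods <= 20:
            raise ConfigurationError(
                f"w_periods must lie in 3..20, got {self.w_periods}"
            )
        if self.tcalib_s < 10:
            raise ConfigurationError(
                f"calibration period must be at least 10 s, got {self.tcalib_s}"
            )
        if not 0 <= self.t_start_s <= 2:
            raise ConfigurationError(
                f"t_start_s must lie in [0, 2] s, got {self.t_start_s}"
            )
        if self.retention_s < 0:
            raise ConfigurationError("retention_s must be >= 0")
        if self.metric_choice not in METRIC_CHOICES:
            raise ConfigurationError(
                f"metric_choice must be one of {METRIC_CHOICES}, "
                f"got {self.metric_choice!r}"
            )
        if self.fir_order < 2:
            raise ConfigurationError("fir_order must be >= 2")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low_hz, self.band_high_hz)

    @property
    def spike(self) -> SpikeConfig:
        return SpikeConfig(np_periods=self.spike_np, tresh=self.spike_tresh)

    def to_dict(self) -> dict:
        return asdict(self)


def window_span_s(w_periods: int, band: BandSpec | None = None) -> float:
    """Intrinsic detector response delay: the averaging window's time span,
    w periods of the band's nominal period (w=10 at 4-5 Hz: ~2.22 s)."""
    band = band or BandSpec()
    return w_periods * band.tmed_s


def calibrate(
    windows: list[WindowSeries], labels: list[str], tcalib_s: float
) -> np.ndarray:
    """Per-channel threshold: the maximum window mean whose window ends at or
    before ``tcalib_s``.  One WindowSeries per channel, all of one metric."""
    if len(windows) != len(labels):
        raise ValidationError("one WindowSeries per channel required")
    out = np.empty(len(windows))
    for i, ws in enumerate(windows):
        mask = ws.window_end_s <= tcalib_s
        if not mask.any():
            raise CalibrationError(
                f"channel {labels[i]}: no complete {ws.w_periods}-period window "
                f"ends within the {tcalib_s} s calibration span"
            )
        out[i] = ws.values[mask].max()
    return out


def detect(
    win_lscn: list[WindowSeries],
    win_er: list[WindowSeries],
    cal: CalibrationResult,
    metric_choice: str = "curve-length",
) -> DetectionTrace:
    """Apply the strict threshold conditions to all post-calibration windows.

    A window is active when its curve-length mean exceeds tresh1, its relative
    energy mean exceeds tresh2, or either, depending on ``metric_choice``.
    """
    if metric_choice not in METRIC_CHOICES:
        raise ConfigurationError(f"unknown metric_choice {metric_choice!r}")
    if len(win_lscn) != len(cal.labels) or len(win_er) != len(cal.labels):
        raise ValidationError("window series and calibration channel sets differ")
    post = win_lscn[0].window_end_s > cal.tcalib_s
    ends = win_lscn[0].window_end_s[post]
    active = np.zeros((len(cal.labels), ends.size), dtype=bool)
    for i in range(len(cal.labels)):
        a1 = win_lscn[i].values[post] > cal.tresh1[i]
        a2 = win_er[i].values[post] > cal.tresh2[i]
        if metric_choice == "curve-length":
            active[i] = a1
        elif metric_choice == "relative-energy":
            active[i] = a2
        else:
            active[i] = a1 | a2
    return DetectionTrace(labels=list(cal.labels), active=active, window_end_s=ends)


def count_activations(trace: DetectionTrace) -> np.ndarray:
    """Number of active window positions per channel (consecutive active
    windows each count once)."""
    return trace.activation_counts


def cumulative_activity(trace: DetectionTrace) -> np.ndarray:
    """Running total over time of activations summed across channels;
    non-decreasing, final value equals the sum of per-channel counts."""
    return np.cumsum(trace.active.sum(axis=0))


class CognitiveLoadDetector(BaseEstimator):
    """Narrowband theta cognitive-load detector with rest-span calibration.

    Parameters mirror :class:`DetectorConfig`.  ``fit(recording)`` runs the
    preprocessing chain and freezes the per-channel thresholds from the first
    ``tcalib_s`` seconds; ``predict()`` returns the
    :class:`~thetaload.types.DetectionTrace` over all later windows of the
    same recording, and ``predict(other)`` applies the frozen thresholds to a
    different recording of the same montage.

    Attributes set by ``fit`` (trailing underscore): ``calibration_``,
    ``thresholds_curve_length_``, ``thresholds_rel_energy_``,
    ``windows_curve_length_``, ``windows_rel_energy_``, ``artifact_flags_``,
    ``period_samples_``, ``labels_``.
    """

    def __init__(
        self,
        band_low_hz: float = 4.0,
        band_high_hz: float = 5.0,
        fir_order: int = 4000,
        lpf_pass_hz: float = 2.0,
        lpf_cut_hz: float = 2.25,
        w_periods: int = 10,
        tcalib_s: float = 10.0,
        t_start_s: float = 2.0,
        retention_s: float = 1.0,
        metric_choice: str = "curve-length",
        spike_tresh: float = 3.0,
        spike_np: int = 10,
        seed: int | None = None,
    ):
        self.band_low_hz = band_low_hz
        self.band_high_hz = band_high_hz
        self.fir_order = fir_order
        self.lpf_pass_hz = lpf_pass_hz
        self.lpf_cut_hz = lpf_cut_hz
        self.w_periods = w_periods
        self.tcalib_s = tcalib_s
        self.t_start_s = t_start_s
        self.retention_s = retention_s
        self.metric_choice = metric_choice
        self.spike_tresh = spike_tresh
        self.spike_np = spike_np
        self.seed = seed

    def _config(self) -> DetectorConfig:
        return DetectorConfig(**{k: getattr(self, k) for k in DetectorConfig.__dataclass_fields__})

    # pipeline stages ------------------------------------------------------

    def _windows(self, rec: RawRecording, cfg: DetectorConfig):
        """Stages (3)-(11): conditioning through sliding-window means."""
        def stage(name, fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except ThetaLoadError as e:
                raise PipelineError(name, str(e)) from e

        rec = stage("normalize", normalize, rec)
        rec = stage("remove_drift", remove_drift, rec, cfg.lpf_pass_hz, cfg.lpf_cut_hz)
        rec = stage("bandpass_theta", bandpass_theta, rec, cfg.band,
                    cfg.fir_order, cfg.retention_s)
        # symmetric edge guard: the leading retention covers the causal FIR
        # transient, the trailing retention the drift estimator's edge effect
        t0 = cfg.t_start_s + cfg.retention_s
        t1 = rec.n_samples / rec.fs - cfg.retention_s
        per_channel = stage("segment", segment, rec, cfg.band, t0, t1)
        flags = []
        win_lscn, win_er = [], []
        for ch, frames in enumerate(per_channel):
            frames, fl = stage("artifact_guard", sanitize, frames, cfg.spike)
            flags.append(fl)
            ms1 = stage("metrics", metric_series, frames, rec.fs, "curve-length")
            ms2 = stage("metrics", metric_series, frames, rec.fs, "relative-energy")
            win_lscn.append(stage("sliding_mean", sliding_mean, ms1, cfg.w_periods))
            win_er.append(stage("sliding_mean", sliding_mean, ms2, cfg.w_periods))
        return win_lscn, win_er, np.array(flags, dtype=bool)

    # sklearn surface ------------------------------------------------------

    def fit(self, recording: RawRecording, y=None) -> "CognitiveLoadDetector":
        cfg = self._config()
        if not isinstance(recording, RawRecording):
            raise ValidationError("fit expects a RawRecording")
        win1, win2, flags = self._windows(recording, cfg)
        try:
            t1 = calibrate(win1, recording.labels, cfg.tcalib_s)
            t2 = calibrate(win2, recording.labels, cfg.tcalib_s)
        except CalibrationError as e:
            raise PipelineError("calibrate", str(e)) from e
        n_cal = int((win1[0].window_end_s <= cfg.tcalib_s).sum())
        self.labels_ = list(recording.labels)
        self.calibration_ = CalibrationResult(
            labels=self.labels_, tresh1=t1, tresh2=t2, tcalib_s=cfg.tcalib_s,
            w_periods=cfg.w_periods, n_calib_windows=n_cal,
        )
        self.thresholds_curve_length_ = t1
        self.thresholds_rel_energy_ = t2
        self.windows_curve_length_ = win1
        self.windows_rel_energy_ = win2
        self.artifact_flags_ = flags
        self.period_samples_ = cfg.band.period_samples(recording.fs)
        self._fit_recording = recording
        return self

    def predict(self, recording: RawRecording | None = None) -> DetectionTrace:
        if not hasattr(self, "calibration_"):
            raise ValidationError("detector is not fitted; call fit first")
        cfg = self._config()
        if recording is None or recording is self._fit_recording:
            win1, win2, flags = (self.windows_curve_length_,
                                 self.windows_rel_energy_, self.artifact_flags_)
        else:
            if list(recording.labels) != self.labels_:
                raise ValidationError("channel labels differ from the fitted run")
            win1, win2, flags = self._windows(recording, cfg)
        trace = detect(win1, win2, self.calibration_, cfg.metric_choice)
        trace.artifact_flags = flags
        trace.meta = {"config": cfg.to_dict()}
        return trace

    def fit_predict(self, recording: RawRecording, y=None) -> DetectionTrace:
        return self.fit(recording).predict()


def run_pipeline(
    rec: RawRecording, cfg: DetectorConfig | None = None
) -> tuple[DetectionTrace, CalibrationResult]:
    """One-shot execution of the full detection pipeline on a recording.

    Calibrates on the first ``tcalib_s`` seconds and detects on everything
    after; deterministic given the recording and configuration.
    """
    cfg = cfg or DetectorConfig()
    det = CognitiveLoadDetector(**cfg.to_dict())
    trace = det.fit_predict(rec)
    return trace, det.calibration_
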