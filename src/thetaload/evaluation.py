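"""Detector scoring against a task profile, and channel ranking by paired t-test.

Windows are labeled by their end time — the moment a detection can first be
reported.  A window counts as task-time when it ends inside a load interval or
within the accepted latency (default 3 s) after one; the latency absorbs
neural after-effects that outlast the stimulus.  Ratios with a zero
denominator are reported as missing (None), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .types import DetectionTrace, TaskProfile

ALPHA_LEVELS = (0.05, 0.02, 0.01)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceReport:
    """The four standard detector ratios; None marks a zero-denominator case."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass
class ChannelTestResult:
    channel: str
    t_abs: float
    df: int
    p_value: float
    decisions: dict[float, bool]  # alpha -> H1 accepted


def label_windows(
    trace: DetectionTrace, profile: TaskProfile
) -> dict[str, ConfusionCounts]:
    """Confusion counts per channel against the task profile.

    TP = active during task time, FN = inactive during task time,
    FP = active outside, TN = inactive outside; task time includes the
    accepted latency after each interval.
    """
    task = np.array([profile.in_task(t) for t in trace.window_end_s])
    out: dict[str, ConfusionCounts] = {}
    for i, lab in enumerate(trace.labels):
        act = trace.active[i]
        out[lab] = ConfusionCounts(
            tp=int(np.sum(act & task)),
            fn=int(np.sum(~act & task)),
            fp=int(np.sum(act & ~task)),
            tn=int(np.sum(~act & ~task)),
        )
    return out


def confusion_metrics(c: ConfusionCounts) -> PerformanceReport:
    """Accuracy, precision, sensitivity, specificity from the four counts."""
    if c.total == 0:
        return PerformanceReport(None, None, None, None)

    def ratio(num, den):
        return num / den if den > 0 else None

    return PerformanceReport(
        accuracy=ratio(c.tp + c.tn, c.total),
        precision=ratio(c.tp, c.tp + c.fp),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
    )


def paired_t(
    counts_load: np.ndarray, counts_noload: np.ndarray
) -> tuple[float, int, float]:
    """Two-tailed paired t-test on activation counts from matched sessions.

    Returns (|t|, df, p).  Zero-variance differences give t=0, p=1 when the
    mean difference is zero, and an infinite-t marker (p=0) otherwise.
    """
    a = np.asarray(counts_load, dtype=float)
    b = np.asarray(counts_noload, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length vectors with N >= 2")
    d = a - b
    df = d.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.isclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        return math.inf, df, 0.0
    res = stats.ttest_rel(a, b)
    return float(abs(res.statistic)), df, float(res.pvalue)


def t_critical(df: int, alpha: float) -> float:
    """Two-tailed critical value of Student's t, to 4 decimals.

    For df=5 this reproduces the textbook 2.5706 (5%), 3.3650 (2%) and
    4.0321 (1%).
    """
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return round(float(stats.t.ppf(1 - alpha / 2, df)), 4)


def channel_test(
    channel: str,
    counts_load: np.ndarray,
    counts_noload: np.ndarray,
    alphas: tuple[float, ...] = ALPHA_LEVELS,
) -> ChannelTestResult:
    """Paired t-test for one channel with H1 decisions at each alpha level."""
    t_abs, df, p = paired_t(counts_load, counts_noload)
    decisions = {a: bool(t_abs > t_critical(df, a)) for a in alphas}
    return ChannelTestResult(channel=channel, t_abs=t_abs, df=df, p_value=p,
                             decisions=decisions)


def rank_channels(
    results: list[ChannelTestResult], p_screen: float = 0.05
) -> dict[float, list[str]]:
    """Group channels into the tier of the smallest alpha at which H1 holds.

    Returns {alpha: [channels]}; each channel appears in exactly one tier
    (its most stringent level) and channels rejected at every level are
    excluded.  Channels failing the p < ``p_screen`` significance screen are
    also excluded, mirroring the screening applied to the printed tables.
    """
    alphas = sorted(ALPHA_LEVELS)  # ascending: 0.01, 0.02, 0.05
    tiers: dict[float, list[str]] = {a: [] for a in alphas}
    for r in results:
        if r.p_value >= p_screen:
            continue
        for a in alphas:
            if r.decisions.get(a, False):
                tiers[a].append(r.channel)
                break
    return tiers


def evaluate_trace(
    trace: DetectionTrace, profile: TaskProfile
) -> "pd.DataFrame":  # noqa: F821 - imported lazily
    """Per-channel confusion counts and ratios as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for lab, c in label_windows(trace, profile).items():
        rep = confusion_metrics(c)
        rows.append({
            "channel": lab, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "accuracy": rep.accuracy, "precision": rep.precision,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
        })
    return pd.DataFrame(rows)
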