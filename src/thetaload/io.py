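"""Readers and writers: EDF/BDF recordings, CSV task profiles, detection
traces, activation counts, and YAML detector configurations.

Recordings are read through MNE's EDF/BDF readers; sample values are only
converted to the format's physical units, never rescaled or reordered.  The
EDF/BDF writer here is a minimal standard-conforming implementation used to
produce synthetic fixtures (16-bit EDF, 24-bit BDF, one-second data records).
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, ValidationError
from .types import DetectionTrace, RawRecording, TaskProfile

__all__ = [
    "read_recording",
    "write_recording",
    "read_task_profile",
    "write_task_profile",
    "write_outputs",
    "read_counts",
    "load_config",
]


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Read an EDF or BDF file into a :class:`RawRecording`.

    ``format`` may be "edf" or "bdf"; when omitted it is taken from the file
    suffix.  All channels are returned at the native sampling rate, in the
    format's physical units (MNE's SI volts).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    readers = {"edf": mne.io.read_raw_edf, "bdf": mne.io.read_raw_bdf}
    if fmt not in readers:
        raise FormatError(f"unsupported recording format {fmt!r} (edf or bdf)")
    _check_declared_size(path, sample_bytes=3 if fmt == "bdf" else 2)
    try:
        raw = readers[fmt](str(path), preload=True, verbose="ERROR")
    except Exception as e:  # mne raises plain ValueError/OSError on bad files
        raise FormatError(f"cannot parse {path} as {fmt.upper()}: {e}") from e
    data = raw.get_data()
    if data.shape[0] == 0:
        raise FormatError(f"{path} contains no channels")
    return RawRecording(samples=data, fs=float(raw.info["sfreq"]),
                        labels=list(raw.ch_names))


def _check_declared_size(path: Path, sample_bytes: int) -> None:
    """Reject files whose size disagrees with the header's declared record
    count (MNE silently tolerates truncated files)."""
    try:
        with open(path, "rb") as f:
            head = f.read(256)
            if len(head) < 256:
                raise FormatError(f"{path}: header shorter than 256 bytes")
            header_bytes = int(head[184:192])
            n_records = int(head[236:244])
            n_signals = int(head[252:256])
            per_signal = f.read(256 * n_signals)
            if len(per_signal) < 256 * n_signals:
                raise FormatError(f"{path}: truncated signal header")
            off = 216 * n_signals
            spr = sum(int(per_signal[off + 8 * i: off + 8 * (i + 1)])
                      for i in range(n_signals))
    except (ValueError, OSError) as e:
        raise FormatError(f"{path}: malformed EDF/BDF header: {e}") from e
    if n_records < 0:  # unknown record count is legal in the format
        return
    expected = header_bytes + n_records * spr * sample_bytes
    actual = path.stat().st_size
    if actual < expected:
        raise FormatError(
            f"{path}: file holds {actual} bytes but the header declares "
            f"{expected} ({n_records} records); truncated file"
        )


# -- minimal EDF/BDF writer -------------------------------------------------

def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValidationError(f"header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _phys_bounds(ch: np.ndarray) -> tuple[float, float]:
    lo, hi = float(ch.min()), float(ch.max())
    if hi - lo < 1e-9:
        lo, hi = lo - 1.0, hi + 1.0
    # round outward to values that survive the 8-char ASCII header fields
    return float(f"{lo - 1e-6 * (hi - lo):.6g}"[:8]), float(f"{hi + 1e-6 * (hi - lo):.6g}"[:8])


def write_recording(
    path: str | Path, rec: RawRecording, format: str | None = None,
    physical_dim: str = "uV",
) -> Path:
    """Write a recording as EDF (16-bit) or BDF (24-bit).

    Uses one-second data records; the trailing partial second, if any, is not
    written, so durations should be whole seconds.  Values are quantized onto
    the per-channel physical range.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("edf", "bdf"):
        raise FormatError(f"unsupported recording format {fmt!r} (edf or bdf)")
    bdf = fmt == "bdf"
    if rec.fs != round(rec.fs):
        raise ValidationError("writer requires an integer sampling rate")
    spr = int(round(rec.fs))  # samples per one-second record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValidationError("recording shorter than one data record (1 s)")
    dig_min, dig_max = (-8388608, 8388607) if bdf else (-32768, 32767)

    digital, pmins, pmaxs = [], [], []
    for ch in rec.samples:
        lo, hi = _phys_bounds(ch)
        g = (dig_max - dig_min) / (hi - lo)
        d = np.clip(np.round((ch - lo) * g + dig_min), dig_min, dig_max)
        digital.append(d.astype(np.int32))
        pmins.append(lo)
        pmaxs.append(hi)

    n_ch = rec.n_channels
    hdr = _io.BytesIO()
    hdr.write(b"\xffBIOSEMI" if bdf else _field("0", 8))
    hdr.write(_field("X X X X", 80))                      # patient id (anonymous)
    hdr.write(_field("Startdate 01-JAN-2020 X X X", 80))  # recording id
    hdr.write(_field("01.01.20", 8))
    hdr.write(_field("00.00.00", 8))
    hdr.write(_field(256 * (1 + n_ch), 8))
    hdr.write(_field("24BIT" if bdf else "", 44))
    hdr.write(_field(n_rec, 8))
    hdr.write(_field("1", 8))
    hdr.write(_field(n_ch, 4))
    for lab in rec.labels:
        hdr.write(_field(lab, 16))
    hdr.write(_field("AgAgCl electrode", 80) * n_ch)
    hdr.write(_field(physical_dim, 8) * n_ch)
    for v in pmins:
        hdr.write(_field(f"{v:.6g}"[:8], 8))
    for v in pmaxs:
        hdr.write(_field(f"{v:.6g}"[:8], 8))
    hdr.write(_field(dig_min, 8) * n_ch)
    hdr.write(_field(dig_max, 8) * n_ch)
    hdr.write(_field("HP:DC LP:none", 80) * n_ch)
    hdr.write(_field(spr, 8) * n_ch)
    hdr.write(_field("", 32) * n_ch)

    with open(path, "wb") as f:
        f.write(hdr.getvalue())
        for r in range(n_rec):
            for d in digital:
                blk = d[r * spr : (r + 1) * spr]
                if bdf:
                    raw = np.empty((spr, 3), dtype=np.uint8)
                    raw[:, 0] = blk & 0xFF
                    raw[:, 1] = (blk >> 8) & 0xFF
                    raw[:, 2] = (blk >> 16) & 0xFF
                    f.write(raw.tobytes())
                else:
                    f.write(blk.astype("<i2").tobytes())
    return path


# -- task profiles ----------------------------------------------------------

def read_task_profile(path: str | Path, accepted_latency_s: float = 3.0) -> TaskProfile:
    """Read a CSV of load intervals (columns start_s, end_s, seconds).

    Rows are sorted and validated; overlapping or degenerate intervals raise
    :class:`~thetaload.errors.ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    intervals = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        for row in reader:
            if not row or row[0].strip().lower().startswith("start"):
                continue
            try:
                a, b = float(row[0]), float(row[1])
            except (ValueError, IndexError) as e:
                raise FormatError(f"bad task-profile row {row!r}: {e}") from e
            intervals.append((a, b))
    return TaskProfile(intervals=intervals, accepted_latency_s=accepted_latency_s)


def write_task_profile(path: str | Path, profile: TaskProfile) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["start_s", "end_s"])
        for a, b in profile.intervals:
            w.writerow([f"{a:g}", f"{b:g}"])
    return path


# -- traces and counts ------------------------------------------------------

def write_outputs(
    trace: DetectionTrace, counts: np.ndarray, out_dir: str | Path,
    prefix: str = "detection",
) -> tuple[Path, Path]:
    """Write the detection trace and per-channel activation counts as CSV.

    Produces ``<prefix>_trace.csv`` with rows (channel, window_end_s, active,
    artifact) and ``<prefix>_counts.csv`` with rows (channel,
    activation_count); re-reading the counts file reproduces the integers
    exactly.
    """
    if trace.n_windows == 0:
        raise ValidationError("refusing to write an empty detection trace")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_path = out_dir / f"{prefix}_trace.csv"
    counts_path = out_dir / f"{prefix}_counts.csv"
    flagged = _window_artifact_flags(trace)
    with open(trace_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["channel", "window_end_s", "active", "artifact"])
        for i, lab in enumerate(trace.labels):
            for j, t in enumerate(trace.window_end_s):
                w.writerow([lab, f"{t:.6f}", int(trace.active[i, j]),
                            int(flagged[i, j])])
    with open(counts_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["channel", "activation_count"])
        for lab, c in zip(trace.labels, np.asarray(counts, dtype=int)):
            w.writerow([lab, int(c)])
    return trace_path, counts_path


def _window_artifact_flags(trace: DetectionTrace) -> np.ndarray:
    """Per-window flag: 1 if any period of the recording was replaced by the
    artifact guard on that channel (coarse provenance marker)."""
    if trace.artifact_flags is None:
        return np.zeros_like(trace.active, dtype=int)
    any_flag = trace.artifact_flags.any(axis=1).astype(int)
    return np.repeat(any_flag[:, None], trace.n_windows, axis=1)


def read_counts(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, newline="") as f:
        for row in csv.reader(f):
            if not row or row[0] == "channel":
                continue
            out[row[0]] = int(row[1])
    return out


def read_trace(path: str | Path) -> DetectionTrace:
    """Re-read a trace CSV written by :func:`write_outputs`."""
    per_channel: dict[str, list[tuple[float, bool]]] = {}
    with open(path, newline="") as f:
        for row in csv.reader(f):
            if not row or row[0] == "channel":
                continue
            per_channel.setdefault(row[0], []).append((float(row[1]), bool(int(row[2]))))
    if not per_channel:
        raise FormatError(f"{path}: empty trace file")
    labels = list(per_channel)
    ends = np.array([t for t, _ in per_channel[labels[0]]])
    active = np.array([[a for _, a in per_channel[lab]] for lab in labels])
    return DetectionTrace(labels=labels, active=active, window_end_s=ends)


def load_config(path: str | Path) -> dict:
    """Load a YAML mapping of DetectorConfig fields."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data
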