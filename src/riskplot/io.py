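"""Signal containers and file I/O for ECG records, R-peak annotations and
RR-interval series.

Supported on-disk formats
-------------------------
* **CSV** — two columns ``time_s,amplitude_mv`` at a fixed sampling step.
* **WFDB subset** — a single-signal record written as a plain-text ``.hea``
  header plus a little-endian 16-bit ``.dat`` file (WFDB format 16), with
  beat annotations in an MIT-format ``.atr`` stream (symbol ``N``).  This is
  a deliberately minimal, self-contained implementation of the subset of the
  WFDB conventions this package needs: one channel, format 16, gain/baseline
  honoured, annotation type NORMAL with SKIP escapes for long gaps.
* **RRI text** — one interval in seconds per line; ``#`` starts a comment.

Amplitudes are treated as millivolts throughout; no rescaling on read beyond
the WFDB gain/baseline conversion.  Sample indexing is 0-based and
``beat_times[0] = 0`` defines the record-local clock for interval series.
"""

from __future__ import annotations

import math
import os
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "PeakAnnotation",
    "RRISeries",
    "read_ecg",
    "write_ecg",
    "read_rri",
    "write_rri",
    "FormatError",
    "ValidationError",
]

# Interval range considered physiologically plausible; values outside are
# flagged (never deleted) by the quality mask downstream.
RRI_MIN_S = 0.2
RRI_MAX_S = 3.0

# WFDB subset constants: ADC gain (adu/mV), zero baseline, 16-bit format.
_WFDB_GAIN = 200.0
_WFDB_FMT = 16
_ANN_NORMAL = 1   # MIT annotation code for a normal beat
_ANN_SKIP = 59    # MIT SKIP escape: 4-byte long interval follows


class FormatError(ValueError):
    """Malformed input file (bad structure, non-uniform sampling, ...)."""


class ValidationError(ValueError):
    """Input violates a domain invariant (e.g. non-positive interval)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ECGRecord:
    """Single-channel ECG trace.

    Parameters
    ----------
    samples : array of float
        Amplitude in mV.
    fs : float
        Sampling frequency in Hz (> 0).
    t0 : float
        Start offset of the first sample, seconds.
    label : str
        Channel name.
    truth_peaks : array of int, optional
        Annotated R-peak sample indices (strictly increasing), when known.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "ECG"
    truth_peaks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("ECG samples must be one-dimensional")
        if not self.fs > 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("ECG samples contain NaN/Inf")
        if self.truth_peaks is not None:
            p = np.asarray(self.truth_peaks, dtype=np.int64)
            if p.size and (np.any(np.diff(p) <= 0) or p[0] < 0 or p[-1] >= self.samples.size):
                raise ValidationError("truth_peaks must be strictly increasing and in range")
            self.truth_peaks = p

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def replace_samples(self, samples: np.ndarray) -> "ECGRecord":
        """New record with the same metadata and different sample values."""
        return ECGRecord(samples=np.asarray(samples, dtype=float), fs=self.fs,
                         t0=self.t0, label=self.label, truth_peaks=self.truth_peaks)


@dataclass
class PeakAnnotation:
    """R-peak positions as sample indices at a given sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if not self.fs > 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if self.indices.size:
            if self.indices[0] < 0 or np.any(np.diff(self.indices) <= 0):
                raise ValidationError("peak indices must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class RRISeries:
    """Ordered RR intervals (seconds) — the HRV signal.

    ``beat_times`` has one more entry than ``intervals`` and satisfies
    ``beat_times[i+1] = beat_times[i] + intervals[i]`` with
    ``beat_times[0] = 0`` unless an explicit anchor is given.
    """

    intervals: np.ndarray
    beat_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValidationError("intervals must be a non-empty 1-D sequence")
        if np.any(self.intervals <= 0) or not np.all(np.isfinite(self.intervals)):
            raise ValidationError("all intervals must be finite and > 0")
        if self.beat_times is None:
            self.beat_times = np.concatenate(([0.0], np.cumsum(self.intervals)))
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if self.beat_times.size != self.intervals.size + 1:
                raise ValidationError("beat_times must have len(intervals) + 1 entries")

    def __len__(self) -> int:
        return int(self.intervals.size)

    def quality_ok(self) -> np.ndarray:
        """Boolean mask of intervals inside the plausible [0.2, 3.0] s range."""
        return (self.intervals >= RRI_MIN_S) & (self.intervals <= RRI_MAX_S)


# ---------------------------------------------------------------------------
# CSV waveform I/O
# ---------------------------------------------------------------------------

def _read_ecg_csv(path: Path) -> ECGRecord:
    try:
        raw = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    rows = []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1:  # tolerate a single header line
                continue
            raise FormatError(f"{path}:{lineno}: non-numeric row") from None
    if len(rows) < 2:
        raise FormatError(f"{path}: need at least two samples")
    data = np.asarray(rows, dtype=float)
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    mean_dt = float(dt.mean())
    if (dt.max() - dt.min()) / mean_dt > 1e-6:
        raise FormatError(f"{path}: non-uniform time step (relative jitter > 1e-6)")
    fs = 1.0 / mean_dt
    # kill floating-point dust so e.g. 1/256-stepped files yield fs == 256.0
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    return ECGRecord(samples=x, fs=fs, t0=float(t[0]))


def _write_ecg_csv(record: ECGRecord, path: Path) -> None:
    t = record.t0 + np.arange(record.samples.size) / record.fs
    lines = ["time_s,amplitude_mv"]
    lines += [f"{ti:.9f},{xi:.10g}" for ti, xi in zip(t, record.samples)]
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# WFDB-subset waveform I/O
# ---------------------------------------------------------------------------

def _wfdb_paths(path: Path) -> tuple[Path, Path, Path, str]:
    base = path.with_suffix("") if path.suffix in {".hea", ".dat", ".atr"} else path
    return base.with_suffix(".hea"), base.with_suffix(".dat"), base.with_suffix(".atr"), base.name


def _read_ecg_wfdb(path: Path) -> ECGRecord:
    hea, dat, atr, _name = _wfdb_paths(path)
    try:
        header_lines = [ln for ln in hea.read_text().splitlines()
                        if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise IOError(f"cannot read {hea}: {exc}") from exc
    if len(header_lines) < 2:
        raise FormatError(f"{hea}: truncated header")
    rec_fields = header_lines[0].split()
    if len(rec_fields) < 4:
        raise FormatError(f"{hea}: record line needs name, n_sig, fs, n_samples")
    n_sig, fs, n_samp = int(rec_fields[1]), float(rec_fields[2]), int(rec_fields[3])
    if n_sig != 1:
        raise FormatError(f"{hea}: only single-signal records are supported (n_sig={n_sig})")
    sig_fields = header_lines[1].split()
    if int(sig_fields[1]) != _WFDB_FMT:
        raise FormatError(f"{hea}: only format {_WFDB_FMT} is supported")
    gain_field = sig_fields[2]
    if "(" in gain_field:
        gain_s, rest = gain_field.split("(", 1)
        baseline = int(rest.split(")")[0])
    else:
        gain_s, baseline = gain_field, 0
    gain = float(gain_s.split("/")[0])
    label = sig_fields[-1] if len(sig_fields) > 8 else "ECG"
    try:
        digital = np.frombuffer(dat.read_bytes(), dtype="<i2")
    except OSError as exc:
        raise IOError(f"cannot read {dat}: {exc}") from exc
    if digital.size != n_samp:
        raise FormatError(f"{dat}: expected {n_samp} samples, found {digital.size}")
    samples = (digital.astype(float) - baseline) / gain
    truth_peaks = _read_annotations(atr) if atr.exists() else None
    return ECGRecord(samples=samples, fs=fs, label=label, truth_peaks=truth_peaks)


def _write_ecg_wfdb(record: ECGRecord, path: Path) -> None:
    hea, dat, atr, name = _wfdb_paths(path)
    digital = np.clip(np.rint(record.samples * _WFDB_GAIN), -32768, 32767).astype("<i2")
    checksum = int(np.int16(digital.astype(np.int64).sum() & 0xFFFF))
    first = int(digital[0]) if digital.size else 0
    fs_s = f"{record.fs:.9g}"
    header = (
        f"{name} 1 {fs_s} {digital.size}\n"
        f"{name}.dat {_WFDB_FMT} {_WFDB_GAIN:.9g}(0)/mV 16 0 {first} {checksum} 0 {record.label}\n"
    )
    try:
        hea.write_text(header)
        dat.write_bytes(digital.tobytes())
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    if record.truth_peaks is not None and record.truth_peaks.size:
        _write_annotations(atr, record.truth_peaks)
    elif atr.exists():
        atr.unlink()


def _write_annotations(path: Path, indices: np.ndarray) -> None:
    """MIT annotation stream: NORMAL beats, SKIP escape for deltas > 1023."""
    out = bytearray()
    prev = 0
    for idx in np.asarray(indices, dtype=np.int64):
        delta = int(idx - prev)
        prev = int(idx)
        if delta > 1023:
            out += struct.pack("<H", (_ANN_SKIP << 10))
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (_ANN_NORMAL << 10) | delta)
    out += struct.pack("<H", 0)  # end of stream
    path.write_bytes(bytes(out))


def _read_annotations(path: Path) -> np.ndarray:
    data = path.read_bytes()
    indices = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data) or i + 2 == len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        if word == 0:
            break
        code, delta = word >> 10, word & 0x3FF
        if code == _ANN_SKIP:
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            pending_skip = (hi << 16) | lo
        elif code == _ANN_NORMAL:
            t += delta + pending_skip
            pending_skip = 0
            indices.append(t)
        else:  # unknown types advance the clock but are not beats
            t += delta + pending_skip
            pending_skip = 0
    return np.asarray(indices, dtype=np.int64)


# ---------------------------------------------------------------------------
# public waveform API
# ---------------------------------------------------------------------------

def read_ecg(path: os.PathLike | str, format: str = "csv") -> ECGRecord:
    """Read an ECG record from ``path``.

    ``format`` is ``"csv"`` (two columns: time s, amplitude mV, fixed step)
    or ``"wfdb"`` (single-signal format-16 record; a sibling ``.atr``
    annotation file, when present, populates ``truth_peaks``).
    """
    path = Path(path)
    if format == "csv":
        return _read_ecg_csv(path)
    if format == "wfdb":
        return _read_ecg_wfdb(path)
    raise ValueError(f"unknown ECG format {format!r} (expected 'csv' or 'wfdb')")


def write_ecg(record: ECGRecord, path: os.PathLike | str, format: str = "csv") -> None:
    """Write ``record`` so that :func:`read_ecg` round-trips it.

    CSV stores the waveform only; the WFDB subset also writes ``truth_peaks``
    as an ``.atr`` annotation stream when they are present.
    """
    path = Path(path)
    if format == "csv":
        _write_ecg_csv(record, path)
    elif format == "wfdb":
        _write_ecg_wfdb(record, path)
    else:
        raise ValueError(f"unknown ECG format {format!r} (expected 'csv' or 'wfdb')")


# ---------------------------------------------------------------------------
# RRI text I/O
# ---------------------------------------------------------------------------

def read_rri(path: os.PathLike | str) -> RRISeries:
    """Read a plain-text interval list (seconds, one per line, ``#`` comments)."""
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    intervals = []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        try:
            value = float(stripped)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: not a number: {stripped!r}") from None
        if value <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive interval {value}")
        intervals.append(value)
    if not intervals:
        raise FormatError(f"{path}: no intervals found")
    return RRISeries(intervals=np.asarray(intervals))


def write_rri(series: RRISeries, path: os.PathLike | str) -> None:
    """Write intervals one per line with microsecond precision."""
    path = Path(path)
    try:
        path.write_text("".join(f"{x:.6f}\n" for x in series.intervals))
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
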