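"""Waveform record data model and file I/O.

A :class:`WaveformRecord` is a named, uniformly sampled multichannel signal —
typically one ECG channel in mV and one ABP channel in mmHg sharing a common
sampling rate (125 Hz for ICU-monitor style records).  Two on-disk formats are
supported:

* a self-describing CSV dialect: ``#``-prefixed header lines carry
  ``record_id``, ``fs``, ``t0`` and per-channel units, followed by a normal
  header row of channel names and one row per sample;
* a minimal WFDB-style pair (``.hea`` text header + format-16 ``.dat`` binary
  signal), covering just the header fields needed for ICU-monitor records —
  not the full standard.

Sample indexing is 0-based everywhere; time intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError

_VALID_ANNOTATION_KINDS = ("r_peak", "abp_peak", "abp_trough")


@dataclass
class WaveformRecord:
    """A uniformly sampled multichannel physiological signal.

    Parameters
    ----------
    record_id : str
        Free-text label for the record.
    fs : float
        Sampling rate in Hz; must be positive.
    channels : dict of str -> ndarray
        Ordered map channel-name -> 1-D sample array.  All channels must have
        identical length and finite values.
    units : dict of str -> str
        Unit string per channel (e.g. ``"mV"``, ``"mmHg"``).
    t0 : float
        Start offset of sample 0 in seconds (default 0).
    """

    record_id: str
    fs: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise FormatError("a record needs at least one channel")
        clean: dict[str, np.ndarray] = {}
        lengths = set()
        for name, data in self.channels.items():
            arr = np.asarray(data, dtype=float)
            if arr.ndim != 1:
                raise FormatError(f"channel {name!r} is not 1-D")
            if arr.size == 0:
                raise FormatError(f"channel {name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"channel {name!r} contains non-finite samples")
            clean[name] = arr
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise FormatError(f"ragged channel lengths: { {k: v.size for k, v in clean.items()} }")
        self.channels = clean
        self.units = {k: self.units.get(k, "") for k in clean}

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WaveformRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.t0 == other.t0
            and self.units == other.units
            and self.channel_names == other.channel_names
            and all(np.array_equal(self.channels[k], other.channels[k]) for k in self.channels)
        )


@dataclass
class BeatAnnotation:
    """Sorted sample indices of detected fiducial points.

    ``kind`` is one of ``r_peak``, ``abp_peak``, ``abp_trough``.
    """

    indices: np.ndarray
    kind: str
    n_samples: int | None = None  # length of the annotated signal, if known

    def __post_init__(self) -> None:
        if self.kind not in _VALID_ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("annotation indices must be 1-D")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("annotation indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("annotation indices must be non-negative")
        if self.n_samples is not None and idx.size and idx[-1] >= self.n_samples:
            raise ValueError("annotation index beyond end of signal")
        self.indices = idx

    def __len__(self) -> int:
        return self.indices.size

    def times(self, fs: float) -> np.ndarray:
        """Fiducial times in seconds for a sampling rate ``fs``."""
        return self.indices / fs


# ---------------------------------------------------------------------------
# CSV format
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"^#\s*([\w-]+)\s*:\s*(.*)$")


def _write_csv(record: WaveformRecord, path: Path) -> None:
    units = ", ".join(f"{k}={v}" for k, v in record.units.items())
    with open(path, "w", newline="") as fh:
        fh.write("# ecg2bp-record: 1\n")
        fh.write(f"# record_id: {record.record_id}\n")
        fh.write(f"# fs: {record.fs!r}\n")
        fh.write(f"# t0: {record.t0!r}\n")
        fh.write(f"# units: {units}\n")
        df = pd.DataFrame({k: v for k, v in record.channels.items()})
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> WaveformRecord:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = _META_RE.match(line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
            elif line.strip():
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric samples ({exc})") from exc
    if df.empty or not len(df.columns):
        raise FormatError(f"{path}: no channels found")
    if df.isna().any().any():
        # pandas fills ragged rows with NaN; treat as a structural problem
        raise FormatError(f"{path}: ragged channel lengths or missing samples")
    units: dict[str, str] = {}
    for part in meta.get("units", "").split(","):
        if "=" in part:
            k, v = part.split("=", 1)
            units[k.strip()] = v.strip()
    try:
        fs = float(meta["fs"]) if "fs" in meta else None
    except ValueError as exc:
        raise FormatError(f"{path}: bad fs value {meta['fs']!r}") from exc
    if fs is None:
        raise FormatError(f"{path}: missing '# fs:' header line")
    return WaveformRecord(
        record_id=meta.get("record_id", path.stem),
        fs=fs,
        channels={c: df[c].to_numpy() for c in df.columns},
        units=units,
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# Minimal WFDB-style format (header + format-16 signal file)
# ---------------------------------------------------------------------------

def _write_wfdb(record: WaveformRecord, path: Path) -> None:
    """Write ``<stem>.hea`` and ``<stem>.dat`` (format 16, little-endian int16).

    Per-channel gain is chosen so the signal spans most of the int16 range;
    round-tripping is lossless only to that quantization step.
    """
    stem = path.with_suffix("")
    n_sig = len(record.channels)
    n = record.n_samples
    digital = np.empty((n, n_sig), dtype=np.int16)
    lines = [f"{stem.name} {n_sig} {record.fs:g} {n}"]
    for j, (name, x) in enumerate(record.channels.items()):
        maxabs = float(np.max(np.abs(x)))
        gain = 30000.0 / maxabs if maxabs > 0 else 200.0
        d = np.rint(x * gain).astype(np.int64)
        d = np.clip(d, -32768, 32767)
        digital[:, j] = d.astype(np.int16)
        unit = record.units.get(name, "") or "adu"
        lines.append(
            f"{stem.name}.dat 16 {gain:.6f}(0)/{unit} 16 0 {digital[0, j]} 0 0 {name}"
        )
    with open(stem.with_suffix(".hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    digital.tofile(stem.with_suffix(".dat"))


def _read_wfdb(path: Path) -> WaveformRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: bad record line {lines[0]!r}")
    rec_name, n_sig, fs, n = head[0], int(head[1]), float(head[2]), int(head[3])
    if len(lines) - 1 < n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")
    names: list[str] = []
    gains: list[float] = []
    baselines: list[int] = []
    units: dict[str, str] = {}
    dat_name = None
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_name = parts[0]
        if parts[1] not in ("16", "16+0"):
            raise FormatError(f"{hea}: only format 16 is supported, got {parts[1]!r}")
        gain_spec = parts[2]
        m = re.match(r"^([-\d.eE+]+)(?:\((-?\d+)\))?(?:/(\S+))?$", gain_spec)
        if not m:
            raise FormatError(f"{hea}: bad gain spec {gain_spec!r}")
        gains.append(float(m.group(1)))
        baselines.append(int(m.group(2) or 0))
        name = parts[-1]
        names.append(name)
        if m.group(3):
            units[name] = m.group(3)
    dat = hea.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(dat)
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n * n_sig:
        raise FormatError(f"{dat}: expected {n * n_sig} samples, found {raw.size}")
    digital = raw.reshape(n, n_sig)
    channels = {
        name: (digital[:, j].astype(float) - baselines[j]) / gains[j]
        for j, name in enumerate(names)
    }
    return WaveformRecord(record_id=rec_name, fs=fs, channels=channels, units=units)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def read_record(path: str | os.PathLike, format: str = "csv") -> WaveformRecord:
    """Read a waveform record from disk.

    Parameters
    ----------
    path : path-like
        File to read.  For ``format="wfdb"`` this may be either the ``.hea``
        file or the record stem.
    format : {"csv", "wfdb"}
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: WaveformRecord, path: str | os.PathLike, format: str = "csv") -> Path:
    """Write a record to disk; returns the path written.

    The output is re-readable by :func:`read_record` with channel values
    preserved to the format's declared precision (exact for CSV within float
    repr, quantized to the per-channel gain for WFDB format 16).
    """
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
        return path
    if format == "wfdb":
        _write_wfdb(record, path)
        return path.with_suffix(".hea")
    raise ValueError(f"unknown format {format!r}")


def slice_record(record: WaveformRecord, start_s: float, end_s: float) -> WaveformRecord:
    """Extract the half-open time interval ``[start_s, end_s)`` as a new record.

    Bounds are relative to the start of the record (not ``t0``); ``t0`` of the
    result is shifted accordingly.
    """
    if not (0 <= start_s < end_s <= record.duration + 1e-12):
        raise RangeError(
            f"slice [{start_s}, {end_s}) outside record of duration {record.duration:.6g} s"
        )
    i0 = int(round(start_s * record.fs))
    i1 = int(round(end_s * record.fs))
    i1 = min(i1, record.n_samples)
    return WaveformRecord(
        record_id=record.record_id,
        fs=record.fs,
        channels={k: v[i0:i1].copy() for k, v in record.channels.items()},
        units=dict(record.units),
        t0=record.t0 + i0 / record.fs,
    )
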