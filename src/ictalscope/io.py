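"""Reading and writing EEG traces and seizure-interval annotations.

Traces travel as :class:`EEGRecord` (channels x samples, microvolts, with a
sampling rate); ground truth travels as :class:`SeizureAnnotation`, an ordered
list of half-open ``[onset_s, offset_s)`` intervals in record time.

Supported on-disk formats:

* ``csv`` — one column per channel, with a YAML sidecar ``<path>.yaml``
  holding ``fs`` and ``record_id``;
* ``bin`` — flat little-endian float32 (channel-major), same sidecar;
* ``edf`` — European Data Format; read via :mod:`mne`, written by a minimal
  16-bit writer sufficient for round-tripping signals + sampling rate.

Annotations are CSV files with columns ``onset_s,offset_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EEGRecord",
    "SeizureAnnotation",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]

_FORMATS = ("csv", "bin", "edf")


@dataclass
class EEGRecord:
    """A continuous EEG trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts. A 1-D array is promoted to one channel.
    fs : float
        Sampling rate in samples/s.
    record_id : str
        Identifier used in manifests and reports.
    start_time_s : float
        Offset of sample 0 in seconds (0 unless the record is a excerpt).
    """

    samples: np.ndarray
    fs: float
    record_id: str = "record"
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a (n_channels, n_samples) array with n_samples >= 1")
        if self.samples.shape[0] < 1:
            raise ValueError("record must have at least one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, i: int = 0) -> np.ndarray:
        """1-D view of channel *i*."""
        return self.samples[i]


@dataclass
class SeizureAnnotation:
    """Sorted, non-overlapping seizure intervals ``[onset_s, offset_s)``."""

    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b)) for a, b in self.events]
        self.events.sort()
        bad = [i for i, (a, b) in enumerate(self.events) if not a < b]
        if bad:
            raise ValueError(f"inverted or empty intervals at rows {bad}")
        overl = [
            i + 1
            for i in range(len(self.events) - 1)
            if self.events[i + 1][0] < self.events[i][1]
        ]
        if overl:
            raise ValueError(f"overlapping intervals at rows {overl}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def validate_against(self, record: EEGRecord) -> "SeizureAnnotation":
        """Check every interval lies within the record; returns self."""
        T = record.duration_s
        for a, b in self.events:
            if a < 0 or b > T + 1e-9:
                raise ValueError(f"event ({a}, {b}) outside record of duration {T}")
        return self

    def total_seizure_s(self) -> float:
        return float(sum(b - a for a, b in self.events))


# ---------------------------------------------------------------------------
# trace I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc} (field: fs)")
    with open(sc) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "fs" not in meta:
        raise ValueError(f"sidecar {sc} missing required field 'fs'")
    return meta


def _write_sidecar(path: Path, record: EEGRecord, extra: dict | None = None) -> None:
    meta = {
        "fs": float(record.fs),
        "record_id": record.record_id,
        "n_channels": record.n_channels,
        "n_samples": record.n_samples,
    }
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_record(path: str | Path, format: str | None = None) -> EEGRecord:
    """Read an EEG trace.

    ``format`` is one of ``csv``, ``bin``, ``edf``; inferred from the file
    extension when omitted.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "edf":
        return _read_edf(path)

    meta = _read_sidecar(path)
    fs = float(meta["fs"])
    rid = str(meta.get("record_id", path.stem))
    if fmt == "csv":
        df = pd.read_csv(path, header=None)
        samples = df.to_numpy(dtype=np.float64).T  # columns are channels
    else:  # bin
        raw = np.fromfile(path, dtype="<f4")
        nch = int(meta.get("n_channels", 1))
        if raw.size % nch:
            raise ValueError(f"binary length {raw.size} not divisible by n_channels={nch}")
        samples = raw.astype(np.float64).reshape(nch, -1)
    return EEGRecord(samples=samples, fs=fs, record_id=rid)


def write_record(record: EEGRecord, path: str | Path, format: str | None = None) -> Path:
    """Write a trace so that :func:`read_record` recovers fs and shape."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "edf":
        _write_edf(record, path)
    elif fmt == "csv":
        pd.DataFrame(record.samples.T).to_csv(path, header=False, index=False)
        _write_sidecar(path, record)
    else:
        record.samples.astype("<f4").tofile(path)
        _write_sidecar(path, record)
    return path


# ---------------------------------------------------------------------------
# EDF
#
# Reading uses mne. Writing is a deliberately small EDF writer: one data
# record per second, 16-bit samples, physical range from the data. Only the
# fields read_record consumes (signals, fs, channel count) are guaranteed.


def _read_edf(path: Path) -> EEGRecord:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts
    return EEGRecord(samples=data * 1e6, fs=fs, record_id=path.stem)


def _write_edf(record: EEGRecord, path: Path) -> None:
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nch = record.n_channels
    # pad to a whole number of 1-s data records
    nrec = int(np.ceil(record.n_samples / fs))
    x = np.zeros((nch, nrec * fs))
    x[:, : record.n_samples] = record.samples

    phys_max = float(np.max(np.abs(x)))
    phys_max = max(phys_max, 1.0)
    dig_min, dig_max = -32768, 32767
    scaled = np.clip(np.round(x / phys_max * dig_max), dig_min, dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * nch), 8),  # header bytes
            pad("", 44),
            pad(str(nrec), 8),
            pad("1", 8),  # record duration, s
            pad(str(nch), 4),
        ]
    )
    labels = b"".join(pad(f"EEG ch{i}", 16) for i in range(nch))
    transducer = b"".join(pad("", 80) for _ in range(nch))
    dim = b"".join(pad("uV", 8) for _ in range(nch))
    pmin = b"".join(pad(f"{-phys_max:.6g}"[:8], 8) for _ in range(nch))
    pmax = b"".join(pad(f"{phys_max:.6g}"[:8], 8) for _ in range(nch))
    dmin = b"".join(pad(str(dig_min), 8) for _ in range(nch))
    dmax = b"".join(pad(str(dig_max), 8) for _ in range(nch))
    prefilt = b"".join(pad("", 80) for _ in range(nch))
    nsamp = b"".join(pad(str(fs), 8) for _ in range(nch))
    reserved = b"".join(pad("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin + dmax + prefilt + nsamp + reserved)
        for r in range(nrec):
            for c in range(nch):
                fh.write(scaled[c, r * fs : (r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotations(path: str | Path) -> SeizureAnnotation:
    """Read ``onset_s,offset_s`` CSV into a validated annotation."""
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"annotation file {path} missing column {col!r}")
    events = list(zip(df["onset_s"].astype(float), df["offset_s"].astype(float)))
    return SeizureAnnotation(events)


def write_annotations(annotation: SeizureAnnotation | Sequence[tuple[float, float]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events = list(annotation)
    pd.DataFrame(events, columns=["onset_s", "offset_s"]).to_csv(path, index=False)
    return path
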