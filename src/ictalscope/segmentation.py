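"""Sliding-window extraction of 5-s EEG segments.

Training segments come from two window schemes: seizure windows slide inside
each annotated event with a 0.25-s stride (seizure EEG is scarce), and
non-seizure windows tile the 5 minutes before and after each event with a
2.5-s stride. Test-time windows tile the whole record at 2.5 s. For a span of
``S`` seconds and stride ``h`` the window count is ``floor((S - 5)/h) + 1``
(zero when ``S < 5``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecord, SeizureAnnotation

__all__ = [
    "Segment",
    "WINDOW_S",
    "extract_seizure_segments",
    "extract_nonseizure_segments",
    "continuous_windows",
    "label_windows",
]

WINDOW_S = 5.0
_EPS = 1e-9  # float guard for start + 5 <= bound comparisons


@dataclass
class Segment:
    """One 5-s excerpt of a record, optionally labeled."""

    record_id: str
    start_s: float
    samples: np.ndarray  # native-rate, length round(5 * fs)
    label: str | None = None  # "seizure" | "non-seizure" | None
    channel: int = 0

    @property
    def duration_s(self) -> float:
        return WINDOW_S


def _slice(record: EEGRecord, start_s: float, channel: int = 0) -> np.ndarray:
    i0 = int(round(start_s * record.fs))
    n = int(round(WINDOW_S * record.fs))
    return record.samples[channel, i0 : i0 + n]


def _window_starts(lo: float, hi: float, stride_s: float) -> np.ndarray:
    """Starts lo, lo+h, ... while start + 5 <= hi."""
    span = hi - lo
    if span < WINDOW_S - _EPS:
        return np.empty(0)
    count = int(np.floor((span - WINDOW_S) / stride_s + _EPS)) + 1
    return lo + stride_s * np.arange(count)


def _overlaps_any(start: float, annotation: SeizureAnnotation) -> bool:
    end = start + WINDOW_S
    return any(max(start, a) < min(end, b) for a, b in annotation)


def extract_seizure_segments(
    record: EEGRecord,
    annotation: SeizureAnnotation,
    stride_s: float = 0.25,
    channel: int = 0,
) -> list[Segment]:
    """Seizure-labeled windows sliding inside each annotated event."""
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    out = []
    for a, b in annotation:
        for s in _window_starts(a, min(b, record.duration_s), stride_s):
            out.append(Segment(record.record_id, float(s), _slice(record, s, channel), "seizure", channel))
    return out


def extract_nonseizure_segments(
    record: EEGRecord,
    annotation: SeizureAnnotation,
    flank_s: float = 300.0,
    stride_s: float = 2.5,
    channel: int = 0,
) -> list[Segment]:
    """Non-seizure windows tiling the flanks before and after each event.

    Flanks are clipped at record boundaries, and any window overlapping any
    annotated event is dropped (prevents label leakage between neighbouring
    events).
    """
    if stride_s <= 0 or flank_s <= 0:
        raise ValueError("stride_s and flank_s must be positive")
    T = record.duration_s
    out = []
    for a, b in annotation:
        for lo, hi in ((max(a - flank_s, 0.0), a), (b, min(b + flank_s, T))):
            for s in _window_starts(lo, hi, stride_s):
                if not _overlaps_any(float(s), annotation):
                    out.append(
                        Segment(record.record_id, float(s), _slice(record, s, channel), "non-seizure", channel)
                    )
    return out


def continuous_windows(record: EEGRecord, stride_s: float = 2.5, channel: int = 0) -> list[Segment]:
    """Unlabeled test windows at 0, stride, 2*stride, ... covering the record."""
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    return [
        Segment(record.record_id, float(s), _slice(record, s, channel), None, channel)
        for s in _window_starts(0.0, record.duration_s, stride_s)
    ]


def label_windows(
    segments: list[Segment],
    annotation: SeizureAnnotation,
    overlap_frac: float = 0.5,
) -> np.ndarray:
    """Ground-truth 0/1 labels for continuous windows.

    A window counts as seizure when its total overlap with annotated events
    is at least ``overlap_frac`` of the window length (default half).
    """
    labels = np.zeros(len(segments), dtype=int)
    for i, seg in enumerate(segments):
        s, e = seg.start_s, seg.start_s + WINDOW_S
        ov = sum(max(0.0, min(e, b) - max(s, a)) for a, b in annotation)
        labels[i] = int(ov >= overlap_frac * WINDOW_S - _EPS)
    return labels
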