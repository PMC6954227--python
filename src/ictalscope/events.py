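"""From per-window classifications to seizure events.

The post-processing rule set: positively classified 5-s windows whose start
times fall within 10 s of each other are merged into one candidate event
(span = first start to last start + 5 s); candidates consisting of a single
window are discarded; a surviving candidate is finalized only if its mean
absolute amplitude is at least 1.2 times that of the nearby EEG (symmetric
flanks, other candidates excluded). A finalized event counts as a true
detection when it overlaps any annotated seizure, otherwise as a false
detection; the false-detection rate is false events per hour analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecord, SeizureAnnotation
from .segmentation import WINDOW_S, continuous_windows

__all__ = [
    "DetectedEvent",
    "EventReport",
    "merge_positive_windows",
    "amplitude_gate",
    "match_events",
    "detect_events",
]

_EPS = 1e-9


@dataclass
class DetectedEvent:
    start_s: float
    end_s: float
    n_member_windows: int
    amplitude_ratio: float = float("nan")
    status: str | None = None  # "true_detection" | "false_detection"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventReport:
    n_true: int
    n_missed: int
    n_false: int
    hours_analyzed: float
    event_sensitivity: float  # NaN when no annotated events
    fdr_per_hour: float


def merge_positive_windows(
    positive_starts: np.ndarray,
    stride_s: float = 2.5,
    gap_s: float = 10.0,
) -> list[DetectedEvent]:
    """Join positive windows within ``gap_s`` (start-to-start, inclusive).

    Candidates with a single member window are removed. Returns unmatched,
    ungated candidates with spans [first start, last start + 5].
    """
    starts = np.sort(np.asarray(positive_starts, dtype=float))
    events: list[DetectedEvent] = []
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - starts[j] <= gap_s + _EPS:
            j += 1
        n = j - i + 1
        if n >= 2:
            events.append(DetectedEvent(float(starts[i]), float(starts[j] + WINDOW_S), n))
        i = j + 1
    return events


def amplitude_gate(
    candidate: DetectedEvent,
    record: EEGRecord,
    ratio: float = 1.2,
    min_flank_s: float = 30.0,
    others: list[DetectedEvent] | None = None,
    channel: int = 0,
) -> tuple[bool, float]:
    """Mean-|x| of the event vs its flanks; pass iff ratio >= 1.2 (inclusive).

    Flank length per side is max(event duration, ``min_flank_s``). Samples
    inside any other candidate event are excluded from the flanks; if one
    side is unavailable the other side alone is used, and with no flank at
    all the candidate is rejected fail-safe.
    """
    fs = record.fs
    x = np.abs(record.samples[channel])
    n = x.size
    i0, i1 = int(round(candidate.start_s * fs)), int(round(candidate.end_s * fs))
    i0, i1 = max(i0, 0), min(i1, n)
    if i1 <= i0:
        raise ValueError("candidate outside record")
    event_mean = float(x[i0:i1].mean())

    flank_s = max(candidate.duration_s, min_flank_s)
    f = int(round(flank_s * fs))
    mask = np.zeros(n, dtype=bool)
    mask[max(i0 - f, 0) : i0] = True
    mask[i1 : min(i1 + f, n)] = True
    for ev in others or []:
        if ev is candidate:
            continue
        a, b = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
        mask[max(a, 0) : min(b, n)] = False
    if not mask.any():
        import warnings

        warnings.warn("no flank samples available for amplitude gate; rejecting candidate")
        return False, float("nan")
    flank_mean = float(x[mask].mean())
    r = event_mean / flank_mean if flank_mean > 0 else float("inf")
    return r >= ratio - _EPS, r


def match_events(
    detected: list[DetectedEvent],
    annotation: SeizureAnnotation,
    hours_analyzed: float,
) -> EventReport:
    """Classify detections by overlap with annotated events (half-open).

    A detection overlapping any annotated event is a true detection; an
    annotated event with no overlapping detection is missed. Sensitivity is
    over annotated events; FDR is false detections per hour.
    """
    if hours_analyzed <= 0:
        raise ValueError("hours_analyzed must be positive")
    hit = [False] * len(annotation)
    n_false = 0
    for d in detected:
        overlaps = [
            k for k, (a, b) in enumerate(annotation) if max(d.start_s, a) < min(d.end_s, b)
        ]
        if overlaps:
            d.status = "true_detection"
            for k in overlaps:
                hit[k] = True
        else:
            d.status = "false_detection"
            n_false += 1
    n_ann = len(annotation)
    n_detected_ann = sum(hit)
    sens = n_detected_ann / n_ann if n_ann else float("nan")
    return EventReport(
        n_true=n_detected_ann,
        n_missed=n_ann - n_detected_ann,
        n_false=n_false,
        hours_analyzed=hours_analyzed,
        event_sensitivity=sens,
        fdr_per_hour=n_false / hours_analyzed,
    )


def detect_events(
    record: EEGRecord,
    score_fn,
    annotation: SeizureAnnotation | None = None,
    threshold: float = 0.5,
    stride_s: float = 2.5,
    gap_s: float = 10.0,
    amplitude_ratio: float = 1.2,
    channel: int = 0,
) -> tuple[list[DetectedEvent], EventReport | None]:
    """Full pipeline: windows -> scores -> merge -> amplitude gate -> match.

    ``score_fn`` maps a list of :class:`~ictalscope.segmentation.Segment` to
    an array of seizure probabilities (e.g. a trained classifier behind its
    modality transform). When ``annotation`` is None the report is None and
    only the gated events are returned.
    """
    if record.duration_s < WINDOW_S:
        raise ValueError("record shorter than one 5-s window")
    windows = continuous_windows(record, stride_s=stride_s, channel=channel)
    scores = np.asarray(score_fn(windows), dtype=float)
    if scores.shape != (len(windows),):
        raise ValueError("score_fn must return one score per window")
    positive = [w.start_s for w, s in zip(windows, scores) if s >= threshold]
    candidates = merge_positive_windows(np.array(positive), stride_s=stride_s, gap_s=gap_s)
    final = []
    for cand in candidates:
        ok, r = amplitude_gate(cand, record, ratio=amplitude_ratio, others=candidates, channel=channel)
        cand.amplitude_ratio = r
        if ok:
            final.append(cand)
    report = None
    if annotation is not None:
        report = match_events(final, annotation, hours_analyzed=record.duration_s / 3600.0)
    return final, report
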