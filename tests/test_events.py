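import numpy as np
import pytest

from ictalscope.events import (
    DetectedEvent,
    amplitude_gate,
    detect_events,
    match_events,
    merge_positive_windows,
)
from ictalscope.io import EEGRecord, SeizureAnnotation
from ictalscope.segmentation import WINDOW_S, continuous_windows, label_windows
from ictalscope.synth import SynthConfig, assemble_record


def brute_force_merge(starts, gap_s=10.0):
    """Independent re-statement of the merge/singleton rules."""
    starts = sorted(starts)
    groups, cur = [], []
    for s in starts:
        if cur and s - cur[-1] > gap_s + 1e-9:
            groups.append(cur)
            cur = []
        cur.append(s)
    if cur:
        groups.append(cur)
    return [(g[0], g[-1] + WINDOW_S, len(g)) for g in groups if len(g) >= 2]


class TestMerge:
    def test_contiguous_run_single_event(self):
        ev = merge_positive_windows(np.array([0.0, 2.5, 5.0]))
        assert len(ev) == 1
        e = ev[0]
        assert (e.start_s, e.end_s, e.n_member_windows) == (0.0, 10.0, 3)

    def test_gap_over_10s_leaves_two_singletons_removed(self):
        assert merge_positive_windows(np.array([0.0, 12.5])) == []

    def test_gap_exactly_10s_is_inclusive(self):
        ev = merge_positive_windows(np.array([0.0, 10.0]))
        assert len(ev) == 1 and ev[0].n_member_windows == 2

    def test_empty_input(self):
        assert merge_positive_windows(np.array([])) == []

    def test_idempotent_event_spans(self):
        starts = np.array([0.0, 2.5, 5.0, 30.0, 32.5, 60.0])
        ev1 = merge_positive_windows(starts)
        # re-merging the member start grids reproduces the same events
        for e in ev1:
            members = starts[(starts >= e.start_s) & (starts + WINDOW_S <= e.end_s + 1e-9)]
            ev2 = merge_positive_windows(members)
            assert len(ev2) == 1 and ev2[0].start_s == e.start_s and ev2[0].end_s == e.end_s

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = rng.integers(0, 25)
            starts = np.unique(rng.integers(0, 200, n) * 2.5)
            got = [(e.start_s, e.end_s, e.n_member_windows) for e in merge_positive_windows(starts)]
            assert got == brute_force_merge(starts)


def step_record(event_level, flank_level, ev=(100.0, 130.0), T=300.0, fs=100.0):
    x = np.full(int(T * fs), flank_level, dtype=float)
    x[int(ev[0] * fs) : int(ev[1] * fs)] = event_level
    return EEGRecord(samples=x, fs=fs, record_id="step")


class TestAmplitudeGate:
    def test_double_amplitude_passes(self):
        rec = step_record(2.0, 1.0)
        ok, r = amplitude_gate(DetectedEvent(100.0, 130.0, 3), rec)
        assert ok and r == pytest.approx(2.0)

    def test_no_amplitude_change_fails(self):
        rec = step_record(1.0, 1.0)
        ok, r = amplitude_gate(DetectedEvent(100.0, 130.0, 3), rec)
        assert not ok and r == pytest.approx(1.0)

    def test_boundary_ratio_is_inclusive(self):
        rec = step_record(1.2, 1.0)
        ok, r = amplitude_gate(DetectedEvent(100.0, 130.0, 3), rec)
        assert ok and r == pytest.approx(1.2)

    def test_other_candidates_excluded_from_flanks(self):
        rec = step_record(2.0, 1.0)
        # a second bogus candidate sits in the post flank at the same level
        x = rec.samples[0]
        x[int(140 * rec.fs) : int(150 * rec.fs)] = 2.0
        other = DetectedEvent(140.0, 150.0, 2)
        ok, r = amplitude_gate(DetectedEvent(100.0, 130.0, 3), rec, others=[other])
        assert ok and r == pytest.approx(2.0)

    def test_no_flank_rejects_with_warning(self):
        rec = step_record(2.0, 1.0, ev=(0.0, 300.0))
        with pytest.warns(UserWarning, match="flank"):
            ok, _ = amplitude_gate(DetectedEvent(0.0, 300.0, 5), rec)
        assert not ok


class TestMatchEvents:
    def test_overlap_is_true_detection(self):
        rep = match_events([DetectedEvent(10, 20, 2)], SeizureAnnotation([(15, 40)]), 1.0)
        assert rep.n_true == 1 and rep.n_false == 0

    def test_touching_halfopen_intervals_do_not_overlap(self):
        rep = match_events([DetectedEvent(10, 20, 2)], SeizureAnnotation([(20, 30)]), 1.0)
        assert rep.n_false == 1 and rep.n_missed == 1

    def test_fdr_per_hour(self):
        det = [DetectedEvent(10 * k, 10 * k + 5, 2) for k in range(1, 4)]
        rep = match_events(det, SeizureAnnotation([]), hours_analyzed=6.0)
        assert rep.fdr_per_hour == pytest.approx(0.5)
        assert np.isnan(rep.event_sensitivity)

    def test_missed_events_counted(self):
        rep = match_events([], SeizureAnnotation([(10, 30), (100, 120)]), 1.0)
        assert rep.n_missed == 2 and rep.event_sensitivity == 0.0


@pytest.fixture(scope="module")
def synth_for_events():
    return assemble_record(SynthConfig(total_duration_s=2500.0, n_events=3, seed=21))


class TestDetectEvents:
    def test_oracle_classifier_recovers_all_events(self, synth_for_events):
        """With ground-truth window labels as scores: all events, zero FDR."""
        rec, ann = synth_for_events

        def oracle(windows):
            return label_windows(windows, ann).astype(float)

        detected, report = detect_events(rec, oracle, annotation=ann)
        assert report.n_true == len(ann)
        assert report.n_missed == 0
        assert report.n_false == 0
        assert report.event_sensitivity == 1.0
        assert report.fdr_per_hour == 0.0
        for d in detected:
            assert d.amplitude_ratio >= 1.2

    def test_all_negative_scores_give_zero_events(self, synth_for_events):
        rec, ann = synth_for_events
        detected, report = detect_events(rec, lambda w: np.zeros(len(w)), annotation=ann)
        assert detected == [] and report.n_false == 0

    def test_isolated_positive_window_removed(self, synth_for_events):
        rec, _ = synth_for_events

        def one_positive(windows):
            s = np.zeros(len(windows))
            s[40] = 1.0
            return s

        detected, _ = detect_events(rec, one_positive)
        assert detected == []

    def test_short_record_rejected(self):
        rec = EEGRecord(samples=np.zeros(3000), fs=1000.0)
        with pytest.raises(ValueError):
            detect_events(rec, lambda w: np.zeros(len(w)))

    def test_chunk_invariance(self, synth_for_events):
        """Detection on two overlapping halves reproduces the full-record events."""
        rec, ann = synth_for_events

        def oracle_for(annotation):
            def fn(windows):
                return label_windows(windows, annotation).astype(float)

            return fn

        full, _ = detect_events(rec, oracle_for(ann), annotation=ann)
        T = rec.duration_s
        cut = round((T / 2) / 2.5) * 2.5
        overlap = 120.0
        halves = []
        for lo, hi in ((0.0, cut + overlap), (cut, T)):
            i0, i1 = int(lo * rec.fs), int(hi * rec.fs)
            sub = EEGRecord(samples=rec.samples[:, i0:i1], fs=rec.fs, record_id="half")
            sub_ann = SeizureAnnotation(
                [(a - lo, b - lo) for a, b in ann if a >= lo and b <= hi]
            )
            det, _ = detect_events(sub, oracle_for(sub_ann))
            halves += [(d.start_s + lo, d.end_s + lo) for d in det]
        got = sorted(set(round(a, 1) for a, _ in halves))
        want = sorted(round(d.start_s, 1) for d in full)
        for w in want:  # every full-record event found in some chunk
            assert any(abs(w - g) < 1e-6 for g in got)
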