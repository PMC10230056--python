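import numpy as np
import pytest

from synergait import (GaitEvent, GaitEventList, PostprocessSpec, extract_transitions,
                       match_events, postprocess)

THREE = "3class"
TWO = "2class"


def series(*runs):
    """Build a label series from (label_index, length) runs."""
    return np.concatenate([np.full(n, v, dtype=np.int64) for v, n in runs])


class TestPostprocess:
    def test_short_stance_run_removed_into_swing(self):
        # 80 samples at 400 Hz = 200 ms < the 218.75 ms stance minimum
        x = series((1, 400), (0, 80), (1, 400))
        out = postprocess(x, TWO)
        assert np.all(out == 1)

    def test_weight_acceptance_run_meeting_threshold_retained(self):
        # 22 samples = 55 ms >= 54.69 ms, so the WA run survives
        x = series((2, 200), (0, 22), (1, 200))
        out = postprocess(x, THREE)
        assert np.sum(out == 0) == 22

    def test_weight_acceptance_run_below_threshold_removed(self):
        # 21 samples = 52.5 ms < 54.69 ms
        x = series((2, 200), (0, 21), (1, 200))
        out = postprocess(x, THREE)
        assert np.sum(out == 0) == 0

    def test_clean_series_is_identity(self):
        x = series((0, 30), (1, 100), (2, 100))
        assert np.array_equal(postprocess(x, THREE), x)

    def test_first_run_merges_forward(self):
        x = series((0, 10), (1, 400))
        out = postprocess(x, TWO)
        assert np.all(out == 1)

    def test_idempotence_on_random_series(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 3, size=600)
            once = postprocess(x, THREE)
            twice = postprocess(once, THREE)
            assert np.array_equal(once, twice)

    def test_output_runs_meet_minimum_durations(self):
        rng = np.random.default_rng(6)
        spec = PostprocessSpec()
        for _ in range(10):
            x = rng.integers(0, 2, size=500)
            out = postprocess(x, TWO, spec)
            change = np.flatnonzero(out[1:] != out[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(out)]))
            names = ("ST", "SW")
            # interior runs meet their class minimum
            for s, e in list(zip(starts, ends))[1:-1]:
                assert e - s >= spec.min_samples(names[out[s]])

    def test_empty_series(self):
        assert postprocess(np.array([], dtype=np.int64), TWO).size == 0


class TestExtractTransitions:
    def test_three_class_cycle_events(self):
        x = series((0, 2), (1, 2), (2, 2), (0, 1))  # WA WA SS SS LA LA WA
        events, anomalies = extract_transitions(x, THREE, label_rate_hz=1.0)
        assert [(e.type, e.time_s) for e in events] == [
            ("OFC", 2.0), ("OIC", 4.0), ("IC", 6.0)
        ]
        assert anomalies == []

    def test_constant_series_no_events(self):
        events, _ = extract_transitions(series((1, 50)), THREE)
        assert len(events) == 0

    def test_two_class_alternation(self):
        x = series((0, 10), (1, 8), (0, 10), (1, 8))
        events, _ = extract_transitions(x, TWO, label_rate_hz=400.0)
        assert [e.type for e in events] == ["FC", "IC", "FC"]

    def test_illegal_transition_typed_by_destination(self):
        x = series((0, 5), (2, 5))  # WA -> LA skips SS
        events, anomalies = extract_transitions(x, THREE)
        assert [e.type for e in events] == ["OIC"]  # LA's entry event
        assert len(anomalies) == 1

    def test_time_offset_applied(self):
        x = series((0, 4), (1, 4))
        events, _ = extract_transitions(x, TWO, label_rate_hz=400.0, t0_s=1.0)
        assert events.events[0].time_s == pytest.approx(1.0 + 4 / 400.0)


class TestMatchEvents:
    def test_perfect_prediction(self):
        truth = GaitEventList([GaitEvent("IC", t) for t in (1.0, 2.0, 3.0)])
        rep = match_events(truth, truth).per_type["IC"]
        assert rep["precision"] == rep["recall"] == rep["f1"] == 1.0
        assert rep["mae_ms"] == 0.0

    def test_counts_to_scores_arithmetic(self):
        # 9 exact hits, 1 spurious, 1 miss -> precision=recall=f1=0.9
        truth = GaitEventList([GaitEvent("FC", float(i)) for i in range(10)])
        pred = GaitEventList(
            [GaitEvent("FC", float(i)) for i in range(9)] + [GaitEvent("FC", 20.0)]
        )
        rep = match_events(pred, truth, max_match_ms=400.0).per_type["FC"]
        assert rep["tp"] == 9 and rep["fp"] == 1 and rep["fn"] == 1
        assert rep["precision"] == pytest.approx(0.9)
        assert rep["recall"] == pytest.approx(0.9)
        assert rep["f1"] == pytest.approx(0.9)

    def test_offset_beyond_tolerance_counts_both_ways(self):
        truth = GaitEventList([GaitEvent("IC", 1.0)])
        pred = GaitEventList([GaitEvent("IC", 1.005)])
        rep = match_events(pred, truth, tolerance_ms=2.5).per_type["IC"]
        assert rep["tp"] == 0 and rep["fp"] == 1 and rep["fn"] == 1
        # MAE is over matched pairs regardless of the TP tolerance
        assert rep["mae_ms"] == pytest.approx(5.0)

    def test_relaxed_tolerance_turns_same_pair_into_tp(self):
        truth = GaitEventList([GaitEvent("IC", 1.0)])
        pred = GaitEventList([GaitEvent("IC", 1.005)])
        rep = match_events(pred, truth, tolerance_ms=50.0).per_type["IC"]
        assert rep["tp"] == 1 and rep["fp"] == 0 and rep["fn"] == 0

    def test_greedy_matching_is_one_to_one(self):
        truth = GaitEventList([GaitEvent("IC", 1.0), GaitEvent("IC", 1.2)])
        pred = GaitEventList([GaitEvent("IC", 1.01)])
        rep = match_events(pred, truth, tolerance_ms=50.0).per_type["IC"]
        assert rep["tp"] == 1 and rep["fn"] == 1 and rep["fp"] == 0

    def test_empty_truth_flagged(self):
        pred = GaitEventList([GaitEvent("IC", 1.0)])
        report = match_events(pred, GaitEventList([]), event_types=("IC",))
        assert report.per_type["IC"]["recall"] == 0.0
        assert "IC" in report.empty_truth_types

    def test_metric_bounds_and_harmonic_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            truth = GaitEventList(
                [GaitEvent("IC", float(t)) for t in np.sort(rng.uniform(0, 30, 12))]
            )
            pred = GaitEventList(
                [GaitEvent("IC", float(t)) for t in np.sort(rng.uniform(0, 30, 10))]
            )
            d = match_events(pred, truth, tolerance_ms=200.0).per_type["IC"]
            p, r, f1 = d["precision"], d["recall"], d["f1"]
            assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f1 <= 1.0
            if p + r > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))
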