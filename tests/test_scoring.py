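"""Tap-to-target matching, summary statistics, and scoring invariants."""

import numpy as np
import pytest

from hddrum.catalog import HandSide
from hddrum.scoring import (
    ExtraTapKind,
    TapEvent,
    match_taps,
    score_session,
    summarize,
)
from conftest import make_timeline, objective_of, oracle_best_assignment, random_instance

L, R = HandSide.LEFT, HandSide.RIGHT


@pytest.fixture
def two_target_instance():
    """Targets L@1000 and L@2000 (half-window 450); one hit, one late miss."""
    timeline = make_timeline([1000, 2000], [L, L], half_window=450)
    taps = [TapEvent(1100, L), TapEvent(2600, L)]
    return timeline, taps


class TestMatchTaps:
    def test_hit_miss_and_outside_classification(self, two_target_instance):
        timeline, taps = two_target_instance
        records, extras = match_taps(timeline, taps)
        assert (records[0].accuracy, records[0].latency_ms) == (1, 100)
        assert (records[1].accuracy, records[1].latency_ms) == (0, None)
        assert len(extras) == 1
        assert extras[0].classification is ExtraTapKind.OUTSIDE_ALL_WINDOWS
        assert extras[0].tap.timestamp_ms == 2600

    def test_empty_tap_list_scores_all_zero(self):
        timeline = make_timeline([0, 500, 1000], [L, R, L])
        records, extras = match_taps(timeline, [])
        assert [r.accuracy for r in records] == [0, 0, 0]
        assert extras == []

    def test_exact_taps_score_perfect_with_zero_latency(self):
        timeline = make_timeline([0, 500, 1000], [L, R, L])
        taps = [TapEvent(b.onset_ms, b.hand) for b in timeline.beats]
        records, extras = match_taps(timeline, taps)
        assert all(r.accuracy == 1 and r.latency_ms == 0 for r in records)
        assert extras == []

    def test_closest_tap_wins_surplus_logged(self):
        timeline = make_timeline([1000], [L], half_window=400)
        taps = [TapEvent(1200, L), TapEvent(1050, L)]
        records, extras = match_taps(timeline, taps)
        assert records[0].latency_ms == 50
        assert [e.classification for e in extras] == [ExtraTapKind.SURPLUS_IN_WINDOW]

    def test_equidistant_tie_goes_to_earlier_tap(self):
        timeline = make_timeline([1000], [L], half_window=400)
        records, _ = match_taps(timeline, [TapEvent(1100, L), TapEvent(900, L)])
        assert records[0].latency_ms == -100

    def test_wrong_drum_never_rescues_target(self):
        timeline = make_timeline([1000], [L], half_window=400)
        records, extras = match_taps(timeline, [TapEvent(1000, R)])
        assert records[0].accuracy == 0
        assert [e.classification for e in extras] == [ExtraTapKind.WRONG_DRUM_IN_WINDOW]


class TestMatchingProperties:
    def test_oracle_equivalence_on_small_instances(self):
        """Greedy matching attains the exhaustive-search optimum."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            timeline, taps = random_instance(rng)
            records, _ = match_taps(timeline, taps)
            assert objective_of(records) == oracle_best_assignment(timeline, taps)

    def test_every_tap_classified_exactly_once(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            timeline, taps = random_instance(rng, max_targets=8, max_taps=12)
            records, extras = match_taps(timeline, taps)
            matched = [r.matched_tap for r in records if r.matched_tap is not None]
            assert len(matched) + len(extras) == len(taps)
            assert sorted(
                t.timestamp_ms for t in matched + [e.tap for e in extras]
            ) == sorted(t.timestamp_ms for t in taps)

    def test_accurate_latency_within_half_window(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            timeline, taps = random_instance(rng, max_targets=8, max_taps=12)
            records, _ = match_taps(timeline, taps)
            for r in records:
                if r.accuracy == 1:
                    beat = timeline.beats[r.target_index]
                    assert abs(r.latency_ms) <= beat.half_window_ms
                    assert r.matched_tap.drum is beat.hand

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            timeline, taps = random_instance(rng, max_taps=10)
            base = match_taps(timeline, taps)
            shuffled = list(taps)
            rng.shuffle(shuffled)
            assert match_taps(timeline, shuffled)[0] == base[0]

    def test_adding_a_tap_never_reduces_hits(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            timeline, taps = random_instance(rng, max_taps=8)
            before = sum(r.accuracy for r in match_taps(timeline, taps)[0])
            extra = TapEvent(int(rng.integers(0, 4000)), L if rng.integers(2) else R)
            after = sum(r.accuracy for r in match_taps(timeline, taps + [extra])[0])
            assert after >= before


class TestSummarize:
    def test_half_hit_session(self, two_target_instance):
        timeline, taps = two_target_instance
        records, extras = match_taps(timeline, taps)
        s = summarize(records, extras, timeline)
        assert s.mean_accuracy == 0.5
        assert s.mean_latency_ms == 100.0
        assert s.mean_left_latency_ms == 100.0
        assert s.min_left_latency_ms == 100.0
        assert s.mean_right_latency_ms is None
        assert s.mean_right_accuracy is None

    def test_all_miss_session_has_missing_latencies(self):
        timeline = make_timeline([0, 1000], [L, R])
        records, extras = match_taps(timeline, [])
        s = summarize(records, extras, timeline)
        assert s.mean_accuracy == 0.0
        assert s.mean_latency_ms is None
        assert s.min_left_latency_ms is None
        assert s.min_right_latency_ms is None

    def test_perfect_session(self):
        timeline = make_timeline([0, 1000], [L, R])
        taps = [TapEvent(b.onset_ms, b.hand) for b in timeline.beats]
        records, extras = match_taps(timeline, taps)
        s = summarize(records, extras, timeline)
        assert s.mean_accuracy == 1.0
        assert s.mean_latency_ms == 0.0
        assert s.min_left_latency_ms == 0.0

    def test_per_hand_accuracies_weighted_average_to_overall(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            timeline, taps = random_instance(rng, max_targets=8, max_taps=12)
            records, extras = match_taps(timeline, taps)
            s = summarize(records, extras, timeline)
            n_l = sum(1 for b in timeline.beats if b.hand is L)
            n_r = timeline.total_targets - n_l
            combined = (
                (s.mean_left_accuracy or 0.0) * n_l + (s.mean_right_accuracy or 0.0) * n_r
            ) / timeline.total_targets
            assert combined == pytest.approx(s.mean_accuracy)

    def test_zero_targets_rejected(self):
        timeline = make_timeline([])
        with pytest.raises(ValueError):
            summarize([], [], timeline)


class TestScoreSession:
    @pytest.mark.parametrize(("session", "width"), [(1, 1000.0), (22, 100.0)])
    def test_metadata_window_duration_tracks_tempo(self, catalog, session, width):
        result = score_session(catalog.session(session), [])
        assert result.metadata.window_duration_ms == width

    def test_metadata_threshold_and_target_count(self, catalog):
        spec = catalog.session(5)
        result = score_session(spec, [])
        assert result.metadata.success_threshold_pct == 70.0
        assert result.metadata.total_target_beats == len(spec.pattern.events) * spec.n_cycles
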