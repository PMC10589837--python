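"""Shared fixtures and the exhaustive tap-matching oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hddrum.catalog import (
    HandSide,
    TargetBeat,
    TargetTimeline,
    default_catalog,
    _clamped_half_windows,
)
from hddrum.scoring import TapEvent


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_timeline(
    onsets, hands=None, half_window=250.0, tempo_bpm=60.0, session_index=0
) -> TargetTimeline:
    """Build a timeline with explicit onsets; windows clamped to stay disjoint."""
    onsets = [int(o) for o in onsets]
    if hands is None:
        hands = [HandSide.LEFT] * len(onsets)
    halves = _clamped_half_windows(onsets, half_window)
    beats = tuple(
        TargetBeat(onset_ms=o, hand=h, half_window_ms=w)
        for o, h, w in zip(onsets, hands, halves)
    )
    return TargetTimeline(session_index=session_index, beats=beats, tempo_bpm=tempo_bpm)


def random_instance(rng: np.random.Generator, max_targets=6, max_taps=6):
    """A random (timeline, taps) scoring instance with disjoint windows."""
    n = int(rng.integers(1, max_targets + 1))
    gaps = rng.integers(150, 1000, size=n)
    onsets = np.cumsum(gaps) - gaps[0]
    hands = [HandSide.LEFT if b else HandSide.RIGHT for b in rng.integers(0, 2, size=n)]
    half = float(rng.integers(60, 500))
    timeline = make_timeline(onsets, hands, half_window=half)
    m = int(rng.integers(0, max_taps + 1))
    lo, hi = -300, int(onsets[-1]) + 300
    taps = [
        TapEvent(
            timestamp_ms=max(0, int(rng.integers(lo, hi + 1))),
            drum=HandSide.LEFT if rng.integers(0, 2) else HandSide.RIGHT,
        )
        for _ in range(m)
    ]
    return timeline, taps


def oracle_best_assignment(timeline: TargetTimeline, taps) -> tuple[int, float]:
    """Exhaustive search over one-to-one tap-to-target assignments.

    Returns the lexicographic optimum (number of accurate pairs, minus the
    summed absolute latency over accurate pairs). A pair is accurate when
    the tap is on the target's drum and inside its window; assigning an
    inaccurate pair can never improve the objective, so only accurate-
    eligible pairs need enumerating for the search to be exhaustive.
    """
    eligible: list[list[int]] = []
    for tap in taps:
        opts = [
            j
            for j, beat in enumerate(timeline.beats)
            if tap.drum is beat.hand
            and abs(tap.timestamp_ms - beat.onset_ms) <= beat.half_window_ms
        ]
        eligible.append(opts)

    best = (0, 0.0)

    def recurse(i: int, used: frozenset[int], score: int, neg_lat: float) -> None:
        nonlocal best
        if i == len(taps):
            best = max(best, (score, neg_lat))
            return
        recurse(i + 1, used, score, neg_lat)  # leave tap unassigned
        for j in eligible[i]:
            if j not in used:
                lat = abs(taps[i].timestamp_ms - timeline.beats[j].onset_ms)
                recurse(i + 1, used | {j}, score + 1, neg_lat - lat)

    recurse(0, frozenset(), 0, 0.0)
    return best


def objective_of(records) -> tuple[int, float]:
    """(number accurate, -sum |latency| over accurate) of a match result."""
    hits = [r for r in records if r.accuracy == 1]
    return len(hits), -float(sum(abs(r.latency_ms) for r in hits))
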