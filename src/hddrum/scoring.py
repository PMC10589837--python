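"""Tap-to-target matching and per-session performance statistics.

A tap is accurate (scored 1) when it lands on the correct drum inside the
symmetric hit window around a target onset; missed targets, wrong-drum
taps, and surplus taps are scored 0. Because timelines guarantee pairwise
disjoint windows, every tap has at most one owning target, which makes the
greedy per-target match (closest correct-drum tap, earlier tap on ties)
globally optimal.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

from hddrum.catalog import (
    HandSide,
    SessionSpec,
    TargetTimeline,
    build_timeline,
    window_width_for_tempo,
)

SUCCESS_THRESHOLD_PCT = 70.0


@dataclass(frozen=True)
class TapEvent:
    """One screen tap: phase-relative timestamp (ms) and drum side."""

    timestamp_ms: int
    drum: HandSide

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise ValueError("timestamp_ms must be >= 0")


@dataclass(frozen=True)
class ScoreRecord:
    """Score for one target beat: binary accuracy and signed latency.

    Latency is tap minus onset, so positive means late. It is present iff
    a tap matched the target.
    """

    target_index: int
    hand: HandSide
    accuracy: int
    matched_tap: Optional[TapEvent] = None
    latency_ms: Optional[int] = None


class ExtraTapKind(str, enum.Enum):
    SURPLUS_IN_WINDOW = "surplus_in_window"
    WRONG_DRUM_IN_WINDOW = "wrong_drum_in_window"
    OUTSIDE_ALL_WINDOWS = "outside_all_windows"


@dataclass(frozen=True)
class ExtraTapRecord:
    """A tap that matched no target; always scored 0."""

    tap: TapEvent
    classification: ExtraTapKind
    accuracy: int = 0


@dataclass(frozen=True)
class SessionSummary:
    """The eight per-session summary statistics of the output file.

    Latency means are over matched (accurate) taps only; minimum latencies
    are the best absolute latency per hand. Fields are None — never 0 —
    when no qualifying tap exists.
    """

    mean_latency_ms: Optional[float]
    mean_accuracy: float
    mean_left_latency_ms: Optional[float]
    mean_right_latency_ms: Optional[float]
    min_left_latency_ms: Optional[float]
    min_right_latency_ms: Optional[float]
    mean_left_accuracy: Optional[float]
    mean_right_accuracy: Optional[float]

    FIELDS = (
        "mean_latency_ms",
        "mean_accuracy",
        "mean_left_latency_ms",
        "mean_right_latency_ms",
        "min_left_latency_ms",
        "min_right_latency_ms",
        "mean_left_accuracy",
        "mean_right_accuracy",
    )


@dataclass(frozen=True)
class SessionMetadata:
    """Session-difficulty metadata carried in every output file."""

    total_target_beats: int
    window_duration_ms: float
    success_threshold_pct: float


@dataclass(frozen=True)
class SessionResult:
    session_index: int
    records: tuple[ScoreRecord, ...]
    extras: tuple[ExtraTapRecord, ...]
    summary: SessionSummary
    metadata: SessionMetadata


class OverlappingWindowsError(RuntimeError):
    """Timeline windows overlap; matching would be ambiguous."""


def _owning_target(timeline: TargetTimeline, onsets: Sequence[int], t: int) -> Optional[int]:
    """Index of the unique target whose window contains time ``t``, if any."""
    i = bisect_left(onsets, t)
    for j in (i - 1, i):
        if 0 <= j < len(onsets):
            beat = timeline.beats[j]
            if abs(t - beat.onset_ms) <= beat.half_window_ms:
                return j
    return None


def match_taps(
    timeline: TargetTimeline, taps: Sequence[TapEvent]
) -> tuple[list[ScoreRecord], list[ExtraTapRecord]]:
    """Match taps to target beats and classify every tap exactly once.

    Each target takes at most one tap: among correct-drum taps inside its
    window, the one with minimum absolute latency (ties go to the earlier
    tap). Unmatched taps become extra-tap records: surplus correct-drum
    taps in a window, wrong-drum taps in a window, or taps outside all
    windows.
    """
    for a, b in zip(timeline.beats, timeline.beats[1:]):
        if a.onset_ms + a.half_window_ms >= b.onset_ms - b.half_window_ms:
            raise OverlappingWindowsError(
                f"windows overlap between onsets {a.onset_ms} and {b.onset_ms}"
            )
    onsets = [b.onset_ms for b in timeline.beats]
    order = sorted(range(len(taps)), key=lambda i: (taps[i].timestamp_ms, i))

    in_window: dict[int, list[int]] = {}
    owner: list[Optional[int]] = [None] * len(taps)
    for i in order:
        j = _owning_target(timeline, onsets, taps[i].timestamp_ms)
        owner[i] = j
        if j is not None:
            in_window.setdefault(j, []).append(i)

    matched_tap_idx: dict[int, int] = {}
    for j, candidates in in_window.items():
        correct = [i for i in candidates if taps[i].drum is timeline.beats[j].hand]
        if correct:
            matched_tap_idx[j] = min(
                correct,
                key=lambda i: (
                    abs(taps[i].timestamp_ms - onsets[j]),
                    taps[i].timestamp_ms,
                    i,
                ),
            )

    records: list[ScoreRecord] = []
    for j, beat in enumerate(timeline.beats):
        i = matched_tap_idx.get(j)
        if i is None:
            records.append(ScoreRecord(target_index=j, hand=beat.hand, accuracy=0))
        else:
            records.append(
                ScoreRecord(
                    target_index=j,
                    hand=beat.hand,
                    accuracy=1,
                    matched_tap=taps[i],
                    latency_ms=taps[i].timestamp_ms - beat.onset_ms,
                )
            )

    extras: list[ExtraTapRecord] = []
    matched_set = set(matched_tap_idx.values())
    for i in order:
        if i in matched_set:
            continue
        j = owner[i]
        if j is None:
            kind = ExtraTapKind.OUTSIDE_ALL_WINDOWS
        elif taps[i].drum is timeline.beats[j].hand:
            kind = ExtraTapKind.SURPLUS_IN_WINDOW
        else:
            kind = ExtraTapKind.WRONG_DRUM_IN_WINDOW
        extras.append(ExtraTapRecord(tap=taps[i], classification=kind))
    return records, extras


def _mean(values: Sequence[float]) -> Optional[float]:
    return sum(values) / len(values) if values else None


def summarize(
    records: Sequence[ScoreRecord],
    extras: Sequence[ExtraTapRecord],
    timeline: TargetTimeline,
) -> SessionSummary:
    """Compute the eight summary statistics from complete score records."""
    if timeline.total_targets == 0:
        raise ValueError("cannot summarize a session with zero targets")
    if len(records) != timeline.total_targets:
        raise ValueError("records must contain exactly one entry per target")

    def side(hand: HandSide) -> list[ScoreRecord]:
        return [r for r in records if r.hand is hand]

    lat = [r.latency_ms for r in records if r.latency_ms is not None]
    left, right = side(HandSide.LEFT), side(HandSide.RIGHT)
    lat_l = [r.latency_ms for r in left if r.latency_ms is not None]
    lat_r = [r.latency_ms for r in right if r.latency_ms is not None]
    return SessionSummary(
        mean_latency_ms=_mean(lat),
        mean_accuracy=sum(r.accuracy for r in records) / len(records),
        mean_left_latency_ms=_mean(lat_l),
        mean_right_latency_ms=_mean(lat_r),
        min_left_latency_ms=min((abs(v) for v in lat_l), default=None),
        min_right_latency_ms=min((abs(v) for v in lat_r), default=None),
        mean_left_accuracy=_mean([r.accuracy for r in left]),
        mean_right_accuracy=_mean([r.accuracy for r in right]),
    )


def score_session(
    spec: SessionSpec,
    taps: Sequence[TapEvent],
    success_threshold_pct: float = SUCCESS_THRESHOLD_PCT,
) -> SessionResult:
    """Score a full session: timeline expansion, matching, and summary."""
    timeline = build_timeline(spec)
    records, extras = match_taps(timeline, taps)
    summary = summarize(records, extras, timeline)
    metadata = SessionMetadata(
        total_target_beats=timeline.total_targets,
        window_duration_ms=window_width_for_tempo(spec.tempo_bpm),
        success_threshold_pct=success_threshold_pct,
    )
    return SessionResult(
        session_index=spec.index,
        records=tuple(records),
        extras=tuple(extras),
        summary=summary,
        metadata=metadata,
    )
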