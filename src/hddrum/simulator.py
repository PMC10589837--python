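"""Virtual tapper: synthetic tap streams with controlled timing behavior.

The tapper follows the standard sensorimotor-synchronization noise model:
each target elicits a tap with probability 1 - miss_prob, offset from the
onset by a Gaussian asynchrony (mean asynchrony + jitter), landing on the
wrong drum with a small probability; spurious extra taps arrive as a
homogeneous Poisson stream. All draws come from one seeded generator, so a
simulated participant is fully replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from hddrum.adherence import EngagementRecord, new_tablet_id
from hddrum.catalog import HandSide, ProgramCatalog, TargetTimeline, build_timeline
from hddrum.progression import (
    FeedbackKind,
    ProgressionState,
    apply_result,
    initial_state,
)
from hddrum.scoring import SessionResult, TapEvent, score_session

#: Dead time (ms) appended after the last window when drawing extra taps.
_TAIL_MS = 1000.0


@dataclass(frozen=True)
class TapperProfile:
    """Behavioral parameters of a simulated participant.

    mean_asynchrony_ms: signed systematic offset of taps from onsets
      (negative = anticipatory, the usual finding in paced tapping).
    jitter_sd_ms: trial-to-trial timing variability (Gaussian SD).
    miss_prob: probability a target elicits no tap at all.
    extra_rate_hz: rate of spurious taps (Poisson, events/second).
    wrong_hand_prob: probability a produced tap lands on the wrong drum.
    """

    mean_asynchrony_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    miss_prob: float = 0.0
    extra_rate_hz: float = 0.0
    wrong_hand_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_prob", "wrong_hand_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_sd_ms < 0 or self.extra_rate_hz < 0:
            raise ValueError("jitter_sd_ms and extra_rate_hz must be >= 0")


@dataclass(frozen=True)
class TrainingPlan:
    """Practice schedule for a simulated program walk-through."""

    sessions_per_week: int = 5
    weeks: int = 8

    def __post_init__(self) -> None:
        if self.sessions_per_week < 1 or self.weeks < 1:
            raise ValueError("plan fields must be >= 1")


def simulate_taps(
    timeline: TargetTimeline,
    profile: TapperProfile,
    rng: Optional[np.random.Generator] = None,
) -> list[TapEvent]:
    """Generate one session's tap stream for the given tapper profile."""
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    taps: list[TapEvent] = []
    for beat in timeline.beats:
        if rng.random() < profile.miss_prob:
            continue
        t = beat.onset_ms + rng.normal(profile.mean_asynchrony_ms, profile.jitter_sd_ms)
        drum = beat.hand
        if rng.random() < profile.wrong_hand_prob:
            drum = drum.opposite
        taps.append(TapEvent(timestamp_ms=max(0, round(t)), drum=drum))

    if profile.extra_rate_hz > 0 and timeline.beats:
        last = timeline.beats[-1]
        span_ms = last.onset_ms + last.half_window_ms + _TAIL_MS
        n_extra = rng.poisson(profile.extra_rate_hz * span_ms / 1000.0)
        times = rng.uniform(0.0, span_ms, size=n_extra)
        sides = rng.integers(0, 2, size=n_extra)
        for t, s in zip(times, sides):
            taps.append(
                TapEvent(
                    timestamp_ms=round(t),
                    drum=HandSide.LEFT if s == 0 else HandSide.RIGHT,
                )
            )
    taps.sort(key=lambda tap: tap.timestamp_ms)
    return taps


def expected_accuracy(profile: TapperProfile, half_window_ms: float) -> float:
    """Closed-form session accuracy for a tapper with no extra taps.

    A target is hit iff the tap is produced (1 - miss_prob), on the right
    drum (1 - wrong_hand_prob), and its Gaussian asynchrony falls inside
    the window: P(|N(mu, sigma)| <= w).
    """
    mu, sd = profile.mean_asynchrony_ms, profile.jitter_sd_ms
    if sd == 0:
        p_window = 1.0 if abs(mu) <= half_window_ms else 0.0
    else:
        p_window = norm.cdf((half_window_ms - mu) / sd) - norm.cdf(
            (-half_window_ms - mu) / sd
        )
    return (1.0 - profile.miss_prob) * (1.0 - profile.wrong_hand_prob) * p_window


def simulate_program(
    catalog: ProgramCatalog,
    profile: TapperProfile,
    plan: TrainingPlan = TrainingPlan(),
    start: datetime = datetime(2024, 1, 1, 10, 0),
) -> tuple[list[EngagementRecord], list[SessionResult], ProgressionState]:
    """Walk the whole program as one simulated participant.

    Each practice slot plays the most advanced unlocked training session
    (repeating it until passed), honoring the unlock rule throughout.
    Engagements are spaced one per day, ``sessions_per_week`` days per
    week. Deterministic for a given profile seed.
    """
    rng = np.random.default_rng(profile.seed)
    tablet_id = new_tablet_id(rng)
    state = initial_state(catalog)
    engagements: list[EngagementRecord] = []
    results: list[SessionResult] = []

    for week in range(plan.weeks):
        for day in range(plan.sessions_per_week):
            session_index = max(i for i in state.unlocked if i >= 1)
            spec = catalog.session(session_index)
            timeline = build_timeline(spec)
            taps = simulate_taps(timeline, profile, rng)
            result = score_session(
                spec, taps, success_threshold_pct=catalog.unlock_threshold * 100
            )
            when = start + timedelta(days=week * 7 + day)
            state, _ = apply_result(
                state,
                session_index,
                result.summary.mean_accuracy,
                timestamp=when.isoformat(),
            )
            engagements.append(
                EngagementRecord(
                    tablet_id=tablet_id,
                    session_index=session_index,
                    start=when,
                    duration_s=spec.nominal_duration_min * 60.0,
                )
            )
            results.append(result)
    return engagements, results, state
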