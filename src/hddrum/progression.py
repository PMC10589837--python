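"""Gamified session progression: unlock rule and end-of-session feedback.

The introduction and the first three training sessions are always
available. From session 3 onward, reaching the accuracy threshold (70% by
default) unlocks the next, more difficult session; otherwise the player is
simply congratulated on completing the session. The unlocked set only ever
grows.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from hddrum.catalog import ProgramCatalog, UNLOCK_THRESHOLD

#: Sessions available before any training: introduction + sessions 1-3.
ALWAYS_UNLOCKED = frozenset({0, 1, 2, 3})

#: Lowest session index whose success can unlock a successor.
FIRST_GATED_SESSION = 3


class FeedbackKind(str, enum.Enum):
    COMPLETED = "completed"
    UNLOCKED_NEXT = "unlocked_next"


class LockedSessionError(ValueError):
    """A result was submitted for a session the player has not unlocked."""


@dataclass(frozen=True)
class ProgressionState:
    """Unlocked sessions, per-session best accuracy, and play history."""

    unlocked: frozenset[int]
    best_accuracy: dict[str, float] = field(default_factory=dict)
    history: tuple[tuple[int, float, str], ...] = ()
    n_training_sessions: int = 22
    threshold: float = UNLOCK_THRESHOLD

    def best_for(self, session_index: int) -> float | None:
        return self.best_accuracy.get(str(session_index))


def initial_state(catalog: ProgramCatalog) -> ProgressionState:
    """Fresh state: introduction and sessions 1-3 unlocked, empty history."""
    return ProgressionState(
        unlocked=frozenset(ALWAYS_UNLOCKED),
        n_training_sessions=catalog.n_training_sessions,
        threshold=catalog.unlock_threshold,
    )


def apply_result(
    state: ProgressionState,
    session_index: int,
    accuracy: float,
    timestamp: str = "",
) -> tuple[ProgressionState, FeedbackKind]:
    """Record a session result; maybe unlock the immediate successor.

    Sessions below the gate (1 and 2) always yield ``completed`` because
    their successors are pre-unlocked; so does the final session, which has
    no successor. The unlocked set never shrinks, and replaying a session
    below threshold never re-locks anything.
    """
    if session_index not in state.unlocked:
        raise LockedSessionError(f"session {session_index} is locked")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")

    key = str(session_index)
    best = dict(state.best_accuracy)
    best[key] = max(best.get(key, 0.0), accuracy)
    history = state.history + ((session_index, accuracy, timestamp),)

    unlocked = state.unlocked
    feedback = FeedbackKind.COMPLETED
    successor = session_index + 1
    if (
        session_index >= FIRST_GATED_SESSION
        and accuracy >= state.threshold
        and successor <= state.n_training_sessions
    ):
        unlocked = unlocked | {successor}
        feedback = FeedbackKind.UNLOCKED_NEXT

    new_state = ProgressionState(
        unlocked=unlocked,
        best_accuracy=best,
        history=history,
        n_training_sessions=state.n_training_sessions,
        threshold=state.threshold,
    )
    return new_state, feedback


def state_to_json(state: ProgressionState) -> str:
    return json.dumps(
        {
            "unlocked": sorted(state.unlocked),
            "best_accuracy": state.best_accuracy,
            "history": [list(h) for h in state.history],
            "n_training_sessions": state.n_training_sessions,
            "threshold": state.threshold,
        },
        indent=2,
    )


def state_from_json(text: str) -> ProgressionState:
    raw = json.loads(text)
    return ProgressionState(
        unlocked=frozenset(int(i) for i in raw["unlocked"]),
        best_accuracy={str(k): float(v) for k, v in raw["best_accuracy"].items()},
        history=tuple(
            (int(i), float(a), str(t)) for i, a, t in raw["history"]
        ),
        n_training_sessions=int(raw["n_training_sessions"]),
        threshold=float(raw["threshold"]),
    )
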