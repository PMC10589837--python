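"""Training-program catalog: rhythm patterns, tempo ramp, target timelines.

The program comprises one introduction plus 22 training sessions built on
drum rudiments (paradiddles) and regular pulses. Each session carries a
target-beat timeline — the scoring reference historically shipped as a MIDI
file next to the session audio — and a tempo-dependent hit-window schedule:
the full window is 1000 ms for tempos below 60 beats/min, shrinking to
100 ms above 100 beats/min (program maximum 117 beats/min).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import BinaryIO, Sequence, Union

from hddrum import smf

#: MIDI note numbers for the two on-screen drums. The left (triangle) drum
#: plays the high-pitch bongo, the right (circle) drum the low-pitch one;
#: general-MIDI percussion keys 60/61 are high/low bongo.
NOTE_LEFT = 60
NOTE_RIGHT = 61

#: Default fraction of an accuracy score required to unlock the next session.
UNLOCK_THRESHOLD = 0.70

#: Hit-window schedule anchors: (tempo beats/min, total window width ms).
WINDOW_SLOW_ANCHOR = (60.0, 1000.0)
WINDOW_FAST_ANCHOR = (100.0, 100.0)

#: Half-window cap as a fraction of the smaller adjacent inter-onset
#: interval; keeps neighbouring windows disjoint so every tap has at most
#: one owning target.
WINDOW_CLAMP_FRACTION = 0.45

MAX_TEMPO_BPM = 117.0
N_TRAINING_SESSIONS = 22

STYLES = ("Hip-Hop", "Funk", "Samba", "Reggaeton")


class HandSide(str, enum.Enum):
    """Which drum a stroke belongs to: left triangle or right circle."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "HandSide":
        return HandSide.RIGHT if self is HandSide.LEFT else HandSide.LEFT


@dataclass(frozen=True)
class RhythmPattern:
    """One cycle of a rhythm: strokes at beat offsets, each on one hand."""

    name: str
    events: tuple[tuple[float, HandSide], ...]
    cycle_length: float

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        offsets = [off for off, _ in self.events]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("beat offsets must be strictly increasing")
        if offsets and (offsets[0] < 0 or offsets[-1] >= self.cycle_length):
            raise ValueError("beat offsets must lie in [0, cycle_length)")


class HandsMode(str, enum.Enum):
    """How a session drills the pattern before the scored run."""

    SEPARATE_THEN_TOGETHER = "separate_then_together"
    BOTH_REVERSED = "both_reversed"


@dataclass(frozen=True)
class SessionSpec:
    """One session of the program (index 0 is the introduction)."""

    index: int
    label: str
    tempo_bpm: float
    pattern: RhythmPattern
    n_cycles: int
    hands_mode: HandsMode
    has_metronome: bool
    background_track_id: int
    phase_layout: tuple[tuple[str, int], ...]
    nominal_duration_min: float

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        if self.tempo_bpm > MAX_TEMPO_BPM:
            raise ValueError(f"tempo_bpm exceeds program maximum {MAX_TEMPO_BPM}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 10 <= self.nominal_duration_min <= 15:
            raise ValueError("nominal_duration_min must be within 10-15 minutes")
        for kind, span in self.phase_layout:
            if kind not in ("training", "performance"):
                raise ValueError(f"unknown phase kind {kind!r}")
            if span < 1:
                raise ValueError("phase span must be >= 1 cycle")


@dataclass(frozen=True)
class TargetBeat:
    """One expected hit: onset (ms), hand, and half hit-window (ms)."""

    onset_ms: int
    hand: HandSide
    half_window_ms: float

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be >= 0")
        if not 50.0 <= self.half_window_ms <= 500.0:
            raise ValueError("half_window_ms must lie in [50, 500]")


@dataclass(frozen=True)
class TargetTimeline:
    """The scoring reference for one session's performance phase.

    Onsets are milliseconds from the start of the scored phase. Windows are
    guaranteed pairwise disjoint.
    """

    session_index: int
    beats: tuple[TargetBeat, ...]
    tempo_bpm: float

    def __post_init__(self) -> None:
        onsets = [b.onset_ms for b in self.beats]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        for a, b in zip(self.beats, self.beats[1:]):
            if a.onset_ms + a.half_window_ms >= b.onset_ms - b.half_window_ms:
                raise ValueError(
                    f"hit windows overlap between onsets {a.onset_ms} and {b.onset_ms}"
                )

    @property
    def total_targets(self) -> int:
        return len(self.beats)


@dataclass(frozen=True)
class ProgramCatalog:
    """The full 1+22-session program and its unlock threshold."""

    sessions: tuple[SessionSpec, ...]
    unlock_threshold: float = UNLOCK_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.unlock_threshold <= 1:
            raise ValueError("unlock_threshold must be in (0, 1]")
        indices = [s.index for s in self.sessions]
        if indices != list(range(len(self.sessions))):
            raise ValueError("session indices must be consecutive from 0")
        training = [s for s in self.sessions if s.index >= 1]
        if self.sessions and self.sessions[0].index != 0:
            raise ValueError("session 0 (introduction) missing")
        tempos = [s.tempo_bpm for s in training]
        if any(b < a for a, b in zip(tempos, tempos[1:])):
            raise ValueError("training tempos must be non-decreasing")
        targets = [len(s.pattern.events) * s.n_cycles for s in training]
        if any(b < a for a, b in zip(targets, targets[1:])):
            raise ValueError("target counts must be non-decreasing")
        for s in training:
            want = (
                HandsMode.SEPARATE_THEN_TOGETHER
                if s.index <= 7
                else HandsMode.BOTH_REVERSED
            )
            if s.hands_mode is not want:
                raise ValueError(f"session {s.index} has wrong hands_mode")
        for s in training:
            if s.background_track_id != (s.index - 1) // 3:
                raise ValueError("background tracks must be constant per group of 3")

    @property
    def n_training_sessions(self) -> int:
        return sum(1 for s in self.sessions if s.index >= 1)

    def session(self, index: int) -> SessionSpec:
        return self.sessions[index]


# ---------------------------------------------------------------------------
# pattern and window construction


def make_paradiddle(n_cycles: int, lead: HandSide) -> RhythmPattern:
    """Build the 8-stroke paradiddle rudiment repeated ``n_cycles`` times.

    A single stroke is followed by a double: leading right, the hand order
    is R L R R L R L L, with the leading hand alternating every 4-stroke
    half-cycle. Strokes fall at half-beat (eighth-note) spacing, so one
    rudiment cycle spans 4 beats.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    a, b = lead, lead.opposite
    hands = (a, b, a, a, b, a, b, b)
    events = tuple(
        (cycle * 4.0 + i * 0.5, hand)
        for cycle in range(n_cycles)
        for i, hand in enumerate(hands)
    )
    return RhythmPattern(
        name=f"paradiddle-{lead.value}-x{n_cycles}",
        events=events,
        cycle_length=4.0 * n_cycles,
    )


def make_pulse(hands: Sequence[HandSide], name: str = "pulse") -> RhythmPattern:
    """Regular quarter-note pulse, one stroke per beat."""
    events = tuple((float(i), hand) for i, hand in enumerate(hands))
    return RhythmPattern(name=name, events=events, cycle_length=float(len(hands)))


def window_width_for_tempo(tempo_bpm: float) -> float:
    """Total hit-window width (ms) as a function of session tempo.

    1000 ms below 60 beats/min, 100 ms above 100 beats/min, and linearly
    interpolated between those anchors, so the window tightens gradually as
    the program speeds up.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    t0, w0 = WINDOW_SLOW_ANCHOR
    t1, w1 = WINDOW_FAST_ANCHOR
    if tempo_bpm < t0:
        return w0
    if tempo_bpm > t1:
        return w1
    return w0 + (tempo_bpm - t0) * (w1 - w0) / (t1 - t0)


def _clamped_half_windows(onsets: Sequence[int], half: float) -> list[float]:
    """Clamp each half-window to 45% of the smaller adjacent gap."""
    out = []
    for i, onset in enumerate(onsets):
        limit = half
        if i > 0:
            limit = min(limit, WINDOW_CLAMP_FRACTION * (onset - onsets[i - 1]))
        if i < len(onsets) - 1:
            limit = min(limit, WINDOW_CLAMP_FRACTION * (onsets[i + 1] - onset))
        out.append(limit)
    return out


def build_timeline(spec: SessionSpec) -> TargetTimeline:
    """Expand a session's pattern into absolute target onsets with windows.

    Onsets are integer milliseconds from the start of the scored
    performance phase. Each target's half-window starts from the tempo
    schedule and is clamped so neighbouring windows never overlap.
    """
    beat_ms = 60_000.0 / spec.tempo_bpm
    onsets = [
        round((cycle * spec.pattern.cycle_length + offset) * beat_ms)
        for cycle in range(spec.n_cycles)
        for offset, _ in spec.pattern.events
    ]
    hands = [hand for _ in range(spec.n_cycles) for _, hand in spec.pattern.events]
    half = window_width_for_tempo(spec.tempo_bpm) / 2.0
    halves = _clamped_half_windows(onsets, half)
    beats = tuple(
        TargetBeat(onset_ms=o, hand=h, half_window_ms=w)
        for o, h, w in zip(onsets, hands, halves)
    )
    return TargetTimeline(
        session_index=spec.index, beats=beats, tempo_bpm=spec.tempo_bpm
    )


# ---------------------------------------------------------------------------
# default catalog

_TEMPO_RAMP = (
    55, 58, 60, 63, 66, 69, 72, 75, 78, 80, 82,
    85, 88, 90, 93, 96, 100, 104, 108, 112, 115, 117,
)


def _training_session(index: int) -> SessionSpec:
    tempo = float(_TEMPO_RAMP[index - 1])
    style = STYLES[((index - 1) // 3) % len(STYLES)]
    if index <= 3:
        # Slow regular rhythms: alternating quarter-note pulse on all beats.
        pattern = make_pulse(
            (HandSide.LEFT, HandSide.RIGHT, HandSide.LEFT, HandSide.RIGHT),
            name="pulse-alternating",
        )
        n_cycles = 9 + index  # 40, 44, 48 targets
    else:
        lead = HandSide.RIGHT if index % 2 == 0 else HandSide.LEFT
        pattern = make_paradiddle(1, lead)
        n_cycles = index + 2  # 48 .. 192 targets
    return SessionSpec(
        index=index,
        label=f"Session {index}: {style}",
        tempo_bpm=tempo,
        pattern=pattern,
        n_cycles=n_cycles,
        hands_mode=(
            HandsMode.SEPARATE_THEN_TOGETHER if index <= 7 else HandsMode.BOTH_REVERSED
        ),
        has_metronome=index != 1,
        background_track_id=(index - 1) // 3,
        phase_layout=(("training", n_cycles), ("performance", n_cycles)),
        nominal_duration_min=float(10 + round(5 * (index - 1) / 21)),
    )


def default_catalog() -> ProgramCatalog:
    """The default 1-introduction + 22-training-session program.

    Session 1 is a slow (<60 beats/min) regular pulse on all four beats
    without a metronome; tempo then ramps monotonically to 117 beats/min
    while target counts grow, with styles and background tracks rotating in
    groups of three sessions.
    """
    intro = SessionSpec(
        index=0,
        label="Introduction",
        tempo_bpm=55.0,
        pattern=make_pulse(
            (HandSide.LEFT, HandSide.RIGHT, HandSide.LEFT, HandSide.RIGHT),
            name="pulse-alternating",
        ),
        n_cycles=8,
        hands_mode=HandsMode.SEPARATE_THEN_TOGETHER,
        has_metronome=False,
        background_track_id=0,
        phase_layout=(("training", 8),),
        nominal_duration_min=10.0,
    )
    sessions = (intro,) + tuple(
        _training_session(i) for i in range(1, N_TRAINING_SESSIONS + 1)
    )
    return ProgramCatalog(sessions=sessions, unlock_threshold=UNLOCK_THRESHOLD)


# ---------------------------------------------------------------------------
# MIDI round trip

_NOTE_FOR_HAND = {HandSide.LEFT: NOTE_LEFT, HandSide.RIGHT: NOTE_RIGHT}
_HAND_FOR_NOTE = {NOTE_LEFT: HandSide.LEFT, NOTE_RIGHT: HandSide.RIGHT}


def write_target_midi(
    timeline: TargetTimeline, destination: Union[str, BinaryIO]
) -> None:
    """Write a timeline as a format-0 MIDI file (PPQ 480, tempo meta-event).

    Hit windows are not stored in MIDI; they are reconstructed from the
    tempo on read.
    """
    us_per_quarter = round(60_000_000 / timeline.tempo_bpm)
    us_per_tick = us_per_quarter / smf.PPQ
    notes = [
        smf.NoteEvent(
            tick=round(b.onset_ms * 1000 / us_per_tick),
            note=_NOTE_FOR_HAND[b.hand],
        )
        for b in timeline.beats
    ]
    smf.write_smf0(destination, notes, us_per_quarter)


def read_target_midi(
    source: Union[str, BinaryIO], session_index: int = 0
) -> TargetTimeline:
    """Read a target timeline back from a format-0 MIDI file.

    The two known note numbers map to left/right; any other note is a
    format error. Half-windows are recomputed from the file's tempo via the
    window schedule and the overlap clamp.
    """
    ppq, us_per_quarter, notes = smf.read_smf0(source)
    us_per_tick = us_per_quarter / ppq
    tempo_bpm = 60_000_000 / us_per_quarter
    onsets: list[int] = []
    hands: list[HandSide] = []
    for ev in notes:
        if ev.note not in _HAND_FOR_NOTE:
            raise smf.MidiFormatError(
                f"unknown note number {ev.note} at tick {ev.tick}; "
                f"expected {NOTE_LEFT} (left) or {NOTE_RIGHT} (right)"
            )
        onsets.append(round(ev.tick * us_per_tick / 1000))
        hands.append(_HAND_FOR_NOTE[ev.note])
    half = window_width_for_tempo(tempo_bpm) / 2.0
    halves = _clamped_half_windows(onsets, half)
    beats = tuple(
        TargetBeat(onset_ms=o, hand=h, half_window_ms=w)
        for o, h, w in zip(onsets, hands, halves)
    )
    return TargetTimeline(session_index=session_index, beats=beats, tempo_bpm=tempo_bpm)


# ---------------------------------------------------------------------------
# JSON config I/O


def catalog_to_json(catalog: ProgramCatalog) -> str:
    def spec_dict(s: SessionSpec) -> dict:
        return {
            "index": s.index,
            "label": s.label,
            "tempo_bpm": s.tempo_bpm,
            "pattern": {
                "name": s.pattern.name,
                "events": [[off, h.value] for off, h in s.pattern.events],
                "cycle_length": s.pattern.cycle_length,
            },
            "n_cycles": s.n_cycles,
            "hands_mode": s.hands_mode.value,
            "has_metronome": s.has_metronome,
            "background_track_id": s.background_track_id,
            "phase_layout": [list(p) for p in s.phase_layout],
            "nominal_duration_min": s.nominal_duration_min,
        }

    return json.dumps(
        {
            "unlock_threshold": catalog.unlock_threshold,
            "sessions": [spec_dict(s) for s in catalog.sessions],
        },
        indent=2,
    )


def catalog_from_json(text: str) -> ProgramCatalog:
    raw = json.loads(text)
    sessions = []
    for s in raw["sessions"]:
        pattern = RhythmPattern(
            name=s["pattern"]["name"],
            events=tuple(
                (float(off), HandSide(h)) for off, h in s["pattern"]["events"]
            ),
            cycle_length=float(s["pattern"]["cycle_length"]),
        )
        sessions.append(
            SessionSpec(
                index=int(s["index"]),
                label=s["label"],
                tempo_bpm=float(s["tempo_bpm"]),
                pattern=pattern,
                n_cycles=int(s["n_cycles"]),
                hands_mode=HandsMode(s["hands_mode"]),
                has_metronome=bool(s["has_metronome"]),
                background_track_id=int(s["background_track_id"]),
                phase_layout=tuple(
                    (str(kind), int(span)) for kind, span in s["phase_layout"]
                ),
                nominal_duration_min=float(s["nominal_duration_min"]),
            )
        )
    return ProgramCatalog(
        sessions=tuple(sessions),
        unlock_threshold=float(raw["unlock_threshold"]),
    )
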