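# Methods

## Scope and model

`hddrum` implements the computational core of a gamified drumming-training
intervention: reference timelines, tap scoring, session progression,
adherence quantification, and a behavioral simulator. It deliberately
excludes everything device- and presentation-facing — audio rendering,
visual cues, the tablet GUI, and cloud upload.

A session's scoring reference is a `TargetTimeline`: target beats at
integer-millisecond onsets (time origin 0 at the start of the scored
performance phase), each with a hand and a symmetric half-window. A tap
scores 1 for a target iff it is on the target's drum and within the
window; its signed latency is tap time minus onset, positive when late,
following sensorimotor-synchronization convention. Accuracy is the count
of targets scored 1 divided by the total number of target beats; surplus,
wrong-drum, and out-of-window taps are logged with accuracy 0 but never
enter the denominator, keeping accuracy in [0, 1] and tied to the
session-difficulty metadata (total target beats, window duration,
success threshold).

## Hit-window schedule

The program's printed anchors are a 1000 ms total window for tempos below
60 beats/min and 100 ms above 100 beats/min. The schedule between those
anchors is not printed; we use the simplest monotone choice, linear
interpolation in tempo between (60 bpm, 1000 ms) and (100 bpm, 100 ms),
constant outside. At sub-beat stroke spacing a schedule window could
overlap its neighbours, which would make tap ownership ambiguous; each
half-window is therefore clamped to 45% of the smaller adjacent
inter-onset interval. 45% (rather than 50%) leaves a guaranteed gap
between consecutive windows, so every tap has at most one owning target
and per-beat 0/1 scoring is well defined.

## Matching

Each target takes at most one tap: among correct-drum taps inside its
window, the one with minimum absolute latency, ties broken toward the
earlier tap (determinism). Because windows are pairwise disjoint, the
tap–target eligibility graph is a union of stars, and this greedy rule
attains the global optimum of (number accurate, then minus the summed
absolute latency); the test suite and acceptance script verify this
against an exhaustive assignment search on random instances of up to 6
targets and 6 taps. Every input tap is classified exactly once — matched,
surplus-in-window, wrong-drum-in-window, or outside-all-windows — so taps
are conserved. A wrong-drum tap inside a window never rescues its
target's score. When both drums carry near-simultaneous targets the
engine still decides per target independently; coupled two-hand judging
is not modeled.

## Default catalog

The program fixes endpoints and ordering only: 1 introduction + 22
training sessions, session 1 a regular four-beat pulse below 60 beats/min
without a metronome, tempo non-decreasing to a maximum of exactly
117 beats/min, complexity non-decreasing, hands practiced separately then
together through session 7 and both-reversed from session 8, styles and
background tracks rotating in groups of three. Within those constraints
the default catalog fixes one documented ramp: tempos 55 → 117 over the
22 sessions, sessions 1–3 alternating-hand quarter-note pulses (40–48
targets), sessions 4–22 eighth-note paradiddles with the lead hand
alternating by session and cycle counts growing from 6 to 24 (48–192
targets), nominal durations ramping 10 → 15 minutes. The exact
per-session values carry no empirical authority; any alternative catalog
can be supplied as JSON, and all invariants are enforced on load.
Paradiddle strokes are placed at half-beat (eighth-note) spacing, the
standard rudiment timing. The likely-typo tension in the source material
about whether the introduced slow rhythm is above or below 1 beat/s is
resolved toward *below* (55 bpm), consistent with the stated 1000 ms
window for the slowest pattern.

## MIDI dialect

Timelines round-trip through single-track format-0 Standard MIDI Files:
PPQ 480, one tempo meta-event, note 60 for the left (high-pitch triangle)
drum and note 61 for the right (low-pitch circle) drum — the
general-MIDI high/low bongo keys. At PPQ 480 a tick is at most ~1.1 ms
across the catalog's tempo range, so onsets survive the round trip to
±1 ms and hands exactly. Hit windows are not representable in MIDI; they
are reconstructed on read from the file's tempo via the schedule and the
overlap clamp. Any other note number is a format error naming the
offending event. The reader/writer is implemented in-package
(`hddrum.smf`) and covers exactly this dialect, not general MIDI.

## Progression

State is (unlocked set, per-session best accuracy, history). The
introduction and sessions 1–3 are always unlocked; from session 3 onward
an accuracy ≥ the threshold (default 0.70, compared exactly, no rounding)
unlocks the immediate successor only — no skipping. Sessions 1 and 2
always yield `completed` feedback since their successors are
pre-unlocked; the final session also yields `completed` because it has no
successor. The unlocked set never shrinks, and the engine imposes no
forced repetition below threshold — that advice is presentation-layer
text. State serializes losslessly to JSON.

## Adherence

Engagement records carry only an anonymous 16-character [A-Z0-9] tablet
code (drawn from a seeded generator; the 36^16 space makes collisions
negligible), the session index, an ISO 8601 start, and a duration.
Weekly rollups use rolling 7-day windows anchored at the first engagement
rather than calendar weeks, because an 8-week home program starts on an
arbitrary day. "5 sessions/week" is counted as sessions, not distinct
days. The adherence fraction is attended/planned sessions, reported
as-is (values above 1 indicate over-practice, which is information, not
an error). Partial engagements count toward duration and are flagged, not
dropped.

## Simulator

The virtual tapper uses the standard sensorimotor-synchronization noise
model: per target, a tap is produced with probability 1 − miss_prob at
onset + N(mean asynchrony, jitter²), landing on the wrong drum with
probability wrong_hand_prob; spurious taps arrive as a homogeneous
Poisson stream over the session span (plus a 1 s tail). All draws come
from a single seeded generator, so simulated sessions and whole program
walk-throughs are replayable bit for bit. Defaults are a noiseless
tapper; tests exercise asynchronies of tens of milliseconds and jitter
SDs of 20–200 ms, the range typical of paced-tapping studies. With no
extra taps, expected accuracy has the closed form
(1 − miss)(1 − wrong)·P(|N(μ, σ)| ≤ w), and accurate-tap latencies follow
a normal truncated at ±w; the suite checks both (Kolmogorov–Smirnov at
n = 10,000, α = 0.01). The simulator does not model learning curves,
perseverative tapping bursts, or hardware touch latency, so passing tests
demonstrate engine correctness, not clinical realism of the tap streams.
Program walk-throughs play the most advanced unlocked session each slot;
real participants may revisit earlier sessions.

## Numerical and format choices

Timestamps and latencies are integer milliseconds; summary statistics are
floats. Missing values (e.g. mean latency of an all-miss session) are
encoded as empty CSV fields / JSON nulls, never sentinel numbers, so they
cannot corrupt means. Output files are RFC 4180 CSV, UTF-8, with a
versioned four-block layout (header, per-event rows, eight summary
statistics, difficulty metadata) that round-trips losslessly; floats are
written with `repr` so parsing reproduces them exactly. CLI exit codes:
0 success, 2 validation error, 64 unknown subcommand.

## Problem sizes

Randomized verification uses 1,000 instances (≤ 6 targets/taps) for the
exhaustive-search comparison, 200-target sessions over 100 seeds for the
closed-form accuracy check, a 10,000-target session for the latency
distribution test, and 40-slot (5/week × 8-week) program walk-throughs —
sizes chosen to keep Monte-Carlo error well inside the asserted bounds.

## Known limitations

- The default catalog's per-session tempos and cycle counts are one
  reasonable instantiation of the stated constraints, not recovered app
  content.
- Metronome sounds are not represented in timelines and never scored.
- Scoring is batch, not streaming; there is no touch-latency
  compensation.
- Coupled judging of simultaneous two-hand targets is out of scope (each
  target is judged independently).
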