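# hddrum

A headless, testable engine for a tablet-based rhythmic drumming training
program used in Huntington disease (HD) neurorehabilitation research.
Drumming along to external rhythmic beats is a neurologic-music-therapy
approach intended to compensate for impaired basal-ganglia timing; running
such a program as an at-home app requires an objective scoring and
monitoring back end. This package implements that back end for
researchers and app developers who need to quantify performance and
adherence without any GUI, audio, or cloud components:

- **Session catalog** — one introduction plus 22 training sessions built
  on paradiddle rudiments (R L R R L R L L) and regular pulses, with a
  monotone tempo ramp from below 60 up to 117 beats/min, and per-session
  target-beat timelines that read/write standard MIDI (format 0).
- **Scoring engine** — matches screen taps to target beats inside a
  symmetric, tempo-dependent hit window and emits per-beat 0/1 accuracy,
  signed latency, and the eight per-session summary statistics.
- **Progression** — the gamification state machine: the first three
  sessions are open from the start; from session 3 onward an accuracy of
  at least 70% unlocks the next, more difficult session.
- **Adherence** — weekly engagement rollups against the prescribed dose
  (10–15 min/day, 5 sessions/week, 8 weeks), keyed by an anonymous
  16-character tablet code.
- **Simulator** — a virtual tapper (Gaussian asynchrony + jitter, miss
  and wrong-hand probabilities, Poisson extra taps) so the whole pipeline
  is testable end to end without participants.

## The scoring model

A session's scoring reference is a timeline of target beats
(onset *tᵢ* in ms, hand *hᵢ*, half-window *wᵢ*). A tap at time *s* on drum
*d* is **accurate** for target *i* iff *d = hᵢ* and |*s − tᵢ*| ≤ *wᵢ*;
its latency is *s − tᵢ* (positive = late). The total window width is
1000 ms for tempos below 60 beats/min, 100 ms above 100 beats/min, and
linear in tempo between; each half-window is then clamped to 45% of the
smaller adjacent inter-onset interval so windows never overlap. With
disjoint windows, giving each target its nearest correct-drum in-window
tap is provably the assignment that maximises the number of accurate
responses (ties broken toward the earlier tap); surplus, wrong-drum, and
out-of-window taps are logged with accuracy 0 but do not enter the
accuracy denominator, which is the total number of target beats.

## Worked example

```python
import hddrum as h

catalog = h.default_catalog()
spec = catalog.session(3)
timeline = h.build_timeline(spec)
profile = h.TapperProfile(mean_asynchrony_ms=-25, jitter_sd_ms=60,
                          miss_prob=0.1, extra_rate_hz=0.1,
                          wrong_hand_prob=0.05, seed=42)
taps = h.simulate_taps(timeline, profile)
result = h.score_session(spec, taps)
```

This scores one simulated session and prints:

```
session 3 (Session 3: Hip-Hop), 60 bpm
targets: 48, window: 1000 ms, threshold: 70%
taps: 48 (6 unmatched)
mean accuracy: 0.875
mean latency: -28.2 ms
left/right accuracy: 0.917 / 0.833
feedback: unlocked_next; unlocked: [0, 1, 2, 3, 4]
```

The virtual tapper anticipates the beat by 25 ms on average (the classic
negative mean asynchrony), misses 10% of targets, and occasionally taps
the wrong drum, so 42 of 48 targets score 1 (accuracy 0.875) and the mean
latency of accurate taps is about −28 ms. Because 87.5% ≥ 70%, applying
the result to a fresh progression state unlocks session 4.

The same pipeline is available from the shell:

```
hddrum catalog --summary --midi-dir midi/
hddrum simulate --session 3 --seed 42 --out taps.csv
hddrum score --session 3 --taps taps.csv --out session3.csv
hddrum progress --state state.json --session 3 --accuracy 0.875
hddrum report --engagements engagements.csv
```

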