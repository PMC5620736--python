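# Methods

## Scope and assumptions

The system targets a single resident living alone, monitored by one PIR
motion sensor per room with room-level localisation. The person is assumed to
be wherever the last sensor fired until a different sensor fires (PIR units
trigger on motion and then sleep to save battery, so absence of events does
not mean absence of the person). Visitors, pets and sensor faults are out of
scope: any secondary source of motion is attributed to the resident and will
distort the model.

## The behaviour model

Time is a weekly grid: 7 weekdays × (1440/Δt) intervals, Δt = 60 min by
default (any divisor of 1440 works). Intervals are half-open on the left,
(t, t+Δt]; an instant exactly on a boundary belongs to the earlier cell, and
midnight sharp to the previous day's last cell. Stays are split at every
boundary, including midnight, so each calendar day's minutes land in that
day's cells; piece minutes sum to the stay duration exactly at timestamp
resolution (seconds are stored; durations are fractional minutes).

Each cell accumulates, over the learning window, per-room stay minutes
`TS^i`, per-room observation counts, and the transition-count matrix
`M^{i,j}` (a consecutive observation pair contributes to the cell containing
the second timestamp; same-room pairs count as self-transitions). Raw sums
are stored; per-day rates divide by the number of window days mapping to the
cell (4 for the default 4-week window).

**Stay probability.** `P^{i,i} = TS^i / Σ_j TS^j`. The denominator equals
Δt × (contributing days) whenever the stays tile the cell, in which case
this is exactly the per-day average stay time over Δt; we use the sum form
because stream edges leave cells partially covered, and the sum form keeps
`Σ_i P^{i,i} = 1` an exact identity rather than an approximation.

**Transition probability.** The off-diagonal row mass `1 − P^{i,i}` is
allocated proportionally to observed exits. Degenerate cases: a room with
stay time but no observed exits keeps the whole row mass on the diagonal
(`P^{i,i} = 1`), so observed rows always sum to 1; a room never observed in
the cell has an all-zero row, and likelihood lookups there return 0. Room
adjacency is enforced by the data alone — transitions that never happen get
probability 0 — because real sensors can misfire; the layout's adjacency
graph is used by the simulator and for validation, not as a hard mask.

**Continuous stays.** Per weekday, maximal runs of consecutive same-room
stays are merged; any interleaved stay in a different room — even of zero
duration — breaks a run. A run crossing midnight is credited to the day it
started. The per-room maximum over the window is the "expected longest
stay". Zero-duration runs are not recorded.

**Window update.** The window (default 4 weeks) shifts by 1 week: retained
observations outside the new span are dropped, new ones appended, and the
model is rebuilt from the buffer. At these data volumes (~10⁴ events per 12
weeks) a rebuild costs milliseconds, and it makes the incremental result
equal to a batch build by construction, which the tests assert exactly.
Full adaptation to a changed routine therefore takes 4 weekly steps of about
a quarter of the gap each.

## Detection

One sample per sampling period (1 min), clock-aligned, regardless of event
arrival times. The raw likelihood is the stay probability of the detected
room, normalised by the cell's most probable room so that diffuse cells do
not read as anomalies; an entirely unmodelled cell yields 0 with the sample
flagged. Smoothing is an unweighted moving average over the 10-min window —
the simplest low-pass filter consistent with the intent; the window grows
from one sample at stream start, and until one full window has elapsed the
abnormality output is suppressed (undefined filter state otherwise).
`h = 1` iff `g < θ` — strictly below, so `θ = 0` never flags.

The automaton keeps one timer (±1 sampling period per step). Normal: timer
resets on h = 0, increments on h = 1, and the state leaves for
PotentialAbnormal when timer > N1 (5 min), so abnormal runs of length ≤ N1
never raise anything. PotentialAbnormal: the timer is *decremented*, not
reset, on normal samples; Abnormal is confirmed at timer ≥ N2 (10 min),
Normal restored when the timer drains to 0. The exit from Abnormal is left
open in the original design; we return to Normal after a sustained normal
streak of N1 minutes, with a `latch_abnormal` option to hold the state until
acknowledged. A false-positive alert is counted as one entry into Abnormal
(estimator and classifier levels count maximal flagged runs instead).

The classifier's stay comparison needs the *current* continuous stay. The
strict merge rule is specified for the learned lists; for the live clock we
chose an N1-minute tolerance: absences from the run's room shorter than the
automaton's own glitch horizon do not reset it. Otherwise a 3-minute
night-time bathroom visit halves the detected sleep stay while the learned
longest stay (a max over window days) almost always reflects an unbroken
night, and prolonged-sleep episodes are recognised hours late. The tolerant
clock is the more sensitive side of the comparison by design.

## Classification

Five activity levels quantise a rate against the model's maximum global
activity in equal 0.2-wide bands of the ratio; the weighted/sampled match is
Normal iff the two levels differ by at most one band, which reproduces the
published 5×5 tridiagonal matching matrix exactly. The sampled global
activity is the observation rate over the trailing Δt minutes — directly
comparable to the model's AG; the weighted expectation blends the current
and previous cells' AG by minutes elapsed in the interval. The expected room
is the argmax of the cell's stay probabilities, ties broken by layout order.

Rule order (first match wins), gated on the automaton being at least
PotentialAbnormal — waiting for full confirmation would add N2 − N1 minutes
of delay for no information:

1. bedroom + over-long stay → OverSleeping;
2. expected room is the bedroom but the person is elsewhere → LessSleeping
   (this includes being out of the house during sleeping hours — the injected
   scenario for the morning profile — so the rule deliberately does not
   exclude Outside);
3. outside + over-long stay → NotBackHome;
4. any other room + over-long stay + activity mismatch + sampled activity at
   the floor + *confirmed* Abnormal → Dead (the severest call requires the
   strongest evidence);
5. otherwise Normal, with an "unclassified deviation" note when the
   automaton is flagging.

Because sleeping-time rules precede the outside rule, a nightly person's
daytime anomalies (sleeping hours 8–16) tend to be read as LessSleeping —
the same confusion pattern the original study reports for that profile.

## Synthetic data

The generator emulates a schedule-driven resident: Profile A (morning
person) sleeps 0–8, is out 8–16 and spends the evening in the living room;
Profile B (nightly person) is out 0–8 and 23–24, sleeps 8–16, evening in the
living room. Segment boundaries jitter uniformly by ±5 min per day. Dwell
events have exponential gaps (mean 5 min active, 30 min asleep); walks
between rooms follow the shortest adjacency path, one observation per room
at 30-s hops. Excursions: night bathroom visits at ~0.5/night (3 min),
kitchen trips from the living room at 0.7/h (mean 6 min), rare store errands
(0.025/h, 2 min). Outside periods emit one virtual exit observation, then
silence until return. Streams are byte-identical for identical (spec, seed).

Anomalies *replace* baseline events in their window (plus a 15-min margin
before it, so a jittered departure walk seconds before the window cannot
contradict the injected behaviour): OverSleeping keeps low-rate bedroom
events running through the extended window; LessSleeping puts active-rate
events in the override room (or a single exit event when the override is
Outside); NotBackHome is an exit event then silence; Dead is a couple of
triggers in the override room then total silence. Ground truth (kind,
window, room) is emitted alongside for scoring.

What the generator does **not** emulate: visitors and multi-occupancy,
sensor noise/misfires, seasonal drift within a profile, heterogeneous sensor
rates per room, and the long-tailed dwell patterns of real homes. Passing
tests therefore demonstrate the pipeline's internal correctness and its
behaviour under clean, schedule-driven data — not robustness to the
confounds of real deployments (the public CASAS-format reader exists for
that kind of validation).

## Problem sizes and defaults

Experiments use the study defaults: Δt = 60 min, 4-week window shifted
weekly, 1-min sampling, 10-min smoothing, θ = 0.25, N1 = 5, N2 = 10.
Injected-anomaly runs simulate 6 weeks (4 training + buffer + anomaly day),
detect over a 32-h span around the anomaly, and average 3 seeds.
False-positive runs simulate 8 weeks and score 4 anomaly-free weeks with
weekly-updated models. The adaptation experiment uses 6 + 6 weeks across the
profile switch. These sizes keep any single experiment under a few seconds
while matching the study's window structure; the 12-week profile length
remains the generator default.

## Known limitations

- Partial-coverage cells (stream edges) silently carry less weight; no
  explicit confidence is attached to cells.
- The false-positive level of the estimator depends strongly on the
  generator's boundary jitter; with ±5-min jitter the classifier level is
  near zero, so the reduction relative to the automaton is structural rather
  than finely measured.
- The Dead rule is blocked while the model expects no activity (e.g. hours
  the person is normally out), because the activity match then reads Normal;
  detection resumes when expected activity returns.
- Multi-sensor rooms are supported in the layout but the simulator emits one
  sensor per room; same-room consecutive observations count as
  self-transitions either way.
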