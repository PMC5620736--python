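# bms — behaviour monitoring from PIR motion-sensor streams

`bms` implements a behaviour monitoring system for ambient assisted living:
it learns the daily room-to-room mobility routine of a single older adult
living alone from the event stream of passive-infrared (PIR) motion sensors,
and raises classified alarms — OverSleeping, LessSleeping, NotBackHome,
Dead — when the routine deviates. It is aimed at researchers and engineers
working on sensor-based in-home monitoring who need a transparent,
annotation-free baseline: no activity labelling, no prior assumptions about
the resident's schedule, and online adaptation to gradual routine changes.

## The model

A PIR trigger is an observation *o = ⟨ts, sensor_id⟩*; each sensor maps to a
room (plus one virtual *Outside* room). Consecutive observations delimit a
**stay** in the room of the earlier one. Time is organised on a weekly grid
of 7 weekdays × (1440/Δt) intervals (default Δt = 60 min), and stays are
split across the intervals they overlap.

Per grid cell, the learner accumulates over a sliding window (default 4
weeks, shifted weekly):

- total stay time per room `TS^i`, giving the stay probability
  `P^{i,i} = TS^i / Σ_j TS^j` — the chance of finding the person in room *i*
  in that weekday/hour;
- transition counts `M^{i,j}`, allocating the residual row mass
  `P^{i,j} = (1 − P^{i,i}) · M^{i,j} / Σ_{k≠i} M^{i,k}`;
- activity rates: global `AG`, inter-room `AE`, per-room `AA^i`
  (observations or transitions per minute);
- per weekday, the list of **continuous stays** per room (maximal runs of
  consecutive same-room stays); their maximum is the expected longest stay.

Detection runs once per minute: the location likelihood *l_n* is the stay
probability of the last-seen room, normalised by the cell's most probable
room; a 10-min moving average yields *g_n*; *h_n = 1* iff *g_n* drops below
the threshold (default 0.25). A three-state automaton (Normal →
PotentialAbnormal → Abnormal) with timeouts N1 = 5 min and N2 = 10 min
filters glitches and confirms alarms. A rule-based classifier then combines
the automaton state with the longest-stay comparison, the expected room and
a weighted-vs-sampled activity match to name the deviation.

The package also ships the synthetic-data generator used in the experiments
(two 12-week single-resident profiles — a "morning person" A and a "nightly
person" B — over a six-room home) with injection of the four anomalies, plus
evaluation metrics: anomaly detection delay (ADD), anomaly confirmation time
(ACT), weekly false-positive alerts (FP) and per-class accuracy.

## Worked example

```python
from datetime import datetime
from bms import (DetectionConfig, build_model, classify_chain, default_anomaly,
                 default_layout, generate, inject, profile_a, run_detection)

layout = default_layout()
stream = generate(profile_a(), layout, start=datetime(2024, 1, 1), weeks=5, seed=7)
model = build_model(stream, layout, window_start=datetime(2024, 1, 1), window_weeks=4)

cell = model.cell(datetime(2024, 1, 29, 4, 25))   # Monday, interval (4-5]
print(f"P(bedroom | Monday (4-5]) = {cell.self_transition_prob('Bedroom'):.3f}")
print(f"longest Monday bedroom stay = {model.longest_cs('Bedroom', 0)/60:.1f} h")

anomaly = default_anomaly("LessSleeping", "A", datetime(2024, 1, 31).date())
stream, truth = inject(stream, anomaly, layout, seed=7)

samples = run_detection(stream, model, layout, DetectionConfig(threshold=0.25),
                        start=datetime(2024, 1, 30, 18), end=datetime(2024, 1, 31, 9))
reports = classify_chain(samples, model, layout)
first = next(r for r in reports if r.label.value == "LessSleeping")
print(f"first alarm: {first.ts}, label {first.label.value}")
```

prints

```
P(bedroom | Monday (4-5]) = 1.000
longest Monday bedroom stay = 8.1 h
first alarm: 2024-01-31 00:12:00, label LessSleeping
```

The model learned that at 4 a.m. on Mondays the resident is asleep in the
bedroom with probability 1.0 and that a night's sleep lasts about 8 h. The
injected LessSleeping episode (out of the house during sleeping hours,
starting at midnight) is detected and correctly named 12 minutes after
onset: the smoothed likelihood needs ~7 min to fall below the threshold and
the automaton a further N1 = 5 min to leave the Normal state.

The same pipeline is available from the shell:

```sh
bms simulate --profile A --weeks 6 --seed 3 \
    --inject-kind LessSleeping --inject-day 2024-02-07 --out data/
bms learn  --events data/events.csv --window-weeks 4 \
    --window-start 2024-01-01 --model model.json
bms detect --events data/events.csv --model model.json \
    --threshold 0.25 --out chain.csv
bms evaluate --chain chain.csv --truth data/truth.json --report report.json
bms casas-import --in annotated.txt --sensor-map map.yaml --out events.csv
```

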