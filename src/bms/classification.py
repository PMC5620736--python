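"""Rule-based classification of confirmed deviations into behaviour classes.

The automaton says *that* the routine deviated; this module says *what* the
deviation looks like, by combining the automaton state with further model
dimensions at the sample instant:

* ``S`` — is the current continuous stay in the detected room longer than the
  longest such stay the model has seen for this weekday? (``High``/``Normal``)
* ``W_AG`` — the *weighted* global activity expected right now: a convex
  blend of the model's AG for the current and previous intervals, weighted by
  the minutes elapsed in the current interval;
* ``S_AG`` — the *sampled* global activity: the observation rate actually
  measured over the trailing interval;
* both activity rates are quantised into five levels relative to the model's
  maximum AG, and ``W`` is ``Normal`` when the two levels differ by at most
  one band (the tridiagonal matching matrix), ``Abnormal`` otherwise;
* the *expected room* is the most probable room of the current cell.

The four behaviour classes:

``OverSleeping``
    in the bedroom far longer than usual (mobility problems, strokes);
``LessSleeping``
    detected away from the bedroom during habitual sleeping time — including
    out of the house (sleeplessness: anxiety, depression, dementia onset);
``NotBackHome``
    outside longer than usual (lost, wandering, unable to return);
``Dead``
    an over-long motionless stay in a room that is neither the bedroom nor
    outside, with measured activity at the floor while the model expects
    activity.

Rules fire in the order Normal-gate, OverSleeping, LessSleeping, NotBackHome,
Dead; sleeping-time deviations take precedence, so an over-long outside stay
during sleeping hours reads as LessSleeping, not NotBackHome.  All anomaly
rules require the automaton to be at least PotentialAbnormal; Dead — the most
severe call — additionally requires a fully confirmed Abnormal state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np

from .detection import DetectionSample, ModelProvider, State, _as_provider
from .events import OUTSIDE, HomeLayout
from .learning import BehaviourModel

#: Sentinel returned for cells with no recorded behaviour at all.
UNMODELLED = "unmodelled"


class ActivityLevel(enum.IntEnum):
    VERY_LOW = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4


def activity_level(x: float, max_ag: float) -> ActivityLevel:
    """Quantise an activity rate into five equal bands of ``x / max_ag``.

    Bands are 0.2 wide; ratios of 0.8 and above are VERY_HIGH.  A
    non-positive ``max_ag`` (no activity anywhere in the model) maps
    everything to VERY_LOW.
    """
    if max_ag <= 0:
        return ActivityLevel.VERY_LOW
    ratio = x / max_ag
    return ActivityLevel(min(4, max(0, int(ratio / 0.2))))


def activity_match(level_w: ActivityLevel, level_s: ActivityLevel) -> str:
    """Match weighted vs sampled activity levels: Normal iff within one band."""
    return "Normal" if abs(int(level_w) - int(level_s)) <= 1 else "Abnormal"


def weighted_global_activity(model: BehaviourModel, now: datetime) -> float:
    """Blend of model AG for the current and previous intervals.

    ``W_AG = minutes/dt * AG(current) + (dt - minutes)/dt * AG(previous)``
    where ``minutes`` is the elapsed time within the current interval.  The
    previous interval wraps across midnight and weekday boundaries.
    """
    grid = model.grid
    cell = grid.cell_of(now)
    minutes = (now - grid.cell_start(now)).total_seconds() / 60.0
    ag_cur = model.cells[cell].global_activity()
    ag_prev = model.cells[grid.prev_cell(cell)].global_activity()
    dt = grid.delta_t
    return minutes / dt * ag_cur + (dt - minutes) / dt * ag_prev


def sampled_global_activity(recent_ts: Sequence[datetime], now: datetime, delta_t: int) -> float:
    """Observation rate over the trailing ``delta_t`` minutes ending at now."""
    count = sum(1 for ts in recent_ts if 0 <= (now - ts).total_seconds() <= delta_t * 60)
    return count / delta_t


def stay_state(current_cs: float, model: BehaviourModel, room: str, weekday: int) -> str:
    """High iff the running continuous stay reaches the learned longest stay."""
    return "High" if current_cs >= model.longest_cs(room, weekday) else "Normal"


def expected_room(model: BehaviourModel, now: datetime) -> str:
    """Most probable room of the current cell; ties break by room order."""
    cell = model.cell(now)
    if cell.unmodelled:
        return UNMODELLED
    return cell.rooms[int(np.argmax(cell.stay_probs()))]


class Label(enum.Enum):
    NORMAL = "Normal"
    OVER_SLEEPING = "OverSleeping"
    LESS_SLEEPING = "LessSleeping"
    NOT_BACK_HOME = "NotBackHome"
    DEAD = "Dead"


@dataclass(frozen=True)
class ClassifierState:
    """Everything the rule set inspects for one sample."""

    z: State
    s: str  # longest-stay state: "Normal" | "High"
    w: str  # activity-match state: "Normal" | "Abnormal"
    sag_level: ActivityLevel
    detected_room: str
    expected: str
    w_ag: float
    s_ag: float


@dataclass(frozen=True)
class AnomalyReport:
    ts: datetime
    label: Label
    evidence: ClassifierState
    note: str = ""


def classify(
    cs: ClassifierState,
    bedroom: str = "Bedroom",
    outside: str = OUTSIDE,
) -> tuple[Label, str]:
    """Apply the behaviour rules; first match wins.

    Returns the label plus a note ("unclassified deviation" when the
    automaton flags a deviation no rule explains).
    """
    if cs.z is State.NORMAL:
        return Label.NORMAL, ""
    if cs.detected_room == bedroom and cs.s == "High":
        return Label.OVER_SLEEPING, ""
    if cs.expected == bedroom and cs.detected_room != bedroom:
        return Label.LESS_SLEEPING, ""
    if cs.detected_room == outside and cs.s == "High":
        return Label.NOT_BACK_HOME, ""
    if (
        cs.detected_room not in (bedroom, outside)
        and cs.z is State.ABNORMAL
        and cs.s == "High"
        and cs.w == "Abnormal"
        and cs.sag_level is ActivityLevel.VERY_LOW
    ):
        return Label.DEAD, ""
    return Label.NORMAL, "unclassified deviation"


def classify_chain(
    samples: Sequence[DetectionSample],
    model: BehaviourModel | ModelProvider,
    layout: HomeLayout,
    bedroom: str = "Bedroom",
) -> list[AnomalyReport]:
    """Classify every detection sample of a run."""
    provider = _as_provider(model)
    reports: list[AnomalyReport] = []
    max_ag_cache: dict[int, float] = {}
    for smp in samples:
        mdl = provider(smp.ts)
        key = id(mdl)
        if key not in max_ag_cache:
            max_ag_cache[key] = mdl.max_global_activity
        max_ag = max_ag_cache[key]
        w_ag = weighted_global_activity(mdl, smp.ts)
        state = ClassifierState(
            z=smp.state,
            s=stay_state(smp.cs_minutes, mdl, smp.room, smp.ts.weekday()),
            w=activity_match(activity_level(w_ag, max_ag), activity_level(smp.sag, max_ag)),
            sag_level=activity_level(smp.sag, max_ag),
            detected_room=smp.room,
            expected=expected_room(mdl, smp.ts),
            w_ag=w_ag,
            s_ag=smp.sag,
        )
        label, note = classify(state, bedroom=bedroom)
        reports.append(AnomalyReport(ts=smp.ts, label=label, evidence=state, note=note))
    return reports
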