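"""Real-time anomaly detection: estimator and confirmation automaton.

The detection process runs asynchronously from learning and emits exactly one
sample per sampling period (default 1 min), regardless of when observations
arrive.  Per sample:

1. the *detected room* is the room of the most recent observation (PIR
   sensors fire on movement and then sleep, so the person is assumed to stay
   where last seen);
2. the **location likelihood** ``l_n`` is the model's stay probability
   ``P^{r,r}`` for that room in the current weekday/interval cell, normalised
   by the stay probability of the cell's most probable room (so a fully
   expected location scores 1 even when the cell's distribution is diffuse);
3. a low-pass filter (unweighted moving average over the smoothing window,
   default 10 min) turns ``l_n`` into the smoothed likelihood ``g_n``;
4. the binary abnormality state is ``h_n = 1`` iff ``g_n`` drops strictly
   below the threshold.

The automaton turns the noisy ``h_n`` chain into three states with a single
timer: ``Normal`` (timer resets on any normal sample; leaves for
``PotentialAbnormal`` once abnormal samples persist beyond the normal timeout
N1), ``PotentialAbnormal`` (timer decrements — is *not* reset — on normal
samples; confirms ``Abnormal`` at N2, returns to ``Normal`` when the timer
drains) and ``Abnormal`` (exits back to ``Normal`` after a sustained normal
streak of length N1, or never, when latched).  Short abnormal glitches
(< N1) therefore never raise an alarm, and an alarm is only confirmed after
N2 minutes of sustained deviation.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Sequence

from .events import HomeLayout, Observation, TimeGrid
from .learning import BehaviourModel, ModelCell


@dataclass(frozen=True)
class DetectionConfig:
    """Detector settings (defaults follow the study configuration)."""

    sampling_minutes: float = 1.0
    smoothing_minutes: float = 10.0
    threshold: float = 0.25
    n1_minutes: float = 5.0  # normal timeout
    n2_minutes: float = 10.0  # abnormal (confirmation) timeout
    latch_abnormal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be within [0, 1]")
        if self.n1_minutes >= self.n2_minutes:
            raise ValueError("N1 must be smaller than N2")

    @property
    def window_samples(self) -> int:
        return max(1, round(self.smoothing_minutes / self.sampling_minutes))


def location_likelihood(model: BehaviourModel, room: str, now: datetime) -> float:
    """Raw location likelihood: the stay probability of the detected room."""
    if room not in model.rooms:
        return 0.0
    return model.cell(now).self_transition_prob(room)


def normalise_likelihood(l: float, cell: ModelCell) -> float:
    """Normalise by the stay probability of the cell's most probable room.

    An all-zero (unmodelled) cell yields 0.  Normalisation never decreases the
    raw value since the maximum stay probability is at most 1.
    """
    peak = float(cell.stay_probs().max())
    if peak <= 0.0:
        return 0.0
    return min(l / peak, 1.0)


def classify_sample(g: float, threshold: float) -> int:
    """Binary abnormality: 1 iff the smoothed likelihood drops below threshold."""
    return 1 if g < threshold else 0


@dataclass
class EstimatorState:
    """Moving-average smoother plus the latest (l, g, h) values."""

    config: DetectionConfig
    history: deque = field(default_factory=deque)
    last_l: float = 1.0
    last_g: float = 1.0
    last_h: int = 0

    def smooth(self, sample: float) -> float:
        """Moving average over the last smoothing-window samples.

        The window grows from 1 at stream start; output always lies within
        the min/max of the window contents.
        """
        self.history.append(sample)
        if len(self.history) > self.config.window_samples:
            self.history.popleft()
        return sum(self.history) / len(self.history)

    @property
    def warmed_up(self) -> bool:
        return len(self.history) >= self.config.window_samples

    def step(self, l: float) -> tuple[float, int]:
        """Feed one normalised likelihood; returns (g, h).

        During warm-up (before one full smoothing window has elapsed) the
        abnormality output is suppressed (h = 0).
        """
        g = self.smooth(l)
        h = classify_sample(g, self.config.threshold) if self.warmed_up else 0
        self.last_l, self.last_g, self.last_h = l, g, h
        return g, h


class State(enum.Enum):
    NORMAL = "Normal"
    POTENTIAL = "PotentialAbnormal"
    ABNORMAL = "Abnormal"


@dataclass
class AutomatonState:
    """Three-state confirmation automaton with one timer."""

    n1: float = 5.0
    n2: float = 10.0
    latch: bool = False
    state: State = State.NORMAL
    timer: float = 0.0
    normal_streak: float = 0.0  # used only to leave Abnormal

    def step(self, h: int, dt: float = 1.0) -> State:
        if self.state is State.NORMAL:
            if h:
                self.timer += dt
                if self.timer > self.n1:
                    self.state = State.POTENTIAL
            else:
                self.timer = 0.0
        elif self.state is State.POTENTIAL:
            if h:
                self.timer += dt
                if self.timer >= self.n2:
                    self.state = State.ABNORMAL
                    self.normal_streak = 0.0
            else:
                self.timer -= dt  # not reset: decremented
                if self.timer <= 0.0:
                    self.state = State.NORMAL
                    self.timer = 0.0
        else:  # ABNORMAL
            if h:
                self.normal_streak = 0.0
            else:
                self.normal_streak += dt
                if not self.latch and self.normal_streak >= self.n1:
                    self.state = State.NORMAL
                    self.timer = 0.0
                    self.normal_streak = 0.0
        return self.state


def automaton_step(a: AutomatonState, h: int, dt: float = 1.0) -> AutomatonState:
    """Functional wrapper over :meth:`AutomatonState.step`."""
    a.step(h, dt)
    return a


@dataclass(frozen=True)
class DetectionSample:
    """One periodic output record of the detection module."""

    ts: datetime
    room: str
    l: float
    g: float
    h: int
    state: State
    cs_minutes: float  # current continuous stay in the detected room
    sag: float  # sampled global activity: trailing-delta_t observation rate
    warmup: bool


ModelProvider = Callable[[datetime], BehaviourModel]


def _as_provider(model: BehaviourModel | ModelProvider) -> ModelProvider:
    if isinstance(model, BehaviourModel):
        return lambda ts: model
    return model


def run_detection(
    observations: Sequence[Observation],
    model: BehaviourModel | ModelProvider,
    layout: HomeLayout,
    config: DetectionConfig | None = None,
    start: datetime | None = None,
    end: datetime | None = None,
) -> list[DetectionSample]:
    """Replay an observation stream through the estimator and automaton.

    Emits one sample per sampling period from ``start`` (default: minute of
    the first observation) to ``end`` (default: last observation), aligned to
    whole sampling periods.  ``model`` may be a single behaviour model or a
    callable returning the model in force at a given time (weekly-updated
    pipelines pass the latter).
    """
    cfg = config or DetectionConfig()
    provider = _as_provider(model)
    obs = [(o.ts, layout.room_of(o.sensor_id)) for o in observations]
    obs = [(ts, room) for ts, room in obs if room is not None]
    if not obs:
        return []
    if start is None:
        start = obs[0][0].replace(second=0, microsecond=0)
    if end is None:
        end = obs[-1][0]

    est = EstimatorState(config=cfg)
    aut = AutomatonState(n1=cfg.n1_minutes, n2=cfg.n2_minutes, latch=cfg.latch_abnormal)
    step = timedelta(minutes=cfg.sampling_minutes)
    samples: list[DetectionSample] = []

    i = 0  # index of next unseen observation
    room: str | None = None
    recent: deque = deque()  # observation timestamps within trailing delta_t

    # Behavioural stay clock: excursions away from the run's room shorter
    # than N1 (the automaton's own glitch horizon) do not reset it, so a
    # two-minute bathroom visit does not cut a night's sleep in two.  The
    # learned longest-stay lists use the strict merge rule; the tolerant
    # clock is deliberately the more sensitive side of the comparison.
    tol = timedelta(minutes=cfg.n1_minutes)
    run_room: str | None = None
    run_start: datetime | None = None
    away_since: datetime | None = None  # first obs away from run_room

    t = start
    while t <= end:
        while i < len(obs) and obs[i][0] <= t:
            ts_i, room_i = obs[i]
            if run_room is None:
                run_room, run_start = room_i, ts_i
            elif room_i == run_room:
                if away_since is not None and ts_i - away_since >= tol:
                    run_start = ts_i  # a long absence did break the run
                away_since = None
            else:
                if away_since is None:
                    away_since = ts_i
                elif ts_i - away_since >= tol:
                    run_room, run_start, away_since = room_i, away_since, None
            room = room_i
            recent.append(ts_i)
            i += 1
        if room is None:  # nothing seen yet: no output until first observation
            t += step
            continue
        if room != run_room and away_since is not None and t - away_since >= tol:
            run_room, run_start, away_since = room, away_since, None
        cs_start = run_start if room == run_room else away_since
        mdl = provider(t)
        delta_t = timedelta(minutes=mdl.grid.delta_t)
        while recent and recent[0] <= t - delta_t:
            recent.popleft()
        cell = mdl.cell(t)
        l_raw = location_likelihood(mdl, room, t)
        l = normalise_likelihood(l_raw, cell)
        warm = not est.warmed_up
        g, h = est.step(l)
        state = aut.step(h, cfg.sampling_minutes)
        samples.append(
            DetectionSample(
                ts=t,
                room=room,
                l=l,
                g=g,
                h=h,
                state=state,
                cs_minutes=(t - cs_start).total_seconds() / 60.0,
                sag=len(recent) / mdl.grid.delta_t,
                warmup=warm,
            )
        )
        t += step
    return samples
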