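"""Learning of the weekly mobility model from an observation stream.

For every weekday and every ``delta_t``-minute interval of the day, a
:class:`ModelCell` summarises the person's behaviour over the learning
window:

* ``TS^i`` — total stay minutes in room *i* within the cell (summed over the
  window days mapping to the cell);
* ``M^{i,j}`` — number of observed transitions from room *i* to room *j*
  (self-transitions included; the matrix need not be symmetric);
* stay probability ``P^{i,i} = TS^i / sum_j TS^j`` — the chance of finding
  the person in room *i* during the interval;
* transition probability
  ``P^{i,j} = (1 - P^{i,i}) * M^{i,j} / sum_{k != i} M^{i,k}`` — the residual
  probability mass allocated proportionally to observed exits;
* activity rates: global ``AG`` (all observations per minute), inter-room
  ``AE`` (non-self transitions per minute) and intra-room ``AA^i`` (per-room
  observations per minute), all averaged over contributing window days.

A cell accumulates contributions from every window day of its weekday (4
days with the default 4-week window), so the raw sums are divided by the
number of contributing days wherever a per-day rate or probability is
needed.  Per weekday the model also keeps the list of *continuous stays*
(maximal runs of consecutive same-room stays) per room; the maximum defines
the "expected longest stay" used by the anomaly classifier.

The learning window slides: every ``shift_weeks`` the oldest observations are
discarded, the newest are appended and the model is rebuilt, so the model
tracks gradual changes in routine (full adaptation after ``length_weeks``
shifts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np

from .events import (
    GridCell,
    HomeLayout,
    Observation,
    Stay,
    StreamStats,
    TimeGrid,
    split_stay,
    stays_from_observations,
)

logger = logging.getLogger("bms")

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelCell:
    """Accumulated behaviour statistics for one weekly grid cell."""

    cell: GridCell
    rooms: tuple[str, ...]
    delta_t: int
    n_days: int
    ts: np.ndarray  # raw stay minutes per room, summed over window days
    m: np.ndarray  # raw transition counts, rooms x rooms
    obs: np.ndarray  # raw observation counts per room

    @classmethod
    def empty(cls, cell: GridCell, rooms: tuple[str, ...], delta_t: int, n_days: int) -> "ModelCell":
        r = len(rooms)
        return cls(
            cell=cell,
            rooms=rooms,
            delta_t=delta_t,
            n_days=n_days,
            ts=np.zeros(r),
            m=np.zeros((r, r), dtype=np.int64),
            obs=np.zeros(r, dtype=np.int64),
        )

    # -- stay / transition probabilities -----------------------------------

    @property
    def total_stay(self) -> float:
        return float(self.ts.sum())

    @property
    def ts_mean(self) -> np.ndarray:
        """Per-day average stay minutes per room."""
        return self.ts / max(self.n_days, 1)

    def observed(self, room: str) -> bool:
        return self.ts[self.rooms.index(room)] > 0

    @property
    def unmodelled(self) -> bool:
        """True when no stay time at all was recorded for this cell."""
        return self.total_stay == 0

    def stay_probs(self) -> np.ndarray:
        """Vector of stay probabilities ``P^{i,i}``; zeros if unmodelled."""
        total = self.total_stay
        if total == 0:
            return np.zeros(len(self.rooms))
        return self.ts / total

    def self_transition_prob(self, room: str) -> float:
        return float(self.stay_probs()[self.rooms.index(room)])

    def transition_prob(self, i: str, j: str) -> float:
        """Off-diagonal transition probability from room ``i`` to ``j``."""
        if i == j:
            raise ValueError("use self_transition_prob for the diagonal")
        return float(self.matrix()[self.rooms.index(i), self.rooms.index(j)])

    def matrix(self) -> np.ndarray:
        """Full row-stochastic transition matrix for the cell.

        Rows of rooms never observed in the cell are all-zero.  When a room
        has stay time but no observed exits the residual mass folds back into
        the diagonal so the row still sums to 1.
        """
        r = len(self.rooms)
        probs = self.stay_probs()
        out = np.zeros((r, r))
        for i in range(r):
            if self.ts[i] <= 0:
                continue  # unobserved room: all-zero row
            exits = self.m[i].astype(float).copy()
            exits[i] = 0.0
            total_exits = exits.sum()
            if total_exits == 0:
                out[i, i] = 1.0
            else:
                out[i, i] = probs[i]
                out[i] += (1.0 - probs[i]) * exits / total_exits
        return out

    # -- activity dimensions ------------------------------------------------

    def global_activity(self) -> float:
        """AG: observations per minute, averaged over contributing days."""
        return float(self.obs.sum()) / max(self.n_days, 1) / self.delta_t

    def inter_room_activity(self) -> float:
        """AE: transitions between distinct rooms per minute."""
        inter = self.m.sum() - np.trace(self.m)
        return float(inter) / max(self.n_days, 1) / self.delta_t

    def intra_room_activity(self, room: str) -> float:
        """AA^i: observations in one room per minute."""
        return float(self.obs[self.rooms.index(room)]) / max(self.n_days, 1) / self.delta_t


@dataclass
class DayProfile:
    """Continuous-stay durations per room for one weekday."""

    weekday: int
    cs_list: dict[str, list[float]] = field(default_factory=dict)

    def add(self, room: str, minutes: float) -> None:
        self.cs_list.setdefault(room, []).append(minutes)

    def longest_cs(self, room: str) -> float:
        """Expected longest continuous stay; 0 when the room was never seen."""
        values = self.cs_list.get(room)
        return max(values) if values else 0.0


@dataclass
class BehaviourModel:
    """Weekly behaviour model: 7 x (1440/delta_t) cells plus day profiles."""

    grid: TimeGrid
    rooms: tuple[str, ...]
    cells: dict[GridCell, ModelCell]
    day_profiles: dict[int, DayProfile]
    window_start: datetime
    window_weeks: int

    @property
    def window_end(self) -> datetime:
        return self.window_start + timedelta(weeks=self.window_weeks)

    def cell(self, when: datetime | GridCell) -> ModelCell:
        key = when if isinstance(when, GridCell) else self.grid.cell_of(when)
        return self.cells[key]

    @property
    def max_global_activity(self) -> float:
        """Maximum AG over all cells — reference point for activity levels."""
        return max(c.global_activity() for c in self.cells.values())

    def longest_cs(self, room: str, weekday: int) -> float:
        return self.day_profiles[weekday].longest_cs(room)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "delta_t": self.grid.delta_t,
            "rooms": list(self.rooms),
            "window_start": self.window_start.isoformat(),
            "window_weeks": self.window_weeks,
            "cells": [
                {
                    "weekday": c.cell.weekday,
                    "k": c.cell.k,
                    "n_days": c.n_days,
                    "ts": c.ts.tolist(),
                    "m": c.m.tolist(),
                    "obs": c.obs.tolist(),
                }
                for c in self.cells.values()
            ],
            "day_profiles": {
                str(d): p.cs_list for d, p in self.day_profiles.items()
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "BehaviourModel":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        grid = TimeGrid(delta_t=doc["delta_t"])
        rooms = tuple(doc["rooms"])
        cells: dict[GridCell, ModelCell] = {}
        for c in doc["cells"]:
            cell = GridCell(c["weekday"], c["k"])
            cells[cell] = ModelCell(
                cell=cell,
                rooms=rooms,
                delta_t=grid.delta_t,
                n_days=c["n_days"],
                ts=np.asarray(c["ts"], dtype=float),
                m=np.asarray(c["m"], dtype=np.int64),
                obs=np.asarray(c["obs"], dtype=np.int64),
            )
        profiles = {
            int(d): DayProfile(weekday=int(d), cs_list={r: list(v) for r, v in cs.items()})
            for d, cs in doc["day_profiles"].items()
        }
        return cls(
            grid=grid,
            rooms=rooms,
            cells=cells,
            day_profiles=profiles,
            window_start=datetime.fromisoformat(doc["window_start"]),
            window_weeks=doc["window_weeks"],
        )


# -- model construction ------------------------------------------------------


def empty_model(
    layout: HomeLayout, grid: TimeGrid, window_start: datetime, window_weeks: int
) -> BehaviourModel:
    if window_start.time() != datetime.min.time():
        raise ValueError("window_start must be at midnight")
    if window_weeks < 1:
        raise ValueError("window length must be at least one week")
    cells = {
        cell: ModelCell.empty(cell, layout.rooms, grid.delta_t, window_weeks)
        for cell in grid.cells()
    }
    profiles = {d: DayProfile(weekday=d) for d in range(7)}
    return BehaviourModel(
        grid=grid,
        rooms=layout.rooms,
        cells=cells,
        day_profiles=profiles,
        window_start=window_start,
        window_weeks=window_weeks,
    )


def accumulate_stays(stays: Iterable[Stay], model: BehaviourModel) -> BehaviourModel:
    """Add stay time to the model's cells (Step 1-2 of the matrix build).

    Each stay is split at grid boundaries and its minutes added to ``TS`` of
    its room in every overlapped cell.  Stays outside the model window are an
    error (stays crossing the window edge are clipped).
    """
    for stay in stays:
        if stay.end < model.window_start or stay.start > model.window_end:
            raise ValueError(f"stay at {stay.start} lies outside the learning window")
        clipped = Stay(
            stay.room,
            max(stay.start, model.window_start),
            min(stay.end, model.window_end),
        )
        for piece in split_stay(clipped, model.grid):
            cell = model.cells[piece.cell]
            cell.ts[cell.rooms.index(piece.room)] += piece.minutes
    return model


def continuous_stays(stays: Sequence[Stay], weekday: int | None = None) -> dict[int, DayProfile]:
    """Merge consecutive same-room stays into continuous-stay runs.

    A run is broken by any interleaved stay in a different room, regardless of
    its duration.  A run is credited to the calendar day on which it started.
    Returns day profiles for all weekdays, or only ``weekday`` when given.
    """
    profiles = {d: DayProfile(weekday=d) for d in range(7)}
    run_room: str | None = None
    run_start: datetime | None = None
    run_minutes = 0.0
    for stay in stays:
        if stay.room != run_room:
            if run_room is not None and run_minutes > 0:
                profiles[run_start.weekday()].add(run_room, run_minutes)
            run_room, run_start, run_minutes = stay.room, stay.start, 0.0
        run_minutes += stay.duration
    if run_room is not None and run_minutes > 0:
        profiles[run_start.weekday()].add(run_room, run_minutes)
    if weekday is not None:
        return {weekday: profiles[weekday]}
    return profiles


def build_model(
    observations: Sequence[Observation],
    layout: HomeLayout,
    grid: TimeGrid | None = None,
    window_start: datetime | None = None,
    window_weeks: int = 4,
    stats: StreamStats | None = None,
) -> BehaviourModel:
    """Batch-build the behaviour model from the observations in the window.

    ``window_start`` defaults to midnight of the first observation's day.
    Observations outside ``[window_start, window_start + weeks)`` are ignored.
    """
    grid = grid or TimeGrid()
    if window_start is None:
        if not observations:
            raise ValueError("need observations or an explicit window_start")
        window_start = datetime.combine(observations[0].ts.date(), datetime.min.time())
    model = empty_model(layout, grid, window_start, window_weeks)
    in_window = [o for o in observations if window_start <= o.ts < model.window_end]
    stays = stays_from_observations(in_window, layout, stats=stats)

    accumulate_stays(stays, model)

    # observation counts and transition counts per cell
    prev_room: str | None = None
    for obs in in_window:
        room = layout.room_of(obs.sensor_id)
        if room is None:
            continue
        cell = model.cells[grid.cell_of(obs.ts)]
        cell.obs[cell.rooms.index(room)] += 1
        if prev_room is not None:
            cell.m[cell.rooms.index(prev_room), cell.rooms.index(room)] += 1
        prev_room = room

    model.day_profiles = continuous_stays(stays)
    return model


# -- sliding learning window -------------------------------------------------


@dataclass
class LearningWindow:
    """Sliding window of retained observations feeding the model."""

    layout: HomeLayout
    grid: TimeGrid = field(default_factory=TimeGrid)
    length_weeks: int = 4
    shift_weeks: int = 1
    start: datetime | None = None
    buffer: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shift_weeks > self.length_weeks:
            raise ValueError("shift must not exceed window length")

    @property
    def end(self) -> datetime | None:
        if self.start is None:
            return None
        return self.start + timedelta(weeks=self.length_weeks)

    def initialise(self, observations: Sequence[Observation], start: datetime | None = None) -> BehaviourModel:
        """Fill the buffer with the first full window and build the model."""
        if start is None:
            start = datetime.combine(observations[0].ts.date(), datetime.min.time())
        self.start = start
        self.buffer = [o for o in observations if start <= o.ts < self.end]
        return self.rebuild()

    def rebuild(self) -> BehaviourModel:
        return build_model(
            self.buffer,
            self.layout,
            grid=self.grid,
            window_start=self.start,
            window_weeks=self.length_weeks,
        )

    def update(self, new_observations: Sequence[Observation]) -> BehaviourModel:
        """Shift the window by ``shift_weeks`` and rebuild the model.

        The oldest observations fall out of the window, the new ones are
        appended.  The result is by construction identical to a from-scratch
        batch build over the shifted window.  A shift period with no new
        observations is allowed (warning only).
        """
        if self.start is None:
            raise RuntimeError("window not initialised")
        self.start = self.start + timedelta(weeks=self.shift_weeks)
        kept = [o for o in self.buffer if o.ts >= self.start]
        added = [o for o in new_observations if self.start <= o.ts < self.end]
        if not added:
            logger.warning("window shift to %s received no new observations", self.start)
        self.buffer = sorted(kept + added, key=lambda o: o.ts)
        return self.rebuild()


def update_model(window: LearningWindow, new_observations: Sequence[Observation]) -> BehaviourModel:
    """Functional alias for :meth:`LearningWindow.update`."""
    return window.update(new_observations)
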