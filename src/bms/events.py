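"""Core domain objects for PIR event streams.

A passive-infrared (PIR) motion sensor emits a timestamped trigger whenever
movement is sensed in its room.  The whole system is built on two derived
notions:

* an **observation** ``o = (ts, sensor_id)`` — one trigger;
* a **stay** — the dwell interval between two consecutive observations,
  attributed to the room of the *earlier* one (the person is assumed to
  remain where they were last seen until a new trigger says otherwise).

Time is organised on a weekly grid: 7 weekdays x (1440 / delta_t) equal
intervals per day.  Intervals are half-open on the left, ``(t, t + delta_t]``,
so an instant falling exactly on a boundary belongs to the earlier-labelled
cell.  Stays that overlap several grid cells (including the midnight weekday
boundary) are split into pieces whose minutes sum exactly to the stay
duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Iterator, NamedTuple, Sequence

import networkx as nx

logger = logging.getLogger("bms")

#: Name of the virtual room modelling periods spent out of the house.
OUTSIDE = "Outside"

MINUTES_PER_DAY = 1440


class Observation(NamedTuple):
    """A single sensor trigger ``o = (ts, sensor_id)``."""

    ts: datetime
    sensor_id: str


@dataclass(frozen=True)
class HomeLayout:
    """Rooms, the sensor->room map and the room-adjacency graph.

    Exactly one virtual ``Outside`` room must be present; the adjacency graph
    (undirected) must be connected so every room is reachable.
    """

    rooms: tuple[str, ...]
    sensor_map: dict[str, str]
    adjacency: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        if self.rooms.count(OUTSIDE) != 1:
            raise ValueError(f"layout must contain exactly one {OUTSIDE!r} room")
        if len(set(self.rooms)) != len(self.rooms):
            raise ValueError("duplicate room names")
        unknown = {r for r in self.sensor_map.values()} - set(self.rooms)
        if unknown:
            raise ValueError(f"sensors map to unknown rooms: {sorted(unknown)}")
        for pair in self.adjacency:
            if not pair <= set(self.rooms):
                raise ValueError(f"adjacency pair {set(pair)} uses unknown rooms")
        if not nx.is_connected(self.graph()):
            raise ValueError("room adjacency graph is not connected")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.rooms)
        g.add_edges_from(tuple(p) for p in self.adjacency)
        return g

    def room_of(self, sensor_id: str) -> str | None:
        return self.sensor_map.get(sensor_id)

    def index(self, room: str) -> int:
        return self.rooms.index(room)

    def path(self, src: str, dst: str) -> list[str]:
        """Shortest room-to-room walk respecting adjacency (inclusive)."""
        return nx.shortest_path(self.graph(), src, dst)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency


def default_layout() -> HomeLayout:
    """Six-room single-resident home: five physical rooms plus Outside.

    One PIR sensor per room (the Outside sensor is virtual: it fires once on
    exit and once on return).  The adjacency mirrors a small apartment where
    the living room is the hub: one cannot go from the bedroom to the kitchen
    without crossing the living room.
    """
    rooms = ("Bedroom", "Bathroom", "Livingroom", "Kitchen", "Store", OUTSIDE)
    sensors = {f"pir_{r.lower()}": r for r in rooms}
    adjacency = frozenset(
        frozenset(p)
        for p in [
            ("Bedroom", "Bathroom"),
            ("Bedroom", "Livingroom"),
            ("Livingroom", "Kitchen"),
            ("Livingroom", OUTSIDE),
            ("Kitchen", "Store"),
        ]
    )
    return HomeLayout(rooms=rooms, sensor_map=sensors, adjacency=adjacency)


class GridCell(NamedTuple):
    """One cell of the weekly grid: (weekday, interval index).

    ``weekday`` follows :meth:`datetime.date.weekday` (Monday = 0 ...
    Sunday = 6); ``k`` indexes the half-open interval
    ``(k * delta_t, (k + 1) * delta_t]`` minutes after midnight.
    """

    weekday: int
    k: int


@dataclass(frozen=True)
class TimeGrid:
    """Weekly time grid with ``delta_t``-minute intervals (default 60)."""

    delta_t: int = 60

    def __post_init__(self) -> None:
        if self.delta_t <= 0 or MINUTES_PER_DAY % self.delta_t:
            raise ValueError("delta_t must be a positive divisor of 1440")

    @property
    def cells_per_day(self) -> int:
        return MINUTES_PER_DAY // self.delta_t

    def cells(self) -> Iterator[GridCell]:
        for d in range(7):
            for k in range(self.cells_per_day):
                yield GridCell(d, k)

    def cell_of(self, ts: datetime) -> GridCell:
        """Cell containing the instant ``ts`` under the ``(t, t+dt]`` rule.

        Midnight sharp belongs to the last cell of the *previous* day.
        """
        minute = ts.hour * 60 + ts.minute + (ts.second + ts.microsecond / 1e6) / 60
        if minute == 0.0:
            prev = ts - timedelta(days=1)
            return GridCell(prev.weekday(), self.cells_per_day - 1)
        k = -(-minute // self.delta_t) - 1  # ceil(minute/dt) - 1
        return GridCell(ts.weekday(), int(k))

    def cell_start(self, ts: datetime) -> datetime:
        """Start instant of the cell containing ``ts`` (exclusive bound)."""
        cell = self.cell_of(ts)
        day = ts.date()
        if cell.weekday != ts.weekday():  # midnight sharp -> previous day
            day = (ts - timedelta(days=1)).date()
        return datetime.combine(day, datetime.min.time()) + timedelta(
            minutes=cell.k * self.delta_t
        )

    def prev_cell(self, cell: GridCell) -> GridCell:
        if cell.k > 0:
            return GridCell(cell.weekday, cell.k - 1)
        return GridCell((cell.weekday - 1) % 7, self.cells_per_day - 1)


@dataclass(frozen=True)
class Stay:
    """A dwell episode in one room delimited by two consecutive observations."""

    room: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("stay ends before it starts")

    @property
    def duration(self) -> float:
        """Duration in fractional minutes."""
        return (self.end - self.start).total_seconds() / 60.0


class StayPiece(NamedTuple):
    """The part of a stay falling inside one grid cell."""

    room: str
    cell: GridCell
    minutes: float


@dataclass
class StreamStats:
    """Counters surfaced to the caller for rejected input records."""

    unknown_sensor: int = 0
    malformed: int = 0


def stays_from_observations(
    observations: Sequence[Observation],
    layout: HomeLayout,
    stats: StreamStats | None = None,
) -> list[Stay]:
    """Turn an ordered observation stream into stays.

    Each consecutive pair ``(o_{i-1}, o_i)`` yields one stay in the room of
    ``o_{i-1}`` spanning ``[ts_{i-1}, ts_i]``.  Zero-duration stays (distinct
    sensors sharing a timestamp) are retained: they carry no dwell time but do
    record the transition.  Observations from unknown sensors are dropped with
    a logged warning; out-of-order timestamps are a hard error.
    """
    stats = stats if stats is not None else StreamStats()
    mapped: list[tuple[datetime, str]] = []
    last_ts: datetime | None = None
    for obs in observations:
        if last_ts is not None and obs.ts < last_ts:
            raise ValueError(f"observations not sorted by timestamp at {obs.ts}")
        last_ts = obs.ts
        room = layout.room_of(obs.sensor_id)
        if room is None:
            stats.unknown_sensor += 1
            logger.warning("unknown sensor %r at %s: record dropped", obs.sensor_id, obs.ts)
            continue
        mapped.append((obs.ts, room))
    return [
        Stay(room=room_a, start=ts_a, end=ts_b)
        for (ts_a, room_a), (ts_b, _room_b) in zip(mapped, mapped[1:])
    ]


def split_stay(stay: Stay, grid: TimeGrid) -> list[StayPiece]:
    """Partition a stay's minutes over the grid cells it overlaps.

    Splitting happens at every cell boundary, including midnight (which also
    changes the weekday).  Piece minutes sum to the stay duration exactly (to
    timestamp resolution).  A zero-duration stay yields no pieces.
    """
    pieces: list[StayPiece] = []
    cursor = stay.start
    step = timedelta(minutes=grid.delta_t)
    while cursor < stay.end:
        cell_start = grid.cell_start(cursor + timedelta(microseconds=1))
        # cell containing the sub-interval starting at `cursor`
        boundary = cell_start + step
        upto = min(boundary, stay.end)
        minutes = (upto - cursor).total_seconds() / 60.0
        mid = cursor + (upto - cursor) / 2
        pieces.append(StayPiece(stay.room, grid.cell_of(mid), minutes))
        cursor = upto
    return pieces


def split_stays(stays: Iterable[Stay], grid: TimeGrid) -> Iterator[StayPiece]:
    for stay in stays:
        yield from split_stay(stay, grid)
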