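"""Synthetic PIR event-stream generator with anomaly injection.

The generator emulates a single resident following a fixed daily schedule of
*segments* (sleep in the bedroom, time out of the house, domestic activity in
the living room), over the six-room home layout plus the virtual Outside
room.  Two built-in profiles:

* **Profile A** — a morning person: sleeps midnight-08:00, out of the house
  08:00-16:00, domestic activities in the living room in the evening
  (16:00-24:00);
* **Profile B** — a nightly person: out of the house midnight-08:00, sleeps
  08:00-16:00, living room 16:00-23:00, leaves again at 23:00.

Mechanics (all rates configurable on the spec):

* segment boundaries jitter uniformly by +/-5 min from day to day;
* while in a room the PIR fires with exponentially distributed gaps
  (mean 5 min while active, 30 min while asleep);
* short excursions (night bathroom visits, kitchen trips while in the living
  room, rare store errands) follow the adjacency graph, emitting one
  observation per traversed room;
* Outside periods emit a single virtual exit observation, then silence until
  the return.

Streams are byte-identical for identical (spec, seed).  Anomalies *replace*
the baseline events inside their window — never overlay them — so the ground
truth used for scoring is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .events import OUTSIDE, HomeLayout, Observation, default_layout

TRAVERSE_MINUTES = 0.5  # per room-to-room hop while walking


@dataclass(frozen=True)
class ExcursionSpec:
    """Short round trip from a segment's primary room."""

    room: str
    per_hour: float  # expected excursions per hour of the segment
    mean_minutes: float  # mean excursion duration


@dataclass(frozen=True)
class Segment:
    """One block of the daily schedule, ``[start_hour, end_hour)``."""

    start_hour: float
    end_hour: float
    room: str
    state: str  # "active" | "asleep" | "outside"
    excursions: tuple[ExcursionSpec, ...] = ()


@dataclass(frozen=True)
class ProfileSpec:
    """A daily mobility routine repeated (with jitter) over several weeks."""

    name: str
    segments: tuple[Segment, ...]
    weeks: int = 12
    jitter_minutes: float = 5.0
    event_gap_minutes: dict = field(
        default_factory=lambda: {"active": 5.0, "asleep": 30.0}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        hours = sorted((s.start_hour, s.end_hour) for s in self.segments)
        if hours[0][0] != 0 or hours[-1][1] != 24:
            raise ValueError("segments must cover the 24-h day")
        for (_, e), (s, _) in zip(hours, hours[1:]):
            if e != s:
                raise ValueError("segments must tile the day without overlap")


def profile_a() -> ProfileSpec:
    """Morning person: bedroom 0-8, outside 8-16, living room 16-24."""
    return ProfileSpec(
        name="A",
        segments=(
            Segment(0, 8, "Bedroom", "asleep",
                    (ExcursionSpec("Bathroom", 0.0625, 3.0),)),  # ~0.5 visits/night
            Segment(8, 16, OUTSIDE, "outside"),
            Segment(16, 24, "Livingroom", "active",
                    (ExcursionSpec("Kitchen", 0.7, 6.0),
                     ExcursionSpec("Store", 0.025, 2.0))),
        ),
    )


def profile_b() -> ProfileSpec:
    """Nightly person: outside 0-8, bedroom 8-16, living room 16-23, out 23-24."""
    return ProfileSpec(
        name="B",
        segments=(
            Segment(0, 8, OUTSIDE, "outside"),
            Segment(8, 16, "Bedroom", "asleep",
                    (ExcursionSpec("Bathroom", 0.0625, 3.0),)),
            Segment(16, 23, "Livingroom", "active",
                    (ExcursionSpec("Kitchen", 0.7, 6.0),
                     ExcursionSpec("Store", 0.025, 2.0))),
            Segment(23, 24, OUTSIDE, "outside"),
        ),
    )


def get_profile(name: str) -> ProfileSpec:
    profiles = {"A": profile_a, "B": profile_b}
    try:
        return profiles[name.upper()]()
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; expected A or B") from None


def _sensor_for(layout: HomeLayout) -> dict[str, str]:
    """Inverse sensor map (one representative sensor per room)."""
    inv: dict[str, str] = {}
    for sensor, room in sorted(layout.sensor_map.items()):
        inv.setdefault(room, sensor)
    return inv


def _walk(
    layout: HomeLayout, src: str, dst: str, at: datetime
) -> tuple[list[tuple[datetime, str]], datetime]:
    """Events for walking ``src -> dst`` along the adjacency graph.

    One observation per entered room, TRAVERSE_MINUTES apart; returns the
    events and the arrival time.
    """
    if src == dst:
        return [], at
    rooms = layout.path(src, dst)[1:]
    events = []
    t = at
    for room in rooms:
        events.append((t, room))
        t += timedelta(minutes=TRAVERSE_MINUTES)
    return events, events[-1][0]


def generate(
    profile: ProfileSpec,
    layout: HomeLayout | None = None,
    start: datetime | date | None = None,
    weeks: int | None = None,
    seed: int | None = None,
) -> list[Observation]:
    """Generate the observation stream for a profile.

    ``start`` defaults to Monday 2024-01-01 (a midnight); ``weeks`` and
    ``seed`` default to the spec's values.
    """
    layout = layout or default_layout()
    weeks = weeks if weeks is not None else profile.weeks
    seed = seed if seed is not None else (profile.seed if profile.seed is not None else 0)
    if isinstance(start, date) and not isinstance(start, datetime):
        start = datetime.combine(start, time())
    start = start or datetime(2024, 1, 1)
    if start.time() != time():
        raise ValueError("stream start must be at midnight")
    for seg in profile.segments:
        if seg.room not in layout.rooms:
            raise ValueError(f"segment room {seg.room!r} not in layout")
        for exc in seg.excursions:
            if exc.room not in layout.rooms:
                raise ValueError(f"excursion room {exc.room!r} not in layout")

    rng = np.random.default_rng(seed)
    end = start + timedelta(weeks=weeks)
    n_days = weeks * 7

    # jittered segment start instants over the whole run, in schedule order
    marks: list[tuple[datetime, Segment]] = []
    for day in range(n_days):
        day0 = start + timedelta(days=day)
        for seg in sorted(profile.segments, key=lambda s: s.start_hour):
            t = day0 + timedelta(hours=seg.start_hour)
            t += timedelta(minutes=float(rng.uniform(-profile.jitter_minutes, profile.jitter_minutes)))
            marks.append((max(t, start), seg))
    marks.sort(key=lambda m: m[0])

    events: list[tuple[datetime, str]] = []
    prev_room = marks[0][1].room  # occupant's room as the stream opens
    events.append((start, prev_room))

    for idx, (t0, seg) in enumerate(marks):
        t1 = marks[idx + 1][0] if idx + 1 < len(marks) else end
        if t1 <= t0:
            continue
        walk_events, arrived = _walk(layout, prev_room, seg.room, t0)
        events.extend(walk_events)
        prev_room = seg.room
        if seg.state == "outside":
            continue  # single exit observation already emitted by the walk

        # dwell events with exponential gaps
        gap = profile.event_gap_minutes[seg.state]
        dwell: list[datetime] = []
        t = arrived + timedelta(minutes=float(rng.exponential(gap)))
        while t < t1:
            dwell.append(t)
            t += timedelta(minutes=float(rng.exponential(gap)))

        # excursions: short round trips from the primary room
        exc_events: list[tuple[datetime, str]] = []
        blocked: list[tuple[datetime, datetime]] = []
        seg_hours = (t1 - t0).total_seconds() / 3600.0
        for exc in seg.excursions:
            count = rng.poisson(exc.per_hour * seg_hours)
            for _ in range(count):
                dur = max(2.0, float(rng.exponential(exc.mean_minutes)))
                lo = t0 + timedelta(minutes=10)
                hi = t1 - timedelta(minutes=10 + dur)
                if hi <= lo:
                    continue
                e0 = lo + timedelta(seconds=float(rng.uniform(0, (hi - lo).total_seconds())))
                e1 = e0 + timedelta(minutes=dur)
                if any(e0 < b1 and b0 < e1 for b0, b1 in blocked):
                    continue
                blocked.append((e0, e1))
                out_walk, _ = _walk(layout, seg.room, exc.room, e0)
                back = layout.path(exc.room, seg.room)[1:]
                back_start = e1 - timedelta(minutes=TRAVERSE_MINUTES * len(back))
                back_walk = [
                    (back_start + timedelta(minutes=TRAVERSE_MINUTES * i), room)
                    for i, room in enumerate(back)
                ]
                exc_events.extend(out_walk)
                exc_events.extend(back_walk)
        dwell = [t for t in dwell if not any(b0 <= t < b1 for b0, b1 in blocked)]
        events.extend((t, seg.room) for t in dwell)
        events.extend(exc_events)

    events = [(t, room) for t, room in events if start <= t < end]
    events.sort(key=lambda e: e[0])
    sensor = _sensor_for(layout)
    return [Observation(ts=t, sensor_id=sensor[room]) for t, room in events]


# -- anomaly injection --------------------------------------------------------


@dataclass(frozen=True)
class AnomalySpec:
    """One injected abnormal episode, replacing baseline events in a window."""

    kind: str  # OverSleeping | LessSleeping | NotBackHome | Dead
    day: date
    start_hour: float
    end_hour: float
    room_override: str

    def __post_init__(self) -> None:
        if self.kind not in {"OverSleeping", "LessSleeping", "NotBackHome", "Dead"}:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if not 0 <= self.start_hour < self.end_hour <= 24:
            raise ValueError("anomaly hours must be an increasing range within one day")

    @property
    def start(self) -> datetime:
        return datetime.combine(self.day, time()) + timedelta(hours=self.start_hour)

    @property
    def end(self) -> datetime:
        return datetime.combine(self.day, time()) + timedelta(hours=self.end_hour)


#: Injected windows per profile, mirroring the study design: OverSleeping
#: extends sleep into the afternoon/evening, LessSleeping puts the person
#: away from bed during habitual sleep hours, NotBackHome prolongs the
#: outside period, Dead is a motionless stay in the store room.
DEFAULT_ANOMALIES: dict[str, dict[str, tuple[float, float, str]]] = {
    "A": {
        "OverSleeping": (8, 19, "Bedroom"),
        "LessSleeping": (0, 8, OUTSIDE),
        "NotBackHome": (16, 23, OUTSIDE),
        "Dead": (8, 23, "Store"),
    },
    "B": {
        "OverSleeping": (16, 23, "Bedroom"),
        "LessSleeping": (8, 16, "Kitchen"),
        "NotBackHome": (8, 23, OUTSIDE),
        "Dead": (8, 23, "Store"),
    },
}


def default_anomaly(kind: str, profile_name: str, day: date) -> AnomalySpec:
    start_h, end_h, room = DEFAULT_ANOMALIES[profile_name.upper()][kind]
    return AnomalySpec(kind=kind, day=day, start_hour=start_h, end_hour=end_h, room_override=room)


def inject(
    stream: Sequence[Observation],
    anomaly: AnomalySpec,
    layout: HomeLayout | None = None,
    seed: int = 0,
    margin_minutes: float = 15.0,
) -> tuple[list[Observation], dict]:
    """Replace the stream's events inside the anomaly window.

    Baseline events are also removed over a short margin *before* the window
    (default 15 min): segment boundaries jitter, so without the margin a
    departing walk a few minutes before the window would contradict the
    injected behaviour (e.g. the person leaving bed just before a prolonged
    sleep).  Returns the modified stream plus the ground-truth record (kind,
    window, room) used for scoring.  The anomaly day must lie within the
    stream.
    """
    layout = layout or default_layout()
    if not stream:
        raise ValueError("cannot inject into an empty stream")
    lo, hi = stream[0].ts, stream[-1].ts
    if anomaly.end <= lo or anomaly.start >= hi:
        raise ValueError(f"anomaly window {anomaly.start}..{anomaly.end} outside the stream")
    if anomaly.room_override not in layout.rooms:
        raise ValueError(f"override room {anomaly.room_override!r} not in layout")

    rng = np.random.default_rng(seed)
    sensor = _sensor_for(layout)
    cut = anomaly.start - timedelta(minutes=margin_minutes)
    kept = [o for o in stream if not (cut <= o.ts < anomaly.end)]

    injected: list[tuple[datetime, str]] = [(anomaly.start, anomaly.room_override)]
    if anomaly.kind == "OverSleeping":
        t = anomaly.start + timedelta(minutes=float(rng.exponential(30.0)))
        while t < anomaly.end:
            injected.append((t, anomaly.room_override))
            t += timedelta(minutes=float(rng.exponential(30.0)))
    elif anomaly.kind == "LessSleeping":
        if anomaly.room_override != OUTSIDE:  # outside: exit event then silence
            t = anomaly.start + timedelta(minutes=float(rng.exponential(5.0)))
            while t < anomaly.end:
                injected.append((t, anomaly.room_override))
                t += timedelta(minutes=float(rng.exponential(5.0)))
    elif anomaly.kind == "NotBackHome":
        pass  # exit observation then silence for the whole window
    elif anomaly.kind == "Dead":
        # a couple of triggers while collapsing, then total silence
        t = anomaly.start + timedelta(minutes=float(rng.exponential(1.0)))
        while t < anomaly.start + timedelta(minutes=3):
            injected.append((t, anomaly.room_override))
            t += timedelta(minutes=float(rng.exponential(1.0)))

    merged = kept + [Observation(ts=t, sensor_id=sensor[room]) for t, room in injected]
    merged.sort(key=lambda o: o.ts)
    truth = {
        "kind": anomaly.kind,
        "start": anomaly.start.isoformat(),
        "end": anomaly.end.isoformat(),
        "room": anomaly.room_override,
    }
    return merged, truth


def inject_all(
    stream: Sequence[Observation],
    anomalies: Sequence[AnomalySpec],
    layout: HomeLayout | None = None,
    seed: int = 0,
) -> tuple[list[Observation], list[dict]]:
    """Inject several anomalies; overlapping windows are an error."""
    windows = sorted((a.start, a.end) for a in anomalies)
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValueError("overlapping anomaly injections")
    out = list(stream)
    truths = []
    for i, anomaly in enumerate(anomalies):
        out, truth = inject(out, anomaly, layout=layout, seed=seed + i)
        truths.append(truth)
    return out, truths
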