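"""File formats: event-log CSV, CASAS text logs, chains, models, config.

Event logs are two-column CSV (``timestamp,sensor_id``, ISO-8601 stamps).
CASAS logs are whitespace-separated text (``date time sensor value ...``); we
keep motion sensors only (ids starting with ``M``) and only their ``ON``
transitions — a PIR reports movement, the OFF edge carries no extra
information.  Detection chains are CSV with one row per sample.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .classification import AnomalyReport
from .detection import DetectionConfig, DetectionSample, State
from .events import Observation, StreamStats
from .learning import BehaviourModel

logger = logging.getLogger("bms")


# -- event logs ---------------------------------------------------------------


def write_events_csv(path: str | Path, observations: Sequence[Observation]) -> None:
    frame = pd.DataFrame(
        {
            "timestamp": [o.ts.isoformat() for o in observations],
            "sensor_id": [o.sensor_id for o in observations],
        }
    )
    frame.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[Observation]:
    frame = pd.read_csv(path)
    return [
        Observation(ts=datetime.fromisoformat(str(row.timestamp)), sensor_id=str(row.sensor_id))
        for row in frame.itertuples()
    ]


def read_casas(
    path: str | Path,
    sensor_map: dict[str, str],
    stats: StreamStats | None = None,
) -> list[Observation]:
    """Read a CASAS-format log keeping mapped PIR motion-ON records only.

    Lines look like ``2010-11-04 08:27:59.1 M003 ON [activity]``.  Sensors
    whose id does not start with ``M`` (doors, temperature, ...) are ignored;
    motion sensors missing from ``sensor_map`` are skipped with a warning;
    malformed lines are counted and skipped.  Output is sorted by timestamp.
    """
    stats = stats if stats is not None else StreamStats()
    observations: list[Observation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                stats.malformed += 1
                logger.warning("%s:%d: malformed line skipped", path, lineno)
                continue
            day, clock, sensor, value = parts[:4]
            if not sensor.startswith("M") or value.upper() != "ON":
                continue
            if sensor not in sensor_map:
                stats.unknown_sensor += 1
                logger.warning("%s:%d: unmapped motion sensor %r skipped", path, lineno, sensor)
                continue
            try:
                ts = datetime.fromisoformat(f"{day} {clock}")
            except ValueError:
                stats.malformed += 1
                logger.warning("%s:%d: bad timestamp skipped", path, lineno)
                continue
            observations.append(Observation(ts=ts, sensor_id=sensor))
    observations.sort(key=lambda o: o.ts)
    return observations


def infer_outside_gaps(
    observations: Sequence[Observation],
    gap_minutes: float = 120.0,
    sensor_id: str = "virtual_outside",
) -> list[Observation]:
    """Insert virtual Outside exits into long silences of a PIR-only log.

    PIR sensors cannot see the person leave the house; a silence longer than
    ``gap_minutes`` is read as an absence, and a virtual Outside observation
    is inserted one minute after the last trigger (the next real trigger is
    the return).  The caller's layout must map ``sensor_id`` to the Outside
    room.  Heuristic: long naps in un-sensed spots look identical to
    absences.
    """
    out: list[Observation] = []
    for current, nxt in zip(observations, list(observations[1:]) + [None]):
        out.append(current)
        if nxt is not None and (nxt.ts - current.ts).total_seconds() > gap_minutes * 60:
            out.append(Observation(ts=current.ts + timedelta(minutes=1), sensor_id=sensor_id))
    return out


# -- detection chains ---------------------------------------------------------

CHAIN_COLUMNS = ["timestamp", "detected_room", "l", "g", "h", "automaton_state", "label"]


def chain_frame(
    samples: Sequence[DetectionSample],
    reports: Sequence[AnomalyReport] | None = None,
) -> pd.DataFrame:
    """One row per detection sample; classifier labels optional."""
    labels = [r.label.value for r in reports] if reports is not None else [""] * len(samples)
    return pd.DataFrame(
        {
            "timestamp": [s.ts for s in samples],
            "detected_room": [s.room for s in samples],
            "l": [s.l for s in samples],
            "g": [s.g for s in samples],
            "h": [s.h for s in samples],
            "automaton_state": [s.state.value for s in samples],
            "label": labels,
        }
    )


def write_chain_csv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_chain_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


# -- models and configuration -------------------------------------------------


def save_model(path: str | Path, model: BehaviourModel) -> None:
    Path(path).write_text(model.to_json())


def load_model(path: str | Path) -> BehaviourModel:
    return BehaviourModel.from_json(Path(path).read_text())


#: Run-configuration keys and their defaults (the study settings).
DEFAULT_CONFIG = {
    "learning_window_weeks": 4,
    "learning_window_shift_weeks": 1,
    "delta_t_minutes": 60,
    "detection_sampling_minutes": 1,
    "estimator_smoothing_minutes": 10,
    "classifier_threshold": 0.25,
    "normal_timeout_minutes": 5,
    "abnormal_timeout_minutes": 10,
    "latch_abnormal": False,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge defaults <- YAML file <- keyword overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def detection_config(config: dict) -> DetectionConfig:
    return DetectionConfig(
        sampling_minutes=config["detection_sampling_minutes"],
        smoothing_minutes=config["estimator_smoothing_minutes"],
        threshold=config["classifier_threshold"],
        n1_minutes=config["normal_timeout_minutes"],
        n2_minutes=config["abnormal_timeout_minutes"],
        latch_abnormal=config["latch_abnormal"],
    )
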