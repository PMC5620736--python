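"""Evaluation metrics and end-to-end experiment orchestration.

Metrics, all computed from a detection chain (one row per sampling period)
against a ground-truth anomaly window, at three levels of the pipeline:

* ``estimator`` — the binary abnormality samples ``h_n``;
* ``automaton`` — the confirmation state ``Z_n`` (abnormal when not Normal);
* ``classifier`` — the rule-based label (abnormal when it names the injected
  behaviour, for delay/confirmation, or is any non-Normal label, for false
  positives).

ADD (anomaly detection delay) is the time from anomaly onset to the first
sample flagging it; ACT (anomaly confirmation time) is the total flagged time
inside the anomaly window; FP is the average number of alert episodes per
anomaly-free week (an episode is a maximal flagged run, or an entry into the
Abnormal state at the automaton level); classification accuracy is the
fraction of in-window samples carrying the injected label.  Runs where a
level never flags the anomaly are excluded from ADD/ACT averages and
reported as misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Sequence

import pandas as pd

from .classification import classify_chain
from .detection import DetectionConfig, run_detection
from .events import HomeLayout, default_layout
from .learning import BehaviourModel, LearningWindow, TimeGrid
from .simulate import AnomalySpec, default_anomaly, get_profile, generate, inject

LEVELS = ("estimator", "automaton", "classifier")


@dataclass
class EvaluationResult:
    """Aggregated metrics for one pipeline level."""

    level: str
    add_minutes: float | None = None
    act_hours: float | None = None
    fp_weekly: float | None = None
    accuracy: float | None = None
    misses: int = 0

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


def _truth_window(truth: dict) -> tuple[datetime, datetime, str]:
    return (
        datetime.fromisoformat(truth["start"]),
        datetime.fromisoformat(truth["end"]),
        truth["kind"],
    )


def _flags(chain: pd.DataFrame, level: str, kind: str | None = None) -> pd.Series:
    """Boolean per-sample abnormality at the requested pipeline level."""
    if level == "estimator":
        return chain["h"].astype(int) == 1
    if level == "automaton":
        return chain["automaton_state"] != "Normal"
    if level == "classifier":
        if kind is not None:
            return chain["label"] == kind
        return ~chain["label"].isin(["Normal", ""])
    raise ValueError(f"unknown level {level!r}")


def anomaly_detection_delay(truth: dict, chain: pd.DataFrame, level: str) -> float | None:
    """Minutes from anomaly onset to the first flagged sample, None if missed."""
    start, end, kind = _truth_window(truth)
    window = chain[(chain["timestamp"] >= start) & (chain["timestamp"] <= end)]
    flagged = window[_flags(window, level, kind)]
    if flagged.empty:
        return None
    first = flagged["timestamp"].iloc[0]
    return (first - start).total_seconds() / 60.0


def anomaly_confirmation_time(
    truth: dict, chain: pd.DataFrame, level: str, sampling_minutes: float = 1.0
) -> float:
    """Hours of flagged time inside the anomaly window."""
    start, end, kind = _truth_window(truth)
    window = chain[(chain["timestamp"] > start) & (chain["timestamp"] <= end)]
    return float(_flags(window, level, kind).sum()) * sampling_minutes / 60.0


def count_alert_episodes(chain: pd.DataFrame, level: str) -> int:
    """Alert episodes: maximal flagged runs (automaton: entries into Abnormal)."""
    if level == "automaton":
        abnormal = (chain["automaton_state"] == "Abnormal").to_numpy()
        if len(abnormal) == 0:
            return 0
        entries = int(abnormal[0]) + int((abnormal[1:] & ~abnormal[:-1]).sum())
        return entries
    flags = _flags(chain, level).to_numpy()
    if len(flags) == 0:
        return 0
    return int(flags[0]) + int((flags[1:] & ~flags[:-1]).sum())


def weekly_false_positives(chains: Sequence[pd.DataFrame], level: str) -> float:
    """Average alert episodes per chain, each chain covering one clean week."""
    if not chains:
        return 0.0
    return sum(count_alert_episodes(c, level) for c in chains) / len(chains)


def classification_accuracy(truth: dict, chain: pd.DataFrame) -> float:
    """Fraction of in-window samples labelled with the injected kind."""
    start, end, kind = _truth_window(truth)
    window = chain[(chain["timestamp"] > start) & (chain["timestamp"] <= end)]
    if window.empty:
        return 0.0
    return float((window["label"] == kind).mean())


# -- experiment orchestration --------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a simulate -> learn -> detect -> score run."""

    profile: str = "A"
    seed: int = 0
    train_weeks: int = 4
    shift_weeks: int = 1
    detection: DetectionConfig = DetectionConfig()
    delta_t: int = 60
    start: datetime = datetime(2024, 1, 1)


def _pipeline_chain(
    observations,
    model,
    layout: HomeLayout,
    cfg: DetectionConfig,
    start: datetime,
    end: datetime,
) -> pd.DataFrame:
    from .io import chain_frame  # local import to avoid a cycle

    samples = run_detection(observations, model, layout, cfg, start=start, end=end)
    reports = classify_chain(samples, model, layout)
    return chain_frame(samples, reports)


def anomaly_run(
    kind: str,
    config: ExperimentConfig,
    layout: HomeLayout | None = None,
) -> dict:
    """One full injected-anomaly experiment.

    Six weeks are simulated; the model is learned on weeks 2-5 and the
    anomaly is injected on the Wednesday of week 6.  Detection runs from six
    hours before the anomaly day until two hours into the next day, so the
    smoothing filter and automaton are fully warmed up at onset.

    Returns the ground truth, the detection chain and per-level ADD, plus
    classifier ACT and accuracy.
    """
    layout = layout or default_layout()
    profile = get_profile(config.profile)
    stream = generate(profile, layout, start=config.start, weeks=6, seed=config.seed)

    window_start = config.start + timedelta(weeks=1)
    window = LearningWindow(
        layout=layout,
        grid=TimeGrid(config.delta_t),
        length_weeks=config.train_weeks,
        shift_weeks=config.shift_weeks,
    )
    model = window.initialise(stream, start=window_start)

    anomaly_day = (config.start + timedelta(weeks=5, days=2)).date()
    spec = default_anomaly(kind, config.profile, anomaly_day)
    stream, truth = inject(stream, spec, layout=layout, seed=config.seed)

    day0 = datetime.combine(anomaly_day, datetime.min.time())
    chain = _pipeline_chain(
        stream,
        model,
        layout,
        config.detection,
        start=day0 - timedelta(hours=6),
        end=day0 + timedelta(hours=26),
    )
    result = {
        "truth": truth,
        "chain": chain,
        "add": {
            level: anomaly_detection_delay(truth, chain, level) for level in LEVELS
        },
        "act_hours": anomaly_confirmation_time(
            truth, chain, "classifier", config.detection.sampling_minutes
        ),
        "accuracy": classification_accuracy(truth, chain),
    }
    return result


def false_positive_run(
    config: ExperimentConfig,
    detect_weeks: int = 4,
    layout: HomeLayout | None = None,
) -> dict:
    """Anomaly-free run: weekly-updated models scoring the following week.

    Simulates ``train_weeks + detect_weeks`` clean weeks.  The model is
    learned on the first ``train_weeks`` weeks and scores week
    ``train_weeks``; the window then shifts weekly, always scoring the week
    after its end — exactly the online regime of a deployed system.
    """
    layout = layout or default_layout()
    profile = get_profile(config.profile)
    total = config.train_weeks + detect_weeks
    stream = generate(profile, layout, start=config.start, weeks=total, seed=config.seed)

    window = LearningWindow(
        layout=layout,
        grid=TimeGrid(config.delta_t),
        length_weeks=config.train_weeks,
        shift_weeks=config.shift_weeks,
    )
    model = window.initialise(stream, start=config.start)

    chains: list[pd.DataFrame] = []
    for w in range(detect_weeks):
        week_start = config.start + timedelta(weeks=config.train_weeks + w)
        week_end = week_start + timedelta(weeks=1)
        chains.append(
            _pipeline_chain(stream, model, layout, config.detection, week_start, week_end)
        )
        if w + 1 < detect_weeks:
            new_obs = [o for o in stream if week_start <= o.ts < week_end]
            model = window.update(new_obs)

    return {
        "chains": chains,
        "fp_weekly": {level: weekly_false_positives(chains, level) for level in LEVELS},
    }


def run_experiment(
    kind: str,
    profile: str,
    seeds: Sequence[int],
    detection: DetectionConfig | None = None,
    fp_detect_weeks: int = 4,
    include_fp: bool = True,
) -> dict[str, EvaluationResult]:
    """Aggregate injected-anomaly and clean-week runs over several seeds.

    Returns one :class:`EvaluationResult` per pipeline level, with ADD/ACT
    averaged over the seeds whose run detected the anomaly (misses counted
    separately) and FP averaged over all clean weeks.
    """
    detection = detection or DetectionConfig()
    adds: dict[str, list[float]] = {level: [] for level in LEVELS}
    misses = {level: 0 for level in LEVELS}
    acts: list[float] = []
    accuracies: list[float] = []
    fps: dict[str, list[float]] = {level: [] for level in LEVELS}

    for seed in seeds:
        cfg = ExperimentConfig(profile=profile, seed=seed, detection=detection)
        run = anomaly_run(kind, cfg)
        for level in LEVELS:
            if run["add"][level] is None:
                misses[level] += 1
            else:
                adds[level].append(run["add"][level])
        acts.append(run["act_hours"])
        accuracies.append(run["accuracy"])
        if include_fp:
            fp = false_positive_run(cfg, detect_weeks=fp_detect_weeks)
            for level in LEVELS:
                fps[level].append(fp["fp_weekly"][level])

    def mean(values: Sequence[float]) -> float | None:
        return sum(values) / len(values) if values else None

    results = {}
    for level in LEVELS:
        results[level] = EvaluationResult(
            level=level,
            add_minutes=mean(adds[level]),
            act_hours=mean(acts) if level == "classifier" else None,
            fp_weekly=mean(fps[level]) if include_fp else None,
            accuracy=mean(accuracies) if level == "classifier" else None,
            misses=misses[level],
        )
    return results
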