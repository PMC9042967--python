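"""Continuous expertise scoring: per-0.2 s scores and their aggregates.

Scores are deliberately unclipped — values above +1 or below -1 are allowed
and meaningful (more than one training-set standard deviation beyond the
expert or novice anchor).  A trial's task average is the arithmetic mean of
its per-timestep scores; a participant's score is the unweighted mean of
task averages over available trials, with no imputation for missing trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FeatureOrderError, NoTrialsError
from .metrics import MetricSeries, apply_normalization
from .model import ExpertiseResults

__all__ = [
    "ScoreSeries",
    "ParticipantScore",
    "score_trial",
    "participant_average",
    "timeline_export",
    "flag_intervals",
]

WINDOW_S = 0.2


@dataclass
class ScoreSeries:
    """Per-0.2 s expertise scores for one trial."""

    time: np.ndarray
    score: np.ndarray
    task_average: float
    participant_id: str = "p00"
    trial_index: int = 0
    group_label: str | None = None
    skill: float | None = None

    def __len__(self) -> int:
        return self.score.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "score": self.score})


@dataclass
class ParticipantScore:
    participant_id: str
    task_averages: list[float]
    participant_average: float
    n_trials_used: int
    group_label: str | None = None
    skill: float | None = None


def score_trial(model: ExpertiseResults, trial: MetricSeries) -> ScoreSeries:
    """Score an un-normalized trial with the model's stored statistics."""
    if trial.names != tuple(model.manifest_names):
        raise FeatureOrderError(
            "trial metric manifest does not match the model's manifest:\n"
            f"  trial: {trial.names}\n  model: {tuple(model.manifest_names)}"
        )
    normalized = apply_normalization(trial, model.stats)
    scores = model.predict_normalized(normalized.values)
    return ScoreSeries(
        time=trial.time.copy(),
        score=scores,
        task_average=float(np.mean(scores)),
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        group_label=trial.group_label,
        skill=trial.skill,
    )


def participant_average(series: list[ScoreSeries]) -> ParticipantScore:
    """Unweighted mean of task averages over the trials that exist."""
    if not series:
        raise NoTrialsError("cannot average over zero trials")
    pid = series[0].participant_id
    for s in series:
        if s.participant_id != pid:
            raise NoTrialsError(
                f"mixed participants in one average: {pid!r} vs {s.participant_id!r}"
            )
    avgs = [float(s.task_average) for s in series]
    return ParticipantScore(
        participant_id=pid,
        task_averages=avgs,
        participant_average=float(np.mean(avgs)),
        n_trials_used=len(avgs),
        group_label=series[0].group_label,
        skill=series[0].skill,
    )


def flag_intervals(time: np.ndarray, below: np.ndarray) -> list[tuple[float, float]]:
    """Maximal contiguous runs of True, as half-open (start_s, end_s) pairs.

    Each flagged timestep covers [t, t + 0.2); adjacent flagged steps merge.
    """
    out: list[tuple[float, float]] = []
    start = None
    for k, flag in enumerate(below):
        if flag and start is None:
            start = float(time[k])
        elif not flag and start is not None:
            out.append((start, float(time[k])))
            start = None
    if start is not None:
        out.append((start, float(time[-1]) + WINDOW_S))
    return out


def timeline_export(series: ScoreSeries, threshold: float = 0.0
                    ) -> list[tuple[float, float]]:
    """Time frames of less-skilled performance: score strictly below threshold."""
    return flag_intervals(series.time, series.score < threshold)
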