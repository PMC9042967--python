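"""Inverse models for coaching and risk detection.

Five models share one mechanism: a sequence-to-sequence LSTM (same layer
stack and node rule as the assessment model) predicts one target metric per
0.2 s step from the other 15 metrics plus a single expertise-level input
channel.

* Coaching mode — targets aspirator force, bipolar force, and inter-tip
  separation.  The expertise channel is forced to the expert code ``1``
  at every timestep regardless of who performed the trial, so the output is
  the expert-level trajectory of that metric given the rest of the
  performance: a continuously revised target the trainee can steer toward.
* Risk mode — targets bleeding (blood volume present) and healthy-tissue
  damage.  The expertise channel is set to the performer's own level code
  (expert 1, senior 0.33, junior -0.33, novice/medical student -1),
  predicting the hazard trajectory expected at that level.

Targets are learned and predicted in z-score space and de-normalized with
the training-set statistics before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    FeatureOrderError,
    InvalidArgumentError,
    InvalidLevelError,
)
from .metrics import MetricSeries, NormalizationStats, apply_normalization, fit_normalization
from .model import Split, minibatch_size, split_by_participant
from .nn import LSTMRegressor, TrainingSchedule

__all__ = [
    "EXPERTISE_LEVELS",
    "COACHING_TARGETS",
    "RISK_TARGETS",
    "FEEDBACK_ROSTER",
    "FeedbackSeries",
    "FeedbackModel",
    "FeedbackResults",
    "train_feedback_model",
    "coach",
    "assess_risk",
    "risk_warnings",
    "expertise_code",
]

#: Closed four-level vocabulary for the expertise input channel.
EXPERTISE_LEVELS: dict[str, float] = {
    "expert": 1.0,
    "senior": 0.33,
    "junior": -0.33,
    "novice": -1.0,
    "medical student": -1.0,  # alias used interchangeably with novice
}

COACHING_TARGETS: tuple[str, ...] = (
    "aspirator_force",
    "bipolar_force",
    "tip_separation",
)
RISK_TARGETS: tuple[str, ...] = ("blood_volume", "healthy_tissue_damage")

#: The five-model roster: target metric -> mode.
FEEDBACK_ROSTER: dict[str, str] = {
    **{t: "coaching" for t in COACHING_TARGETS},
    **{t: "risk" for t in RISK_TARGETS},
}


def expertise_code(level) -> float:
    """Map a level label (or an exact level code) onto the closed code set."""
    if isinstance(level, str):
        try:
            return EXPERTISE_LEVELS[level]
        except KeyError:
            raise InvalidLevelError(
                f"unknown expertise level {level!r}; admitted: "
                f"{sorted(set(EXPERTISE_LEVELS))}"
            ) from None
    code = float(level)
    if code not in set(EXPERTISE_LEVELS.values()):
        raise InvalidLevelError(
            f"expertise code must be one of {{1, 0.33, -0.33, -1}}, got {code}"
        )
    return code


@dataclass
class FeedbackSeries:
    """Predicted target-metric trajectory for one trial, original units."""

    time: np.ndarray
    value: np.ndarray
    target_metric: str
    mode: str  # "coaching" | "risk"
    level_code: float
    participant_id: str = "p00"
    trial_index: int = 0

    def __len__(self) -> int:
        return self.value.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, self.target_metric: self.value})


@dataclass
class FeedbackResults:
    """A fitted inverse model plus its normalization and manifest context."""

    target_metric: str
    mode: str
    regressor: LSTMRegressor
    stats: NormalizationStats
    manifest_names: tuple[str, ...]
    schedule: TrainingSchedule
    seed: int
    rmse_history: dict[str, list[float]]
    test_rmse: float

    @property
    def input_names(self) -> tuple[str, ...]:
        """15 non-target metrics, in manifest order, plus the expertise channel."""
        return tuple(n for n in self.manifest_names if n != self.target_metric) + (
            "expertise_level",
        )

    def prepare_inputs(self, trial: MetricSeries, level_code: float) -> np.ndarray:
        """Build the (T, 16) input matrix the network actually sees.

        Exposed so callers (and tests) can verify the expertise channel:
        its value occupies the last column at every timestep.
        """
        if trial.names != tuple(self.manifest_names):
            raise FeatureOrderError(
                "trial manifest does not match the feedback model's manifest"
            )
        normalized = apply_normalization(trial, self.stats)
        keep = [j for j, n in enumerate(trial.names) if n != self.target_metric]
        X = np.column_stack(
            [normalized.values[:, keep], np.full(len(trial), level_code)]
        )
        return X

    def _predict(self, trial: MetricSeries, level_code: float) -> np.ndarray:
        X = self.prepare_inputs(trial, level_code)
        pred_z = self.regressor.predict(X)
        j = tuple(self.manifest_names).index(self.target_metric)
        return pred_z * self.stats.sd[j] + self.stats.mean[j]

    def coach(self, trial: MetricSeries) -> FeedbackSeries:
        """Expert-level target trajectory: expertise channel forced to 1."""
        if self.mode != "coaching":
            raise InvalidArgumentError(
                f"{self.target_metric!r} is a {self.mode} model, not coaching"
            )
        value = self._predict(trial, EXPERTISE_LEVELS["expert"])
        return FeedbackSeries(
            time=trial.time.copy(),
            value=value,
            target_metric=self.target_metric,
            mode="coaching",
            level_code=EXPERTISE_LEVELS["expert"],
            participant_id=trial.participant_id,
            trial_index=trial.trial_index,
        )

    def assess_risk(self, trial: MetricSeries, level) -> FeedbackSeries:
        """Hazard trajectory at the performer's own expertise level."""
        if self.mode != "risk":
            raise InvalidArgumentError(
                f"{self.target_metric!r} is a {self.mode} model, not risk"
            )
        code = expertise_code(level)
        value = self._predict(trial, code)
        return FeedbackSeries(
            time=trial.time.copy(),
            value=value,
            target_metric=self.target_metric,
            mode="risk",
            level_code=code,
            participant_id=trial.participant_id,
            trial_index=trial.trial_index,
        )

    def summary(self) -> str:
        return "\n".join([
            f"Inverse model for {self.target_metric!r} ({self.mode} mode)",
            f"inputs: {len(self.input_names)} (15 metrics + expertise channel), "
            f"lstm units: {self.regressor.hidden_units}",
            f"final train RMSE (z-units): {self.rmse_history['train'][-1]:.4f}",
            f"test RMSE (z-units): {self.test_rmse:.4f}",
        ])


class FeedbackModel:
    """Inverse-model builder for one target metric.

    Trained on the same expert/novice development cohort as the assessment
    model: inputs are the 15 remaining (z-scored) metrics plus the trial
    performer's expertise code; the target is the held-out metric in z-score
    space.
    """

    def __init__(self, target_metric: str, trials: list[MetricSeries],
                 split: Split | None = None, dropout_rate: float = 0.2):
        if target_metric not in FEEDBACK_ROSTER:
            raise FeatureOrderError(
                f"no inverse model is defined for {target_metric!r}; "
                f"roster: {sorted(FEEDBACK_ROSTER)}"
            )
        if not trials:
            raise InvalidArgumentError("no trials supplied")
        names = trials[0].names
        if target_metric not in names:
            raise FeatureOrderError(f"{target_metric!r} missing from trial manifest")
        for tr in trials:
            if tr.names != names:
                raise FeatureOrderError("trials carry inconsistent metric manifests")
        self.target_metric = target_metric
        self.mode = FEEDBACK_ROSTER[target_metric]
        self.trials = trials
        self.split = split
        self.dropout_rate = dropout_rate
        self.manifest_names = names

    def fit(self, epochs: int = 1000, seed: int = 0,
            schedule: TrainingSchedule | None = None,
            repeats_per_person: int = 6) -> FeedbackResults:
        split = self.split or split_by_participant(self.trials, seed=seed)
        parts = split.partition(self.trials)
        stats = fit_normalization(parts["train"])
        n_inputs = len(self.manifest_names)  # 15 metrics + expertise channel
        keep = [j for j, n in enumerate(self.manifest_names)
                if n != self.target_metric]
        j_target = self.manifest_names.index(self.target_metric)

        def pairs(subset):
            out = []
            for tr in subset:
                code = expertise_code(tr.group_label)
                z = apply_normalization(tr, stats).values
                X = np.column_stack([z[:, keep], np.full(len(tr), code)])
                out.append((X, z[:, j_target]))
            return out

        train_pairs = pairs(parts["train"])
        val_pairs = pairs(parts["validation"])
        test_pairs = pairs(parts["test"])
        if schedule is None:
            schedule = TrainingSchedule(
                epochs=epochs,
                minibatch_size=minibatch_size(len(train_pairs), repeats_per_person),
                seed=seed,
            )
        regressor = LSTMRegressor(n_inputs, n_inputs + 1, self.dropout_rate, seed=seed)
        history = regressor.fit_sequences(train_pairs, schedule, validation=val_pairs)
        test_rmse = regressor.evaluate(test_pairs) if test_pairs else float("nan")
        return FeedbackResults(
            target_metric=self.target_metric,
            mode=self.mode,
            regressor=regressor,
            stats=stats,
            manifest_names=self.manifest_names,
            schedule=schedule,
            seed=seed,
            rmse_history=history,
            test_rmse=test_rmse,
        )


def train_feedback_model(target_metric: str, trials: list[MetricSeries],
                         schedule: TrainingSchedule | None = None,
                         split: Split | None = None, seed: int = 0
                         ) -> FeedbackResults:
    """Functional wrapper over :class:`FeedbackModel`."""
    return FeedbackModel(target_metric, trials, split=split).fit(
        seed=seed, schedule=schedule
    )


def coach(model: FeedbackResults, trial: MetricSeries) -> FeedbackSeries:
    return model.coach(trial)


def assess_risk(model: FeedbackResults, trial: MetricSeries, level) -> FeedbackSeries:
    return model.assess_risk(trial, level)


def risk_warnings(model: FeedbackResults, trial: MetricSeries, level,
                  factor: float = 2.0) -> list[tuple[float, float]]:
    """Intervals where the predicted hazard at the user's level exceeds the
    expert-level prediction by ``factor`` (or is positive where the expert
    prediction is not)."""
    from .scoring import flag_intervals

    user = model.assess_risk(trial, level).value
    expert = model.assess_risk(trial, "expert").value
    warn = np.where(expert > 0, user > factor * expert, user > 0)
    return flag_intervals(trial.time, warn)
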