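"""Expertise assessment model: participant-grouped splitting, the two-layer
LSTM regression network, and its training loop.

The model regresses a continuous expertise score against the 16-metric
sequence of a trial, trained sequence-to-sequence on two-end labels: every
timestep of an expert trial carries target +1 and of a novice trial -1.
Hidden width follows the fixed rule "number of input metrics plus one".
Because the targets are z-score-anchored (+1/-1 = one training-set standard
deviation above/below the mean performance), scores of unseen performers fall
on — and may exceed — the expert-novice continuum.

Usage follows the Model/Results convention::

    model = ExpertiseModel.from_cohort(metric_trials)       # labels from groups
    results = model.fit(epochs=100, seed=0)
    results.summary()
    scores = results.score(held_out_trial)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CannotSplitError,
    FeatureOrderError,
    InvalidArgumentError,
    InvalidSpecError,
)
from .metrics import (
    MetricSeries,
    NormalizationStats,
    apply_normalization,
    fit_normalization,
)
from .nn import LSTMRegressor, TrainingSchedule, learning_rate_at, rmse

__all__ = [
    "Split",
    "ModelSpec",
    "TrainingSchedule",
    "split_by_participant",
    "build_model",
    "minibatch_size",
    "labels_for",
    "train",
    "rmse",
    "learning_rate_at",
    "ExpertiseModel",
    "ExpertiseResults",
]

SUBSETS = ("train", "validation", "test")

#: two-end label encoding used at training time
GROUP_LABELS = {"expert": 1.0, "novice": -1.0}


@dataclass(frozen=True)
class Split:
    """Participant-grouped train/validation/test partition."""

    assignment: dict[str, str]  # participant_id -> subset

    def subset_of(self, participant_id: str) -> str:
        return self.assignment[participant_id]

    def partition(self, trials: list[MetricSeries]) -> dict[str, list[MetricSeries]]:
        out: dict[str, list[MetricSeries]] = {s: [] for s in SUBSETS}
        for tr in trials:
            out[self.assignment[tr.participant_id]].append(tr)
        return out


def split_by_participant(
    trials: list[MetricSeries],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> Split:
    """Randomly assign whole participants to subsets, targeting trial-count
    fractions by greedy closest-to-target assignment over shuffled participants.

    Every trial of a participant lands in exactly one subset.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise InvalidArgumentError(f"fractions must sum to 1, got {fractions}")
    counts: dict[str, int] = {}
    for tr in trials:
        counts[tr.participant_id] = counts.get(tr.participant_id, 0) + 1
    pids = sorted(counts)
    if len(pids) < 3:
        raise CannotSplitError(
            f"need at least 3 participants to form 3 subsets, got {len(pids)}"
        )
    total = sum(counts.values())
    targets = {s: f * total for s, f in zip(SUBSETS, fractions)}
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(pids))
    assigned: dict[str, str] = {}
    current = {s: 0 for s in SUBSETS}
    for pid in order:
        deficits = {s: targets[s] - current[s] for s in SUBSETS}
        best = max(SUBSETS, key=lambda s: deficits[s])  # ties break train>val>test
        assigned[pid] = best
        current[best] += counts[pid]
    return Split(assignment=assigned)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture descriptor: sequence input -> LSTM -> dropout -> LSTM ->
    dropout -> fully-connected(1) -> MSE regression."""

    n_features: int
    lstm_units: int
    dropout_rate: float = 0.2
    layers: tuple[str, ...] = (
        "sequence_input",
        "lstm",
        "dropout",
        "lstm",
        "dropout",
        "fully_connected(1)",
        "regression(mse)",
    )

    def validate(self) -> None:
        if self.n_features < 1:
            raise InvalidSpecError("n_features must be >= 1")
        if self.lstm_units != self.n_features + 1:
            raise InvalidSpecError(
                f"lstm_units must equal n_features + 1, got {self.lstm_units}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidSpecError("dropout_rate must lie in [0, 1)")


def build_model(n_features: int, dropout_rate: float = 0.2) -> ModelSpec:
    """Fixed layer stack with the node-count rule: units = n_features + 1."""
    if n_features < 1:
        raise InvalidSpecError(f"n_features must be >= 1, got {n_features}")
    spec = ModelSpec(n_features=n_features, lstm_units=n_features + 1,
                     dropout_rate=dropout_rate)
    spec.validate()
    return spec


def minibatch_size(n_training_trials: int, repeats_per_person: int) -> int:
    """Training-trial count divided by repeats per person, floored, minimum 1."""
    if n_training_trials < 1 or repeats_per_person < 1:
        raise InvalidArgumentError("both arguments must be positive integers")
    return max(1, n_training_trials // repeats_per_person)


def labels_for(trial: MetricSeries) -> np.ndarray:
    """Constant per-timestep target: +1 for expert trials, -1 for novice."""
    if trial.group_label not in GROUP_LABELS:
        raise InvalidArgumentError(
            f"trial group {trial.group_label!r} has no two-end training label; "
            "training uses expert/novice trials only"
        )
    return np.full(len(trial), GROUP_LABELS[trial.group_label])


@dataclass
class ExpertiseResults:
    """A fitted expertise model: weights plus everything needed to score.

    The normalization statistics and the feature manifest travel with the
    weights; scoring a trial whose manifest does not match is refused.
    """

    spec: ModelSpec
    schedule: TrainingSchedule
    regressor: LSTMRegressor
    stats: NormalizationStats
    manifest_names: tuple[str, ...]
    split: Split
    seed: int
    rmse_history: dict[str, list[float]]
    test_rmse: float

    def predict_normalized(self, normalized_values: np.ndarray) -> np.ndarray:
        return self.regressor.predict(normalized_values)

    def score(self, trial: MetricSeries):
        from .scoring import score_trial

        return score_trial(self, trial)

    def summary(self) -> str:
        h = self.rmse_history
        lines = [
            "Expertise assessment model (sequence-to-sequence LSTM regression)",
            "=" * 66,
            f"features: {self.spec.n_features}   lstm units: {self.spec.lstm_units}"
            f"   dropout: {self.spec.dropout_rate}",
            f"layers: {' -> '.join(self.spec.layers)}",
            f"epochs: {self.schedule.epochs}   minibatch: {self.schedule.minibatch_size}"
            f"   initial lr: {self.schedule.initial_lr}"
            f" (x{self.schedule.lr_decay_factor} every {self.schedule.lr_decay_every})",
            f"seed: {self.seed}",
            f"final train RMSE:      {h['train'][-1]:.4f}",
            f"final validation RMSE: {h['validation'][-1]:.4f}",
            f"test RMSE:             {self.test_rmse:.4f}",
            "labels: expert = +1, novice = -1 (per 0.2 s timestep; scores unclipped)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "expertise",
            "spec": {
                "n_features": self.spec.n_features,
                "lstm_units": self.spec.lstm_units,
                "dropout_rate": self.spec.dropout_rate,
            },
            "schedule": {
                "initial_lr": self.schedule.initial_lr,
                "lr_decay_factor": self.schedule.lr_decay_factor,
                "lr_decay_every": self.schedule.lr_decay_every,
                "epochs": self.schedule.epochs,
                "minibatch_size": self.schedule.minibatch_size,
                "seed": self.schedule.seed,
            },
            "weights": self.regressor.weights_to_dict(),
            "normalization": self.stats.to_dict(),
            "manifest": list(self.manifest_names),
            "split": dict(self.split.assignment),
            "seed": self.seed,
            "rmse_history": self.rmse_history,
            "test_rmse": self.test_rmse,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExpertiseResults":
        spec = ModelSpec(
            n_features=d["spec"]["n_features"],
            lstm_units=d["spec"]["lstm_units"],
            dropout_rate=d["spec"]["dropout_rate"],
        )
        sched = TrainingSchedule(**d["schedule"])
        reg = LSTMRegressor.from_weights(
            spec.n_features, spec.lstm_units, spec.dropout_rate, d["weights"]
        )
        return cls(
            spec=spec,
            schedule=sched,
            regressor=reg,
            stats=NormalizationStats.from_dict(d["normalization"]),
            manifest_names=tuple(d["manifest"]),
            split=Split(assignment=dict(d["split"])),
            seed=d["seed"],
            rmse_history=d["rmse_history"],
            test_rmse=d["test_rmse"],
        )


class ExpertiseModel:
    """Two-end expertise regression on 16-metric trial sequences.

    Parameters
    ----------
    trials : list of MetricSeries
        Un-normalized metric series, group-labelled ``expert`` or ``novice``.
    split : Split, optional
        Participant-grouped partition; drawn with :func:`split_by_participant`
        under the fit seed when omitted.
    dropout_rate : float
        Dropout after each LSTM layer (training only).
    """

    def __init__(self, trials: list[MetricSeries], split: Split | None = None,
                 dropout_rate: float = 0.2):
        if not trials:
            raise InvalidArgumentError("no trials supplied")
        names = trials[0].names
        for tr in trials:
            if tr.names != names:
                raise FeatureOrderError("trials carry inconsistent metric manifests")
        self.trials = trials
        self.split = split
        self.spec = build_model(len(names), dropout_rate)
        self.manifest_names = names

    @classmethod
    def from_cohort(cls, trials: list[MetricSeries], **kwargs) -> "ExpertiseModel":
        return cls(trials, **kwargs)

    def fit(
        self,
        epochs: int = 1000,
        seed: int = 0,
        schedule: TrainingSchedule | None = None,
        repeats_per_person: int = 6,
    ) -> ExpertiseResults:
        split = self.split or split_by_participant(self.trials, seed=seed)
        parts = split.partition(self.trials)
        if not parts["train"]:
            raise CannotSplitError("split left the training subset empty")
        stats = fit_normalization(parts["train"])

        def pairs(subset: list[MetricSeries]):
            return [
                (apply_normalization(tr, stats).values, labels_for(tr))
                for tr in subset
            ]

        train_pairs = pairs(parts["train"])
        val_pairs = pairs(parts["validation"])
        test_pairs = pairs(parts["test"])

        if schedule is None:
            schedule = TrainingSchedule(
                epochs=epochs,
                minibatch_size=minibatch_size(len(train_pairs), repeats_per_person),
                seed=seed,
            )
        regressor = LSTMRegressor(
            self.spec.n_features,
            self.spec.lstm_units,
            self.spec.dropout_rate,
            seed=seed,
        )
        history = regressor.fit_sequences(train_pairs, schedule, validation=val_pairs)
        test_rmse = regressor.evaluate(test_pairs) if test_pairs else float("nan")
        return ExpertiseResults(
            spec=self.spec,
            schedule=schedule,
            regressor=regressor,
            stats=stats,
            manifest_names=self.manifest_names,
            split=split,
            seed=seed,
            rmse_history=history,
            test_rmse=test_rmse,
        )


def train(
    spec: ModelSpec,
    schedule: TrainingSchedule,
    split: Split,
    trials: list[MetricSeries],
    seed: int | None = None,
) -> ExpertiseResults:
    """Functional wrapper over :class:`ExpertiseModel` for a prepared split."""
    spec.validate()
    model = ExpertiseModel(trials, split=split, dropout_rate=spec.dropout_rate)
    return model.fit(schedule=schedule, seed=schedule.seed if seed is None else seed)
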