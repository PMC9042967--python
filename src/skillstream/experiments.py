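"""End-to-end validation experiments on synthetic cohorts.

The central check of the whole pipeline: train the assessment model on the
two-end development cohort only (experts vs novices), then score performers
the model never saw — a nine-rung skill ladder and a four-group cohort —
and verify that the continuous score recovers the hidden skill ordering.
This is the synthetic analogue of validating a simulator-based skill score
against expertise groups and training seniority.

Problem sizes default to a desk-scale protocol (10+10 development
performers, six 60-120 s trials each, 100 training epochs) chosen to keep a
full five-seed replication within minutes on one CPU while leaving the
sequence statistics representative of full-length trials.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .metrics import extract_metrics, regularize
from .model import ExpertiseModel
from .scoring import participant_average
from .simulate import (
    TrialConfig,
    development_cohort,
    four_group_cohort,
    simulate_cohort,
    skill_ladder_cohort,
)
from .validation import group_comparison, training_year_regression

__all__ = ["expertise_recovery_experiment", "GROUP_ORDER"]

GROUP_ORDER = ("expert", "senior", "junior", "novice")


def _metric_trials(design, config, seed):
    return [extract_metrics(regularize(s))
            for s in simulate_cohort(design, config, seed)]


def _participant_means(results, trials):
    by_pid: dict[str, list] = {}
    for tr in trials:
        sc = results.score(tr)
        by_pid.setdefault(sc.participant_id, []).append(sc)
    return {pid: participant_average(v) for pid, v in by_pid.items()}


def _training_year(group: str, index: int) -> int:
    """Synthetic seniority: juniors in years 1-3, seniors in years 4-7
    (year 7 standing in for fellows)."""
    if group == "junior":
        return 1 + index % 3
    return 4 + index % 4


def expertise_recovery_experiment(
    seed: int,
    n_seeds: int = 5,
    n_per_end: int = 10,
    trials_per_participant: int = 6,
    duration_range: tuple[float, float] = (60.0, 120.0),
    epochs: int = 100,
    ladder_levels: int = 9,
    four_group_sizes: tuple[int, int, int, int] = (6, 6, 6, 6),
) -> dict:
    """Train on the ±1 ends; test skill recovery on held-out skill ladders.

    For each of ``n_seeds`` replicate seeds: simulate a development cohort,
    fit the assessment model, then (a) score a ``ladder_levels``-rung skill
    ladder and record the Spearman rank correlation between true skill and
    mean participant score, and (b) score a four-group cohort and record
    whether the group means order expert > senior > junior > novice.  The
    last replicate also runs the ANOVA and the training-year regression on
    its four-group cohort.
    """
    config = TrialConfig(duration_range_s=duration_range)
    spearmans: list[float] = []
    orderings: list[bool] = []
    last_group_means: dict[str, float] = {}
    anova_report = None
    regression_report = None

    for rep in range(n_seeds):
        rep_seed = (seed + rep) % (2**31 - 1)
        dev = _metric_trials(
            development_cohort(n_per_end, n_per_end, trials_per_participant),
            config, rep_seed,
        )
        results = ExpertiseModel.from_cohort(dev).fit(
            epochs=epochs, seed=rep_seed,
            repeats_per_person=trials_per_participant,
        )

        ladder = _metric_trials(
            skill_ladder_cohort(ladder_levels, trials_per_participant),
            config, rep_seed + 10_000,
        )
        pmeans = _participant_means(results, ladder)
        skills = [p.skill for p in pmeans.values()]
        scores = [p.participant_average for p in pmeans.values()]
        spearmans.append(float(spearmanr(skills, scores).statistic))

        four = _metric_trials(
            four_group_cohort(*four_group_sizes, trials_per_participant),
            config, rep_seed + 20_000,
        )
        pmeans4 = _participant_means(results, four)
        by_group: dict[str, list[float]] = {}
        for p in pmeans4.values():
            by_group.setdefault(p.group_label, []).append(p.participant_average)
        gmeans = {g: float(np.mean(v)) for g, v in by_group.items()}
        orderings.append(
            all(gmeans[a] > gmeans[b] for a, b in zip(GROUP_ORDER, GROUP_ORDER[1:]))
        )

        if rep == n_seeds - 1:
            last_group_means = gmeans
            anova_report = group_comparison(by_group).anova
            trainees = [
                (pid, p) for pid, p in pmeans4.items()
                if p.group_label in ("senior", "junior")
            ]
            years, t_scores = [], []
            for pid, p in sorted(trainees):
                idx = int(pid.split("-")[1])
                years.append(_training_year(p.group_label, idx))
                t_scores.append(p.participant_average)
            regression_report = training_year_regression(t_scores, years).regression

    return {
        "spearman_per_seed": spearmans,
        "spearman_mean": float(np.mean(spearmans)),
        "ordering_per_seed": orderings,
        "ordering_fraction": float(np.mean(orderings)),
        "group_means": last_group_means,
        "anova": anova_report,
        "regression": regression_report,
    }
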