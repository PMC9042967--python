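"""Shared fixtures: small synthetic cohorts and a quickly-fitted model.

Everything is generated at test time from seeds; durations are kept short so
the whole suite stays desk-scale while exercising the same code paths as
full-length trials.
"""

from __future__ import annotations

import numpy as np
import pytest

import skillstream as ss


SHORT_CONFIG = ss.TrialConfig(duration_s=20.0, duration_range_s=(12.0, 20.0))


@pytest.fixture(scope="session")
def short_config() -> ss.TrialConfig:
    return SHORT_CONFIG


@pytest.fixture(scope="session")
def raw_trial() -> ss.RawStream:
    return ss.simulate_trial(SHORT_CONFIG, skill=0.5, seed=42)


@pytest.fixture(scope="session")
def metric_trial(raw_trial) -> ss.MetricSeries:
    return ss.extract_metrics(ss.regularize(raw_trial))


@pytest.fixture(scope="session")
def mini_cohort_trials() -> list[ss.MetricSeries]:
    """4 experts + 4 novices, 3 short trials each (24 trials)."""
    design = ss.development_cohort(n_experts=4, n_novices=4, trials_per_participant=3)
    streams = ss.simulate_cohort(design, SHORT_CONFIG, seed=7)
    return [ss.extract_metrics(ss.regularize(s)) for s in streams]


@pytest.fixture(scope="session")
def fitted_results(mini_cohort_trials) -> ss.ExpertiseResults:
    """A briefly trained assessment model shared across scoring/feedback tests."""
    model = ss.ExpertiseModel.from_cohort(mini_cohort_trials)
    return model.fit(epochs=25, seed=3, repeats_per_person=3)


def random_fixture_stream(seed: int, duration_s: float = 2.0) -> ss.RawStream:
    """A short random stream for oracle-equivalence checks."""
    cfg = ss.TrialConfig(duration_s=duration_s)
    rng = np.random.default_rng(seed)
    skill = float(rng.uniform(-1, 1))
    return ss.simulate_trial(cfg, skill, seed=seed)
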