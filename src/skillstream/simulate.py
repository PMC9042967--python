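"""Synthetic bimanual surgical-trial generator.

Produces 50 Hz raw instrument streams with a controllable ground-truth skill
parameter in [-1, +1], emulating the statistical structure of a virtual
subpial tumor-resection trial: a dominant-hand ultrasonic aspirator and a
nondominant-hand bipolar forceps, each with a 3D tip position (mm), an
applied force (N) and an activation state, plus tissue-state channels
(tumor volume removed, blood volume present, healthy-tissue damage).

Mechanism
---------
Tip trajectories are a slow purposeful drift around the tumor site plus an
Ornstein-Uhlenbeck tremor whose innovation scale decreases with skill, so
velocity, acceleration, path length and inter-tip coordination all separate
by skill.  Forces are nonnegative mean-reverting processes whose mean and
dispersion decrease with skill.  Bleeding and healthy-tissue damage are
Poisson marked point processes with intensity decreasing in skill; blood is
cleared by aspiration.  Tumor removal accrues while the aspirator is active
near the tumor, with efficiency increasing in skill.  All skill-to-parameter
maps are affine in skill and recorded in :data:`SKILL_DIRECTIONS` /
:func:`skill_parameter_map` so downstream tests can assert directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError

__all__ = [
    "TrialConfig",
    "GroupSpec",
    "CohortDesign",
    "RawStream",
    "SKILL_DIRECTIONS",
    "skill_parameter_map",
    "simulate_trial",
    "simulate_cohort",
    "development_cohort",
    "trainee_cohort",
    "four_group_cohort",
    "skill_ladder_cohort",
]

#: Expected sign of E[metric | skill=+1] - E[metric | skill=-1] for each of
#: the 16 downstream performance metrics (the generator's separation manifest).
SKILL_DIRECTIONS: dict[str, int] = {
    "aspirator_force": -1,
    "bipolar_force": -1,
    "aspirator_velocity": -1,
    "bipolar_velocity": -1,
    "aspirator_acceleration": -1,
    "bipolar_acceleration": -1,
    "tip_separation": -1,
    "tip_relative_velocity": -1,
    "aspirator_path_length": -1,
    "bipolar_path_length": -1,
    "aspirator_active_fraction": +1,
    "bipolar_active_fraction": +1,
    "tumor_removed": +1,
    "blood_volume": -1,
    "bleeding_rate": -1,
    "healthy_tissue_damage": -1,
}


@dataclass(frozen=True)
class TrialConfig:
    """Physical configuration of one simulated trial.

    ``duration_s`` is used when a single trial is simulated directly;
    cohort generation draws each trial's duration uniformly from
    ``duration_range_s`` so downstream code must handle variable-length
    sequences.
    """

    duration_s: float = 120.0
    raw_dt: float = 0.02
    workspace_extent_mm: float = 10.0
    noise_scale: float = 1.0
    #: per-second base rates for bleeding / tissue-damage events and the
    #: base tumor-removal rate constant (at skill 0, aspirator active)
    event_rates: dict = field(
        default_factory=lambda: {"bleeding": 0.20, "damage": 0.12, "tumor": 0.008}
    )
    duration_range_s: tuple[float, float] = (90.0, 180.0)

    def validate(self) -> None:
        if self.duration_s <= 0 or self.raw_dt <= 0:
            raise InvalidConfigError(
                f"duration_s and raw_dt must be positive, got "
                f"{self.duration_s}, {self.raw_dt}"
            )
        if round(self.duration_s / self.raw_dt) < 2:
            raise InvalidConfigError("trial must contain at least 2 samples")
        if self.workspace_extent_mm <= 0 or self.noise_scale <= 0:
            raise InvalidConfigError("workspace extent and noise scale must be positive")


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_participants: int
    skill_mean: float
    skill_sd: float


@dataclass(frozen=True)
class CohortDesign:
    """Roster of expertise groups with per-group skill distributions.

    Skill for each participant is drawn once from a normal distribution
    truncated to [-1, 1] and shared across all of that participant's trials.
    """

    groups: tuple[GroupSpec, ...]
    trials_per_participant: int = 6

    def validate(self) -> None:
        if self.trials_per_participant < 1:
            raise InvalidConfigError("trials_per_participant must be >= 1")
        for g in self.groups:
            if g.n_participants < 0:
                raise InvalidConfigError(f"group {g.label!r} has negative size")


@dataclass
class RawStream:
    """One simulated trial at raw (50 Hz) resolution.

    Positions in mm, forces in N, blood/damage volumes in mL, tumor removed
    as a fraction of initial tumor volume in [0, 1].
    """

    time: np.ndarray
    aspirator_pos: np.ndarray  # (n, 3) mm
    aspirator_force: np.ndarray
    aspirator_active: np.ndarray  # bool
    bipolar_pos: np.ndarray
    bipolar_force: np.ndarray
    bipolar_active: np.ndarray
    tumor_removed: np.ndarray
    blood_present: np.ndarray
    healthy_damage: np.ndarray
    participant_id: str = "p00"
    trial_index: int = 0
    group_label: str | None = None
    skill: float | None = None

    def __len__(self) -> int:
        return self.time.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time": self.time,
            "asp_x": self.aspirator_pos[:, 0],
            "asp_y": self.aspirator_pos[:, 1],
            "asp_z": self.aspirator_pos[:, 2],
            "asp_force": self.aspirator_force,
            "asp_active": self.aspirator_active.astype(int),
            "bip_x": self.bipolar_pos[:, 0],
            "bip_y": self.bipolar_pos[:, 1],
            "bip_z": self.bipolar_pos[:, 2],
            "bip_force": self.bipolar_force,
            "bip_active": self.bipolar_active.astype(int),
            "tumor_removed": self.tumor_removed,
            "blood_present": self.blood_present,
            "healthy_damage": self.healthy_damage,
        }
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        participant_id: str = "p00",
        trial_index: int = 0,
        group_label: str | None = None,
        skill: float | None = None,
    ) -> "RawStream":
        return cls(
            time=df["time"].to_numpy(float),
            aspirator_pos=df[["asp_x", "asp_y", "asp_z"]].to_numpy(float),
            aspirator_force=df["asp_force"].to_numpy(float),
            aspirator_active=df["asp_active"].to_numpy(float) > 0.5,
            bipolar_pos=df[["bip_x", "bip_y", "bip_z"]].to_numpy(float),
            bipolar_force=df["bip_force"].to_numpy(float),
            bipolar_active=df["bip_active"].to_numpy(float) > 0.5,
            tumor_removed=df["tumor_removed"].to_numpy(float),
            blood_present=df["blood_present"].to_numpy(float),
            healthy_damage=df["healthy_damage"].to_numpy(float),
            participant_id=participant_id,
            trial_index=trial_index,
            group_label=group_label,
            skill=skill,
        )


def skill_parameter_map(skill: float, config: TrialConfig) -> dict[str, float]:
    """Affine skill-to-parameter maps used by the generator.

    All maps are monotone in skill; their signs imply the metric-separation
    directions recorded in :data:`SKILL_DIRECTIONS`.
    """
    s = float(np.clip(skill, -1.0, 1.0))
    ns = config.noise_scale
    return {
        # OU tremor innovation scale, mm / sqrt(s); decreasing in skill
        "tremor_sigma": ns * (1.10 - 0.65 * s),
        # mean inter-tip working separation, mm; decreasing in skill
        "separation_mm": 11.0 - 4.0 * s,
        # force process mean (N) and innovation scale; decreasing in skill
        "asp_force_mean": 0.90 - 0.40 * s,
        "asp_force_sigma": ns * (0.28 - 0.13 * s),
        "bip_force_mean": 0.60 - 0.25 * s,
        "bip_force_sigma": ns * (0.20 - 0.09 * s),
        # stationary activation (pedal-on) fractions; increasing in skill
        "asp_on_fraction": 0.65 + 0.20 * s,
        "bip_on_fraction": 0.50 + 0.15 * s,
        # event intensities, 1/s; decreasing in skill
        "bleed_rate": config.event_rates["bleeding"] * (1.0 - 0.6 * s),
        "damage_rate": config.event_rates["damage"] * (1.0 - 0.7 * s),
        # tumor removal rate constant, 1/s while active; increasing in skill
        "tumor_rate": config.event_rates["tumor"] * (1.0 + 0.8 * s),
    }


def _slow_drift(n: int, dt: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth purposeful 3D motion: two random low-frequency sinusoids per axis."""
    t = np.arange(n) * dt
    out = np.zeros((n, 3))
    for ax in range(3):
        for _ in range(2):
            f = rng.uniform(0.05, 0.20)  # Hz
            phase = rng.uniform(0, 2 * np.pi)
            out[:, ax] += 0.5 * amplitude * np.sin(2 * np.pi * f * t + phase)
    return out


def _ou_tremor(n: int, dt: float, sigma: float, rng: np.random.Generator,
               theta: float = 4.0, dim: int = 3) -> np.ndarray:
    eps = rng.standard_normal((n, dim))
    x = np.zeros((n, dim))
    scale = sigma * np.sqrt(dt)
    for k in range(1, n):
        x[k] = x[k - 1] - theta * x[k - 1] * dt + scale * eps[k]
    return x


def _ou_force(n: int, dt: float, mean: float, sigma: float,
              rng: np.random.Generator, theta: float = 2.0) -> np.ndarray:
    eps = rng.standard_normal(n)
    f = np.empty(n)
    f[0] = max(mean, 0.0)
    scale = sigma * np.sqrt(dt)
    for k in range(1, n):
        f[k] = f[k - 1] + theta * (mean - f[k - 1]) * dt + scale * eps[k]
        if f[k] < 0.0:
            f[k] = 0.0
    return f


def _markov_active(n: int, dt: float, on_fraction: float,
                   rng: np.random.Generator, cycle_s: float = 2.5) -> np.ndarray:
    """Two-state activation with given stationary on-fraction and ~cycle_s dwell scale."""
    p = float(np.clip(on_fraction, 0.05, 0.95))
    p_off_to_on = dt / (cycle_s * (1.0 - p))
    p_on_to_off = dt / (cycle_s * p)
    u = rng.uniform(size=n)
    active = np.empty(n, dtype=bool)
    active[0] = u[0] < p
    for k in range(1, n):
        if active[k - 1]:
            active[k] = u[k] >= p_on_to_off
        else:
            active[k] = u[k] < p_off_to_on
    return active


def simulate_trial(
    config: TrialConfig,
    skill: float,
    seed: int,
    participant_id: str = "p00",
    trial_index: int = 0,
    group_label: str | None = None,
) -> RawStream:
    """Simulate one bimanual trial at ``round(duration_s / raw_dt)`` samples.

    Deterministic: identical (config, skill, seed) give a bit-identical stream.
    """
    config.validate()
    if not (-1.0 <= skill <= 1.0):
        raise InvalidConfigError(f"skill must lie in [-1, 1], got {skill}")
    rng = np.random.default_rng(seed)
    n = int(round(config.duration_s / config.raw_dt))
    dt = config.raw_dt
    time = np.arange(n) * dt
    par = skill_parameter_map(skill, config)

    amp = 0.4 * config.workspace_extent_mm
    tumor_center = np.zeros(3)
    asp_pos = (
        tumor_center
        + _slow_drift(n, dt, amp, rng)
        + _ou_tremor(n, dt, par["tremor_sigma"], rng)
    )
    # bipolar works at a skill-dependent offset from the aspirator's site
    offset_dir = rng.standard_normal(3)
    offset_dir /= np.linalg.norm(offset_dir)
    bip_pos = (
        tumor_center
        + par["separation_mm"] * offset_dir
        + _slow_drift(n, dt, 0.6 * amp, rng)
        + _ou_tremor(n, dt, par["tremor_sigma"], rng)
    )

    asp_force = _ou_force(n, dt, par["asp_force_mean"], par["asp_force_sigma"], rng)
    bip_force = _ou_force(n, dt, par["bip_force_mean"], par["bip_force_sigma"], rng)
    asp_active = _markov_active(n, dt, par["asp_on_fraction"], rng)
    bip_active = _markov_active(n, dt, par["bip_on_fraction"], rng)

    # marked Poisson events: bleeding adds blood, damage accrues irreversibly
    bleed_hits = rng.uniform(size=n) < par["bleed_rate"] * dt
    bleed_marks = rng.exponential(0.5, size=n) * bleed_hits
    damage_hits = rng.uniform(size=n) < par["damage_rate"] * dt
    damage_marks = rng.exponential(0.25, size=n) * damage_hits
    healthy_damage = np.cumsum(damage_marks)

    blood = np.empty(n)
    blood[0] = bleed_marks[0]
    clear = np.exp(-0.9 * dt)   # aspiration clears blood
    passive = np.exp(-0.05 * dt)
    for k in range(1, n):
        decay = clear if asp_active[k] else passive
        blood[k] = blood[k - 1] * decay + bleed_marks[k]

    # tumor removal: first-order kinetics gated by activation and proximity
    tumor = np.empty(n)
    tumor[0] = 0.0
    dist2 = np.sum((asp_pos - tumor_center) ** 2, axis=1)
    prox = np.exp(-dist2 / (2.0 * 8.0**2))
    rate = par["tumor_rate"] * asp_active * prox
    for k in range(1, n):
        tumor[k] = tumor[k - 1] + rate[k] * (1.0 - tumor[k - 1]) * dt

    return RawStream(
        time=time,
        aspirator_pos=asp_pos,
        aspirator_force=asp_force,
        aspirator_active=asp_active,
        bipolar_pos=bip_pos,
        bipolar_force=bip_force,
        bipolar_active=bip_active,
        tumor_removed=np.clip(tumor, 0.0, 1.0),
        blood_present=blood,
        healthy_damage=healthy_damage,
        participant_id=participant_id,
        trial_index=trial_index,
        group_label=group_label,
        skill=float(skill),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if -1.0 <= x <= 1.0:
            return float(x)
    return float(np.clip(mean, -1.0, 1.0))


def simulate_cohort(
    design: CohortDesign, config: TrialConfig, seed: int
) -> list[RawStream]:
    """Simulate every trial of a cohort; a pure function of (design, config, seed).

    Each participant's skill is drawn once and shared across their trials;
    trial durations are drawn uniformly from ``config.duration_range_s``.
    """
    design.validate()
    config.validate()
    streams: list[RawStream] = []
    lo, hi = config.duration_range_s
    for gi, group in enumerate(design.groups):
        for pi in range(group.n_participants):
            p_ss = np.random.SeedSequence([seed, gi, pi])
            p_rng = np.random.default_rng(p_ss)
            skill = _truncated_normal(p_rng, group.skill_mean, group.skill_sd)
            pid = f"{group.label}-{pi:02d}"
            for ti in range(design.trials_per_participant):
                duration = float(p_rng.uniform(lo, hi))
                trial_seed = int(p_rng.integers(0, 2**31 - 1))
                cfg = replace(config, duration_s=duration)
                streams.append(
                    simulate_trial(
                        cfg,
                        skill,
                        trial_seed,
                        participant_id=pid,
                        trial_index=ti,
                        group_label=group.label,
                    )
                )
    return streams


# ---------------------------------------------------------------------------
# Canonical cohort designs.  Group sizes mirror the study design the pipeline
# is validated against: 14 experts + 12 novices form the development cohort
# (156 trials), 14 seniors + 10 juniors the 24-trainee test cohort (144
# trials).  Skill anchors at ±0.8 for the ends and ±0.33 for the trainee
# groups, matching the risk module's expertise-level codes.
# ---------------------------------------------------------------------------

def development_cohort(n_experts: int = 14, n_novices: int = 12,
                       trials_per_participant: int = 6) -> CohortDesign:
    """Two-end (expert/novice) cohort used to train the assessment model."""
    return CohortDesign(
        groups=(
            GroupSpec("expert", n_experts, 0.8, 0.1),
            GroupSpec("novice", n_novices, -0.8, 0.1),
        ),
        trials_per_participant=trials_per_participant,
    )


def trainee_cohort(n_seniors: int = 14, n_juniors: int = 10,
                   trials_per_participant: int = 6) -> CohortDesign:
    """Held-out trainee cohort scored (never trained on) by the model."""
    return CohortDesign(
        groups=(
            GroupSpec("senior", n_seniors, 0.33, 0.15),
            GroupSpec("junior", n_juniors, -0.33, 0.15),
        ),
        trials_per_participant=trials_per_participant,
    )


def four_group_cohort(n_experts: int = 14, n_seniors: int = 14,
                      n_juniors: int = 10, n_novices: int = 12,
                      trials_per_participant: int = 6) -> CohortDesign:
    """Full four-group cohort for group-comparison statistics."""
    return CohortDesign(
        groups=(
            GroupSpec("expert", n_experts, 0.8, 0.1),
            GroupSpec("senior", n_seniors, 0.33, 0.15),
            GroupSpec("junior", n_juniors, -0.33, 0.15),
            GroupSpec("novice", n_novices, -0.8, 0.1),
        ),
        trials_per_participant=trials_per_participant,
    )


def skill_ladder_cohort(n_levels: int = 9, trials_per_participant: int = 6
                        ) -> CohortDesign:
    """Deterministic skill ladder from -1 to +1 (one participant per rung)."""
    levels = np.linspace(-1.0, 1.0, n_levels)
    return CohortDesign(
        groups=tuple(
            GroupSpec(f"ladder{i}", 1, float(v), 0.0) for i, v in enumerate(levels)
        ),
        trials_per_participant=trials_per_participant,
    )
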