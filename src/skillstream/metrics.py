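"""Raw-stream regularization and 16-metric extraction on a 0.2 s grid.

The raw 50 Hz stream is first regularized onto an exact 0.02 s grid
(linear interpolation for continuous channels, previous-sample hold for
activation states), then reduced to 16 performance metrics per half-open
0.2 s window.  Ten metrics form the core bimanual set (per-instrument
force, velocity magnitude and acceleration magnitude, inter-tip separation,
tumor removed, bleeding, healthy-tissue damage); the remaining six —
per-instrument path length and active fraction, bleeding rate, and
inter-tip relative velocity — round out the five-category scheme (safety,
quality, efficiency, bimanual cognitive, movement) and are flagged
``reconstructed`` in the manifest.  The pipeline is parametric in the
manifest, so the set can be swapped.

Window conventions
------------------
Windows are half-open ``[t, t+0.2)`` anchored at the first raw timestamp; a
trailing partial window is dropped, so a trial of ``n`` raw samples yields
``floor(n / 10)`` metric rows.  Velocity is the first difference of tip
position at raw resolution (defined from the second sample on) and
acceleration the first difference of velocity (from the third sample on);
window means average the defined samples inside the window.  Cumulative
channels (tumor removed, healthy damage) enter as end-minus-start deltas
over the window so features are roughly stationary in trial time; blood is
not cumulative (it is cleared by aspiration) and enters as its within-window
mean level, with a separate bleeding-rate metric counting only inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateFeatureError,
    FeatureOrderError,
    MalformedStreamError,
    TooShortTrialError,
)
from .simulate import RawStream

__all__ = [
    "MetricDef",
    "METRIC_MANIFEST",
    "MetricSeries",
    "NormalizationStats",
    "regularize",
    "extract_metrics",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
]

WINDOW_S = 0.2  # decision interval: 5 assessments per second


@dataclass(frozen=True)
class MetricDef:
    name: str
    unit: str
    category: str  # safety | quality | efficiency | bimanual_cognitive | movement
    reduction: str  # window reduction rule
    reconstructed: bool = False


#: Fixed feature order for the whole pipeline; models refuse to score trials
#: whose manifest does not match this order.
METRIC_MANIFEST: tuple[MetricDef, ...] = (
    MetricDef("aspirator_force", "N", "safety", "window mean"),
    MetricDef("bipolar_force", "N", "safety", "window mean"),
    MetricDef("aspirator_velocity", "mm/s", "movement", "window mean of |v|"),
    MetricDef("bipolar_velocity", "mm/s", "movement", "window mean of |v|"),
    MetricDef("aspirator_acceleration", "mm/s^2", "movement", "window mean of |a|"),
    MetricDef("bipolar_acceleration", "mm/s^2", "movement", "window mean of |a|"),
    MetricDef("tip_separation", "mm", "bimanual_cognitive", "window mean"),
    MetricDef("tip_relative_velocity", "mm/s", "bimanual_cognitive",
              "window mean of |v_dom - v_nondom|", reconstructed=True),
    MetricDef("aspirator_path_length", "mm", "movement", "window sum of |dp|",
              reconstructed=True),
    MetricDef("bipolar_path_length", "mm", "movement", "window sum of |dp|",
              reconstructed=True),
    MetricDef("aspirator_active_fraction", "", "efficiency", "window mean",
              reconstructed=True),
    MetricDef("bipolar_active_fraction", "", "efficiency", "window mean",
              reconstructed=True),
    MetricDef("tumor_removed", "fraction", "quality", "end-minus-start delta"),
    MetricDef("blood_volume", "mL", "safety", "window mean"),
    MetricDef("bleeding_rate", "mL/s", "safety", "window positive inflow / 0.2 s",
              reconstructed=True),
    MetricDef("healthy_tissue_damage", "mL", "safety", "end-minus-start delta"),
)

METRIC_NAMES: tuple[str, ...] = tuple(m.name for m in METRIC_MANIFEST)


@dataclass
class MetricSeries:
    """16 performance metrics for one trial on the 0.2 s decision grid."""

    time: np.ndarray          # (n,) window start times, s
    values: np.ndarray        # (n, 16)
    manifest: tuple[MetricDef, ...] = METRIC_MANIFEST
    participant_id: str = "p00"
    trial_index: int = 0
    group_label: str | None = None
    skill: float | None = None

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.manifest)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.names.index(name)]
        except ValueError:
            raise FeatureOrderError(f"metric {name!r} not in manifest") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "time", self.time)
        return df


def regularize(raw: RawStream) -> RawStream:
    """Resample a stream onto an exact 0.02 s grid from its first timestamp.

    Continuous channels are linearly interpolated; activation states are
    carried forward from the most recent earlier sample.  Monotone channels
    stay monotone (linear interpolation preserves monotonicity).
    """
    t = np.asarray(raw.time, float)
    if t.ndim != 1 or t.size < 2:
        raise MalformedStreamError("stream needs at least 2 timestamped samples")
    if np.any(np.diff(t) <= 0):
        raise MalformedStreamError("timestamps must be strictly increasing")

    dt = 0.02
    n_out = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) * dt

    def interp(y: np.ndarray) -> np.ndarray:
        if y.ndim == 1:
            return np.interp(grid, t, y)
        return np.column_stack([np.interp(grid, t, y[:, j]) for j in range(y.shape[1])])

    def hold(b: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(t, grid, side="right") - 1
        return b[np.clip(idx, 0, len(t) - 1)]

    return RawStream(
        time=grid,
        aspirator_pos=interp(raw.aspirator_pos),
        aspirator_force=interp(raw.aspirator_force),
        aspirator_active=hold(raw.aspirator_active),
        bipolar_pos=interp(raw.bipolar_pos),
        bipolar_force=interp(raw.bipolar_force),
        bipolar_active=hold(raw.bipolar_active),
        tumor_removed=interp(raw.tumor_removed),
        blood_present=interp(raw.blood_present),
        healthy_damage=interp(raw.healthy_damage),
        participant_id=raw.participant_id,
        trial_index=raw.trial_index,
        group_label=raw.group_label,
        skill=raw.skill,
    )


def _window_mean_defined(x: np.ndarray, start: int, stop: int, first_defined: int) -> float:
    """Mean of x over window samples with index >= first_defined."""
    lo = max(start, first_defined)
    if lo >= stop:
        return 0.0
    return float(np.mean(x[lo:stop]))


def extract_metrics(raw: RawStream) -> MetricSeries:
    """Reduce a regularized stream to the 16-metric series at 0.2 s."""
    t = np.asarray(raw.time, float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise MalformedStreamError("stream must be regularized and strictly increasing")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-9):
        raise MalformedStreamError("stream is not on a uniform grid; regularize first")
    per_win = int(round(WINDOW_S / dt))
    n = t.size
    n_win = n // per_win
    if n_win < 1:
        raise TooShortTrialError(
            f"trial has {n} samples; at least {per_win} (one {WINDOW_S} s window) required"
        )

    def speed(pos: np.ndarray) -> np.ndarray:
        v = np.zeros(n)
        v[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
        return v

    def accel(pos: np.ndarray) -> np.ndarray:
        vvec = np.zeros((n, 3))
        vvec[1:] = np.diff(pos, axis=0) / dt
        a = np.zeros(n)
        a[2:] = np.linalg.norm(np.diff(vvec[1:], axis=0), axis=1) / dt
        return a

    asp_v, bip_v = speed(raw.aspirator_pos), speed(raw.bipolar_pos)
    asp_a, bip_a = accel(raw.aspirator_pos), accel(raw.bipolar_pos)
    vvec_asp = np.zeros((n, 3))
    vvec_asp[1:] = np.diff(raw.aspirator_pos, axis=0) / dt
    vvec_bip = np.zeros((n, 3))
    vvec_bip[1:] = np.diff(raw.bipolar_pos, axis=0) / dt
    rel_v = np.zeros(n)
    rel_v[1:] = np.linalg.norm(vvec_asp[1:] - vvec_bip[1:], axis=1)
    sep = np.linalg.norm(raw.aspirator_pos - raw.bipolar_pos, axis=1)
    step_asp = np.zeros(n)
    step_asp[1:] = np.linalg.norm(np.diff(raw.aspirator_pos, axis=0), axis=1)
    step_bip = np.zeros(n)
    step_bip[1:] = np.linalg.norm(np.diff(raw.bipolar_pos, axis=0), axis=1)
    blood_in = np.zeros(n)
    blood_in[1:] = np.maximum(np.diff(raw.blood_present), 0.0)

    out = np.empty((n_win, len(METRIC_MANIFEST)))
    times = np.empty(n_win)
    for w in range(n_win):
        a, b = w * per_win, (w + 1) * per_win
        times[w] = t[a]
        out[w, 0] = np.mean(raw.aspirator_force[a:b])
        out[w, 1] = np.mean(raw.bipolar_force[a:b])
        out[w, 2] = _window_mean_defined(asp_v, a, b, 1)
        out[w, 3] = _window_mean_defined(bip_v, a, b, 1)
        out[w, 4] = _window_mean_defined(asp_a, a, b, 2)
        out[w, 5] = _window_mean_defined(bip_a, a, b, 2)
        out[w, 6] = np.mean(sep[a:b])
        out[w, 7] = _window_mean_defined(rel_v, a, b, 1)
        out[w, 8] = np.sum(step_asp[max(a, 1):b])
        out[w, 9] = np.sum(step_bip[max(a, 1):b])
        out[w, 10] = np.mean(raw.aspirator_active[a:b].astype(float))
        out[w, 11] = np.mean(raw.bipolar_active[a:b].astype(float))
        out[w, 12] = raw.tumor_removed[b - 1] - raw.tumor_removed[a]
        out[w, 13] = np.mean(raw.blood_present[a:b])
        out[w, 14] = np.sum(blood_in[max(a, 1):b]) / WINDOW_S
        out[w, 15] = raw.healthy_damage[b - 1] - raw.healthy_damage[a]

    return MetricSeries(
        time=times,
        values=out,
        manifest=METRIC_MANIFEST,
        participant_id=raw.participant_id,
        trial_index=raw.trial_index,
        group_label=raw.group_label,
        skill=raw.skill,
    )


@dataclass
class NormalizationStats:
    """Per-metric z-score statistics estimated on the training subset only.

    Standard deviations use the population convention (divide by n) so that
    re-applying fitted stats to the pooled training rows gives exactly mean 0
    and sd 1.
    """

    mean: np.ndarray
    sd: np.ndarray
    names: tuple[str, ...] = field(default=METRIC_NAMES)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mean": [float(x) for x in self.mean],
            "sd": [float(x) for x in self.sd],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            mean=np.asarray(d["mean"], float),
            sd=np.asarray(d["sd"], float),
            names=tuple(d["names"]),
        )


def fit_normalization(training_trials: list[MetricSeries]) -> NormalizationStats:
    """Pool all timesteps of all training trials and fit per-metric mean/sd."""
    if len(training_trials) < 1:
        raise ValueError("need at least one training trial")
    names = training_trials[0].names
    for tr in training_trials[1:]:
        if tr.names != names:
            raise FeatureOrderError("training trials carry inconsistent manifests")
    pooled = np.concatenate([tr.values for tr in training_trials], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least two pooled rows to estimate a spread")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)  # population (ddof=0)
    for j in range(pooled.shape[1]):
        # ptp is exact for a constant column; sd may pick up rounding noise
        if np.ptp(pooled[:, j]) == 0.0 or sd[j] == 0.0:
            raise DegenerateFeatureError(names[j])
    return NormalizationStats(mean=mean, sd=sd, names=names)


def _check_manifest(trial: MetricSeries, stats: NormalizationStats) -> None:
    if trial.names != tuple(stats.names):
        raise FeatureOrderError(
            "trial manifest does not match normalization stats: "
            f"{trial.names} vs {tuple(stats.names)}"
        )


def apply_normalization(trial: MetricSeries, stats: NormalizationStats) -> MetricSeries:
    """Z-score a trial with training-set statistics."""
    _check_manifest(trial, stats)
    return MetricSeries(
        time=trial.time.copy(),
        values=(trial.values - stats.mean) / stats.sd,
        manifest=trial.manifest,
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        group_label=trial.group_label,
        skill=trial.skill,
    )


def invert_normalization(trial: MetricSeries, stats: NormalizationStats) -> MetricSeries:
    """Algebraic inverse of :func:`apply_normalization`."""
    _check_manifest(trial, stats)
    return MetricSeries(
        time=trial.time.copy(),
        values=trial.values * stats.sd + stats.mean,
        manifest=trial.manifest,
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        group_label=trial.group_label,
        skill=trial.skill,
    )
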