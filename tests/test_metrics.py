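"""Regularization and metric extraction: grid conventions, window accounting,
brute-force oracle equivalence, unit coherence, and z-score normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skillstream as ss
from skillstream.exceptions import (
    DegenerateFeatureError,
    FeatureOrderError,
    MalformedStreamError,
    TooShortTrialError,
)
from .conftest import random_fixture_stream
from .oracles import brute_force_metrics


def _stream_with_times(t):
    n = len(t)
    z = np.zeros(n)
    return ss.RawStream(
        time=np.asarray(t, float),
        aspirator_pos=np.zeros((n, 3)),
        aspirator_force=z.copy(),
        aspirator_active=np.zeros(n, bool),
        bipolar_pos=np.zeros((n, 3)),
        bipolar_force=z.copy(),
        bipolar_active=np.zeros(n, bool),
        tumor_removed=z.copy(),
        blood_present=z.copy(),
        healthy_damage=z.copy(),
    )


class TestRegularize:
    def test_identity_on_exact_grid(self, raw_trial):
        reg = ss.regularize(raw_trial)
        assert len(reg) == len(raw_trial)
        np.testing.assert_allclose(reg.aspirator_pos, raw_trial.aspirator_pos,
                                   atol=1e-9)
        np.testing.assert_array_equal(reg.aspirator_active, raw_trial.aspirator_active)

    def test_linear_midpoint(self):
        st_ = _stream_with_times([0.0, 0.04])
        st_.aspirator_pos[1] = [2.0, 0.0, 0.0]
        reg = ss.regularize(st_)
        assert len(reg) == 3
        assert reg.aspirator_pos[1, 0] == pytest.approx(1.0)  # 1 mm at t=0.02

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(MalformedStreamError):
            ss.regularize(_stream_with_times([0.0, 0.0, 0.02]))

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(MalformedStreamError):
            ss.regularize(_stream_with_times([0.0, 0.05, 0.03]))

    def test_monotone_channels_stay_monotone_on_irregular_input(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 2.0, 60))
        t[0], t[-1] = 0.0, 2.0
        st_ = _stream_with_times(t)
        st_.tumor_removed = np.sort(rng.uniform(0, 1, 60))
        st_.healthy_damage = np.cumsum(rng.uniform(0, 0.1, 60))
        reg = ss.regularize(st_)
        assert np.all(np.diff(reg.tumor_removed) >= -1e-12)
        assert np.all(np.diff(reg.healthy_damage) >= -1e-12)

    def test_activation_uses_previous_sample_hold(self):
        st_ = _stream_with_times([0.0, 0.03, 0.06])
        st_.aspirator_active = np.array([True, False, True])
        reg = ss.regularize(st_)
        # grid 0.00,0.02,0.04,0.06 -> holds values at/before each grid point
        np.testing.assert_array_equal(reg.aspirator_active,
                                      [True, True, False, True])


class TestExtractMetrics:
    def test_row_count_is_floor_duration_over_window(self):
        tr = ss.extract_metrics(
            ss.regularize(ss.simulate_trial(ss.TrialConfig(duration_s=12.0), 0.0, 1))
        )
        assert len(tr) == 60  # 12 s at 5 decisions per second
        assert tr.values.shape == (60, 16)

    def test_window_accounting_rule(self, raw_trial):
        tr = ss.extract_metrics(ss.regularize(raw_trial))
        assert len(tr) == len(raw_trial) // 10

    def test_grid_step_is_window(self, metric_trial):
        assert np.allclose(np.diff(metric_trial.time), 0.2)

    def test_stationary_tips_zero_velocity_acceleration(self):
        st_ = _stream_with_times(np.arange(20) * 0.02)
        tr = ss.extract_metrics(st_)
        assert np.all(tr.column("aspirator_velocity") == 0)
        assert np.all(tr.column("bipolar_acceleration") == 0)
        assert np.all(tr.column("aspirator_path_length") == 0)

    def test_three_four_five_separation(self):
        st_ = _stream_with_times(np.arange(10) * 0.02)
        st_.bipolar_pos[:] = [3.0, 4.0, 0.0]
        tr = ss.extract_metrics(st_)
        assert tr.column("tip_separation")[0] == pytest.approx(5.0)

    def test_too_short_trial_rejected(self):
        with pytest.raises(TooShortTrialError):
            ss.extract_metrics(_stream_with_times(np.arange(5) * 0.02))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_oracle(self, seed):
        """Vectorized extraction equals a sample-by-sample loop recomputation."""
        raw = ss.regularize(random_fixture_stream(seed))
        got = ss.extract_metrics(raw).values
        expected = brute_force_metrics(raw)
        np.testing.assert_allclose(got, expected, atol=1e-9, rtol=0)

    def test_unit_coherence_under_position_scaling(self):
        """Doubling all positions doubles every length-derived metric and
        leaves forces, fractions and tissue channels unchanged."""
        raw = ss.regularize(random_fixture_stream(99))
        scaled = ss.RawStream(
            time=raw.time,
            aspirator_pos=raw.aspirator_pos * 2,
            aspirator_force=raw.aspirator_force,
            aspirator_active=raw.aspirator_active,
            bipolar_pos=raw.bipolar_pos * 2,
            bipolar_force=raw.bipolar_force,
            bipolar_active=raw.bipolar_active,
            tumor_removed=raw.tumor_removed,
            blood_present=raw.blood_present,
            healthy_damage=raw.healthy_damage,
        )
        base = ss.extract_metrics(raw)
        twice = ss.extract_metrics(scaled)
        doubled = {"aspirator_velocity", "bipolar_velocity", "aspirator_acceleration",
                   "bipolar_acceleration", "tip_separation", "tip_relative_velocity",
                   "aspirator_path_length", "bipolar_path_length"}
        for name in ss.METRIC_NAMES:
            if name in doubled:
                np.testing.assert_allclose(twice.column(name), 2 * base.column(name),
                                           rtol=1e-12, err_msg=name)
            else:
                np.testing.assert_allclose(twice.column(name), base.column(name),
                                           rtol=1e-12, err_msg=name)


class TestNormalization:
    def test_fitted_stats_zscore_training_pool(self, mini_cohort_trials):
        stats = ss.fit_normalization(mini_cohort_trials)
        pooled = np.concatenate(
            [ss.apply_normalization(t, stats).values for t in mini_cohort_trials]
        )
        np.testing.assert_allclose(pooled.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(pooled.std(axis=0), 1, rtol=1e-8)

    def test_two_point_metric_population_sd(self):
        # values {1, 3}: mean 2, population sd 1
        base = random_fixture_stream(1)
        tr = ss.extract_metrics(ss.regularize(base))
        a = ss.MetricSeries(time=tr.time[:1], values=np.full((1, 16), 1.0))
        b = ss.MetricSeries(time=tr.time[:1], values=np.full((1, 16), 3.0))
        stats = ss.fit_normalization([a, b])
        np.testing.assert_allclose(stats.mean, 2.0)
        np.testing.assert_allclose(stats.sd, 1.0)

    def test_constant_metric_raises_naming_it(self, metric_trial):
        frozen = ss.MetricSeries(
            time=metric_trial.time, values=metric_trial.values.copy()
        )
        frozen.values[:, 6] = 4.2  # tip_separation constant
        with pytest.raises(DegenerateFeatureError) as err:
            ss.fit_normalization([frozen, frozen])
        assert err.value.metric_name == "tip_separation"

    def test_mean_maps_to_zero_and_mean_plus_sd_to_one(self, mini_cohort_trials):
        stats = ss.fit_normalization(mini_cohort_trials)
        probe = ss.MetricSeries(
            time=np.array([0.0, 0.2]),
            values=np.vstack([stats.mean, stats.mean + stats.sd]),
        )
        z = ss.apply_normalization(probe, stats)
        np.testing.assert_allclose(z.values[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values[1], 1.0, atol=1e-12)

    def test_round_trip_recovers_input(self, mini_cohort_trials):
        stats = ss.fit_normalization(mini_cohort_trials)
        tr = mini_cohort_trials[0]
        back = ss.invert_normalization(ss.apply_normalization(tr, stats), stats)
        np.testing.assert_allclose(back.values, tr.values, atol=1e-10)

    def test_manifest_mismatch_rejected(self, metric_trial, mini_cohort_trials):
        stats = ss.fit_normalization(mini_cohort_trials)
        wrong = ss.NormalizationStats(
            mean=stats.mean, sd=stats.sd, names=tuple(reversed(stats.names))
        )
        with pytest.raises(FeatureOrderError):
            ss.apply_normalization(metric_trial, wrong)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 40))
def test_normalization_round_trip_property(seed, rows):
    """apply then invert is the identity for any finite metric table."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(rows, 16)) * rng.uniform(0.5, 20) + rng.uniform(-5, 5)
    tr = ss.MetricSeries(time=np.arange(rows) * 0.2, values=values)
    probe = ss.MetricSeries(time=tr.time, values=values + 1.0)
    stats = ss.fit_normalization([tr, probe])
    back = ss.invert_normalization(ss.apply_normalization(tr, stats), stats)
    np.testing.assert_allclose(back.values, tr.values, atol=1e-8)
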