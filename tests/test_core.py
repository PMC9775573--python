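"""Shared manikin reductions: steady-state selection, averaging, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clotherm as ct
from clotherm.core import SteadyStateError


def _flat_trial(geometry, env, value=10.0, duration=1200.0, dt=10.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    temps = np.full((t.size, 17), 34.0)
    losses = np.full((t.size, 17), value)
    return ct.TrialRecord(
        trial_id="flat", mode="dry", geometry=geometry, environment=env,
        timestamps=t, surface_temp=temps, heat_loss=losses,
    )


class TestDetectSteadyState:
    def test_constant_series_returns_final_window(self, geometry, mild_env):
        trial = _flat_trial(geometry, mild_env, duration=1800.0)
        win = ct.detect_steady_state(trial, min_duration=600.0)
        assert win.end_time == 1800.0
        assert win.start_time == 1200.0

    def test_exponential_approach_window_after_transient(self, geometry, mild_env):
        # heat loss relaxing to a plateau with a 300 s time constant over a
        # 4200 s trial: the detected window must lie beyond 3 time constants
        tau, dt = 300.0, 10.0
        t = np.arange(0.0, 4200.0 + dt / 2, dt)
        h_ss = 8.0
        losses = np.tile(h_ss * (1 + np.exp(-t / tau))[:, None], (1, 17))
        trial = ct.TrialRecord(
            trial_id="warmup", mode="dry", geometry=geometry, environment=mild_env,
            timestamps=t, surface_temp=np.full((t.size, 17), 34.0), heat_loss=losses,
        )
        win = ct.detect_steady_state(trial, min_duration=600.0, slope_tolerance=0.005)
        assert win.start_time > 3 * tau
        # within the detected window the analytic curve deviates from its
        # plateau by less than the slope tolerance allows
        assert np.exp(-win.start_time / tau) < 0.02

    def test_white_noise_window_mean_near_truth(self, geometry, mild_env):
        # Monte-Carlo: noisy-but-steady series must be accepted and its
        # window mean must estimate the true level
        n_ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 1200.0 + 5, 10.0)
            # per-zone noise scaled so the whole-body series has sd 1 W
            losses = rng.normal(100.0 / 17, 1.0 / np.sqrt(17), size=(t.size, 17))
            trial = ct.TrialRecord(
                trial_id=f"wn{seed}", mode="dry", geometry=geometry, environment=mild_env,
                timestamps=t, surface_temp=np.full((t.size, 17), 34.0), heat_loss=losses,
            )
            win = ct.detect_steady_state(trial, min_duration=600.0)
            means = ct.average_window(trial, win)
            total = means.heat_loss.sum()
            if abs(total - 100.0) <= 3 * 1.0 / np.sqrt(means.n_samples):
                n_ok += 1
        assert n_ok >= 95

    def test_monotone_diverging_series_fails(self, geometry, mild_env):
        t = np.arange(0.0, 1200.0 + 5, 10.0)
        losses = np.tile((1.0 + 0.05 * t)[:, None], (1, 17))
        trial = ct.TrialRecord(
            trial_id="ramp", mode="dry", geometry=geometry, environment=mild_env,
            timestamps=t, surface_temp=np.full((t.size, 17), 34.0), heat_loss=losses,
        )
        with pytest.raises(SteadyStateError, match="slope|variation"):
            ct.detect_steady_state(trial, min_duration=600.0)

    def test_trial_shorter_than_min_duration_rejected(self, geometry, mild_env):
        trial = _flat_trial(geometry, mild_env, duration=300.0)
        with pytest.raises(ValueError, match="min_duration"):
            ct.detect_steady_state(trial, min_duration=600.0)


class TestAverageWindow:
    def test_constant_series_idempotent(self, geometry, mild_env):
        trial = _flat_trial(geometry, mild_env, value=7.5)
        means = ct.average_window(trial, ct.SteadyWindow(0.0, 600.0))
        assert np.allclose(means.heat_loss, 7.5)
        assert np.allclose(means.surface_temp, 34.0)

    def test_two_sample_mean(self, geometry, mild_env):
        t = np.array([0.0, 10.0])
        losses = np.stack([np.full(17, 10.0), np.full(17, 20.0)])
        trial = ct.TrialRecord(
            trial_id="two", mode="dry", geometry=geometry, environment=mild_env,
            timestamps=t, surface_temp=np.full((2, 17), 34.0), heat_loss=losses,
        )
        means = ct.average_window(trial, ct.SteadyWindow(0.0, 10.0))
        assert np.allclose(means.heat_loss, 15.0)
        assert means.n_samples == 2

    def test_linear_ramp_matches_closed_form(self, geometry, mild_env):
        a, b, T = 5.0, 0.01, 1200.0
        t = np.arange(0.0, T + 5, 10.0)
        losses = np.tile((a + b * t)[:, None], (1, 17))
        trial = ct.TrialRecord(
            trial_id="ramp", mode="dry", geometry=geometry, environment=mild_env,
            timestamps=t, surface_temp=np.full((t.size, 17), 34.0), heat_loss=losses,
        )
        means = ct.average_window(trial, ct.SteadyWindow(0.0, T))
        # discrete mean of a+bt over an inclusive grid equals a+bT/2 exactly
        assert means.heat_loss[0] == pytest.approx(a + b * T / 2, abs=1e-9)

    def test_window_outside_trial_rejected(self, geometry, mild_env):
        trial = _flat_trial(geometry, mild_env)
        with pytest.raises(ValueError, match="outside"):
            ct.average_window(trial, ct.SteadyWindow(600.0, 5000.0))


class TestRepeatability:
    @pytest.mark.parametrize(
        "a, b, rel, ok",
        [
            (0.100, 0.103, 0.0296, True),
            (0.100, 0.105, 0.0488, False),
            (0.35, 0.35, 0.0, True),
        ],
    )
    def test_four_percent_rule(self, a, b, rel, ok):
        res = ct.repeatability_check(a, b)
        assert res.relative_difference == pytest.approx(rel, abs=5e-4)
        assert res.passed is ok

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(1e-3, 1e3, allow_nan=False),
        b=st.floats(1e-3, 1e3, allow_nan=False),
    )
    def test_symmetric_in_arguments(self, a, b):
        assert ct.repeatability_check(a, b).relative_difference == pytest.approx(
            ct.repeatability_check(b, a).relative_difference
        )

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            ct.repeatability_check(0.0, 1.0)


class TestMeanSurfaceTemperature:
    def test_uniform_temps(self, geometry):
        assert ct.mean_surface_temperature(np.full(17, 34.0), geometry) == pytest.approx(34.0)

    def test_two_zone_hand_case(self):
        g = ct.ManikinGeometry(zones=(ct.Zone("a", "a", 0.5), ct.Zone("b", "b", 0.5)))
        assert ct.mean_surface_temperature([30.0, 38.0], g) == pytest.approx(34.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_matches_weighted_sum_oracle_and_bounds(self, geometry, seed):
        rng = np.random.default_rng(seed)
        temps = rng.uniform(20.0, 40.0, 17)
        expected = sum(t * z.area for t, z in zip(temps, geometry.zones)) / geometry.total_area
        got = ct.mean_surface_temperature(temps, geometry)
        assert got == pytest.approx(expected, abs=1e-12)
        assert temps.min() <= got <= temps.max()

    def test_missing_zone_rejected(self, geometry):
        with pytest.raises(ValueError, match="per zone"):
            ct.mean_surface_temperature(np.full(16, 34.0), geometry)


class TestTypes:
    def test_geometry_total_area_is_zone_sum(self, geometry):
        assert geometry.total_area == pytest.approx(sum(z.area for z in geometry.zones), rel=1e-9)
        assert geometry.total_area == pytest.approx(1.77)

    def test_duplicate_zone_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ct.ManikinGeometry(zones=(ct.Zone("a", "x", 0.5), ct.Zone("b", "x", 0.5)))

    def test_operative_equals_air_when_radiant_matches(self, mild_env):
        assert mild_env.operative_temperature == mild_env.air_temperature
        env = ct.Environment(air_temperature=20.0, relative_humidity=40.0, radiant_temperature=30.0)
        assert env.operative_temperature == pytest.approx(25.0)

    def test_dry_trial_rejects_skin_rh(self, geometry, mild_env):
        t = np.array([0.0, 10.0])
        with pytest.raises(ValueError, match="skin_rh"):
            ct.TrialRecord(
                trial_id="x", mode="dry", geometry=geometry, environment=mild_env,
                timestamps=t, surface_temp=np.full((2, 17), 34.0),
                heat_loss=np.full((2, 17), 5.0), skin_rh=96.0,
            )

    def test_nonmonotone_timestamps_rejected(self, geometry, mild_env):
        t = np.array([0.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="increasing"):
            ct.TrialRecord(
                trial_id="x", mode="dry", geometry=geometry, environment=mild_env,
                timestamps=t, surface_temp=np.full((3, 17), 34.0),
                heat_loss=np.full((3, 17), 5.0),
            )
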