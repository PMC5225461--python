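"""Daily recursion: stationarity, nesting, linearity, and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trainsig import (
    ModelKind,
    ModelParameters,
    TrainingTimeSeries,
    predict_at_measurements,
    simulate_trajectory,
)

ALL_KINDS = list(ModelKind)


def convolution_sum_perf(params, loads, perf0):
    """Independent oracle for Model T: explicit double-sum solution.

    Perf_n = perf0 + k_s2 * sum_{m=1}^{n-1} (1-k_off)^{n-1-m} * Signal_m with
    Signal_m = sum_{j<=m} W_j exp(-k_s1 (m-j)), computed by brute force.
    """
    n = len(loads)
    perf = np.full(n, float(perf0))
    for day in range(1, n):
        acc = 0.0
        for m in range(1, day):
            sig = sum(
                loads[j] * math.exp(-params.k_s1 * (m - j)) for j in range(1, m + 1)
            )
            acc += (1.0 - params.k_off) ** (day - 1 - m) * sig
        perf[day] = perf0 + params.k_s2 * acc
    return perf


class TestStationarity:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_zero_training_keeps_performance_at_baseline(self, kind, full_params):
        traj = simulate_trajectory(kind, full_params, np.zeros(100), perf0=250.0)
        assert np.all(traj.perf == 250.0)
        assert np.all(traj.observable == 250.0)
        assert np.all(traj.signal == 0.0)

    @pytest.mark.parametrize("removal", ["euler", "exact"])
    def test_stationarity_holds_under_both_discretizations(self, full_params, removal):
        traj = simulate_trajectory(
            ModelKind.TIF, full_params, np.zeros(60), perf0=312.5, removal=removal
        )
        assert np.all(traj.perf == 312.5)

    def test_zero_transformation_gain_freezes_performance(self, full_params):
        """With k_s2 = 0 production stays at baseline for any loads."""
        params = ModelParameters(k_off=0.03, k_s1=0.3, k_s2=0.0)
        loads = np.zeros(50)
        loads[1::3] = 300.0
        traj = simulate_trajectory(ModelKind.T, params, loads, perf0=250.0)
        assert np.all(traj.perf == 250.0)


class TestNestedReductions:
    def _loads(self):
        loads = np.zeros(80)
        loads[1::2] = 340.0
        return loads

    def test_ti_with_zero_inhibition_equals_t(self):
        loads = self._loads()
        base = dict(k_off=0.0305, k_s1=0.292, k_s2=0.0074)
        t = simulate_trajectory(ModelKind.T, ModelParameters(**base), loads, 250.0)
        ti = simulate_trajectory(
            ModelKind.TI, ModelParameters(**base, k_i=0.0), loads, 250.0
        )
        np.testing.assert_array_equal(t.perf, ti.perf)
        np.testing.assert_array_equal(t.observable, ti.observable)

    def test_tf_with_zero_fatigue_gain_equals_t(self):
        loads = self._loads()
        base = dict(k_off=0.0305, k_s1=0.292, k_s2=0.0074)
        t = simulate_trajectory(ModelKind.T, ModelParameters(**base), loads, 250.0)
        tf = simulate_trajectory(
            ModelKind.TF, ModelParameters(**base, k_f1=0.0, k_f2=0.5), loads, 250.0
        )
        np.testing.assert_array_equal(t.perf, tf.perf)
        np.testing.assert_array_equal(t.observable, tf.net_perf)

    def test_tif_reduces_to_tf_and_ti(self, full_params):
        loads = self._loads()
        tif_no_inhib = simulate_trajectory(
            ModelKind.TIF,
            ModelParameters(k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_i=0.0,
                            k_f1=0.1, k_f2=0.1),
            loads, 250.0,
        )
        tf = simulate_trajectory(
            ModelKind.TF,
            ModelParameters(k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_f1=0.1, k_f2=0.1),
            loads, 250.0,
        )
        np.testing.assert_array_equal(tif_no_inhib.net_perf, tf.net_perf)

        tif_no_fatigue = simulate_trajectory(
            ModelKind.TIF,
            ModelParameters(k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_i=0.0021,
                            k_f1=0.0, k_f2=0.1),
            loads, 250.0,
        )
        ti = simulate_trajectory(
            ModelKind.TI,
            ModelParameters(k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_i=0.0021),
            loads, 250.0,
        )
        np.testing.assert_array_equal(tif_no_fatigue.net_perf, ti.perf)


class TestOracles:
    def test_single_dose_matches_explicit_double_sum(self, median_ti_params):
        """One 200-tu dose on day 1 under Model T: recursion == direct sum."""
        loads = np.zeros(60)
        loads[1] = 200.0
        p = median_ti_params
        traj = simulate_trajectory(ModelKind.T, p, loads, 250.0)
        for day in range(2, 60):
            expected = 250.0 + p.k_s2 * 200.0 * sum(
                (1.0 - p.k_off) ** (day - 1 - m) * math.exp(-p.k_s1 * (m - 1))
                for m in range(1, day)
            )
            assert traj.perf[day] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        loads=st.lists(st.floats(0, 500), min_size=4, max_size=50),
        k_off=st.floats(0.005, 0.15),
        k_s1=st.floats(0.05, 1.5),
        k_s2=st.floats(1e-4, 0.05),
    )
    def test_recursion_equals_convolution_sum_oracle(self, loads, k_off, k_s1, k_s2):
        loads = np.array([0.0] + loads)
        params = ModelParameters(k_off=k_off, k_s1=k_s1, k_s2=k_s2)
        traj = simulate_trajectory(ModelKind.T, params, loads, 250.0)
        oracle = convolution_sum_perf(params, loads, 250.0)
        np.testing.assert_allclose(traj.perf, oracle, rtol=1e-9, atol=1e-9)

    def test_steady_state_matches_closed_form(self, median_ti_params):
        """Constant 250 tu/day under TI converges to the linear-recursion fixed point."""
        p = median_ti_params
        loads = np.full(3000, 250.0)
        loads[0] = 0.0
        traj = simulate_trajectory(ModelKind.TI, p, loads, 250.0)
        closed = 250.0 + p.k_s2 * (1 - p.k_i * 250.0) * (
            250.0 / (1 - math.exp(-p.k_s1))
        ) / p.k_off
        assert abs(traj.perf[-1] - closed) < 1e-6
        assert closed == pytest.approx(363.775, abs=0.01)


class TestLinearity:
    def test_superposition_under_model_t(self, rng):
        """Model T deviation responses add: response(a+b) = response(a)+response(b)."""
        params = ModelParameters(k_off=0.03, k_s1=0.3, k_s2=0.008)
        a = np.zeros(70)
        b = np.zeros(70)
        a[1:] = rng.uniform(0, 300, 69)
        b[1:] = rng.uniform(0, 300, 69)
        dev = lambda w: simulate_trajectory(ModelKind.T, params, w, 250.0).perf - 250.0
        np.testing.assert_allclose(dev(a + b), dev(a) + dev(b), rtol=1e-10, atol=1e-9)


class TestTrajectoryInvariants:
    def test_signal_decays_geometrically_on_rest_stretches(self, median_ti_params):
        loads = np.zeros(40)
        loads[1] = 300.0
        traj = simulate_trajectory(ModelKind.TI, median_ti_params, loads, 250.0)
        assert np.all(traj.signal >= 0)
        ratio = traj.signal[3:10] / traj.signal[2:9]
        np.testing.assert_allclose(ratio, math.exp(-median_ti_params.k_s1), rtol=1e-12)

    def test_inhibition_zero_on_rest_days_and_fatigue_starts_at_zero(self, full_params):
        loads = np.zeros(30)
        loads[5] = 300.0
        traj = simulate_trajectory(ModelKind.TIF, full_params, loads, 250.0)
        assert traj.fatigue[0] == 0.0
        assert np.all(traj.inhib[loads == 0] == 0.0)
        assert traj.inhib[5] == pytest.approx(full_params.k_i * 300.0)
        np.testing.assert_array_equal(traj.net_perf, traj.perf - traj.fatigue)


class TestRejections:
    def test_nonfinite_and_negative_inputs_rejected(self, median_ti_params):
        with pytest.raises(ValueError):
            simulate_trajectory(ModelKind.T, median_ti_params, [0, np.nan, 3], 250.0)
        with pytest.raises(ValueError):
            simulate_trajectory(ModelKind.T, median_ti_params, [0, -5.0], 250.0)
        with pytest.raises(ValueError):
            simulate_trajectory(ModelKind.T, median_ti_params, [0, 100.0], -10.0)
        with pytest.raises(ValueError):
            ModelParameters(k_off=-0.1, k_s1=0.3, k_s2=0.01)
        with pytest.raises(ValueError):
            ModelParameters(k_off=0.1, k_s1=0.3, k_s2=0.01, k_f1=0.1, k_f2=-0.2)

    def test_overdose_inhibition_is_not_an_error(self, median_ti_params):
        """Doses above 1/k_i legitimately give negative marginal production."""
        loads = np.zeros(10)
        loads[1] = 600.0  # > 1/0.0021
        traj = simulate_trajectory(ModelKind.TI, median_ti_params, loads, 250.0)
        assert traj.inhib[1] > 1.0
        assert np.all(np.isfinite(traj.perf))


class TestPredictAtMeasurements:
    def test_zero_load_series_predicts_baseline_everywhere(self):
        series = TrainingTimeSeries(
            loads=np.zeros(20),
            measurement_days=[0, 7, 14],
            measurements=[300.0, 299.0, 301.0],
        )
        params = ModelParameters(k_off=0.03, k_s1=0.3, k_s2=0.008)
        pred = predict_at_measurements(ModelKind.T, params, series)
        np.testing.assert_array_equal(pred, [300.0, 300.0, 300.0])

    def test_tf_with_zero_gain_predicts_like_t(self, noisy_ti_series):
        base = dict(k_off=0.0305, k_s1=0.292, k_s2=0.0074)
        pred_t = predict_at_measurements(
            ModelKind.T, ModelParameters(**base), noisy_ti_series
        )
        pred_tf = predict_at_measurements(
            ModelKind.TF, ModelParameters(**base, k_f1=0.0, k_f2=0.3), noisy_ti_series
        )
        np.testing.assert_array_equal(pred_t, pred_tf)

    def test_tif_one_step_hand_computation(self, full_params):
        """One 300-tu session on day 1, measurement day 2: net = Perf_2 - fatigue."""
        loads = np.zeros(3)
        loads[1] = 300.0
        series = TrainingTimeSeries(
            loads=loads, measurement_days=[0, 2], measurements=[250.0, 260.0]
        )
        p = full_params  # k_f1=0.1, k_f2=0.1
        pred = predict_at_measurements(ModelKind.TIF, p, series)
        traj = simulate_trajectory(ModelKind.TIF, p, loads, 250.0)
        expected_fatigue_2 = 0.1 * 300.0 * math.exp(-0.1)
        assert traj.fatigue[2] == pytest.approx(expected_fatigue_2, rel=1e-12)
        assert pred[1] == pytest.approx(traj.perf[2] - expected_fatigue_2, rel=1e-12)
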