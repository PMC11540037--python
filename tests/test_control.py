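"""Heater read-out (Kalman), calibration, and feed-forward/closed-loop
control, including the airflow-perturbation ablation."""

import numpy as np
import pytest

from fastnose.control import (CONSTANT, CYCLED, ControllerConfig, HeaterMode,
                              KalmanState, calibrate, estimate_rheat,
                              fit_openloop_map, heater_cycle_waveform,
                              run_calibration, simulate_hotplate)
from fastnose.pipeline import _settled_mask, run_control_ablation
from fastnose.sensor import heater_electrical


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_noise_free_calibration_inverts_heater_law_exactly(sensors):
    p = sensors[0]
    cal = run_calibration(p, ambient=25.0)
    a_true = 1.0 / (p.r_h0_ohm * p.alpha_h_per_degc)
    b_true = 25.0 - 1.0 / p.alpha_h_per_degc
    assert cal.a == pytest.approx(a_true, rel=1e-12)
    assert cal.b == pytest.approx(b_true, rel=1e-9)


def test_two_point_calibration_is_interpolating_line():
    cal = calibrate([1.0, 2.0], [40.0, 60.0], [150.0, 400.0])
    assert cal.temperature(40.0) == pytest.approx(150.0)
    assert cal.temperature(60.0) == pytest.approx(400.0)
    assert cal.temperature(50.0) == pytest.approx(275.0)


def test_rank_deficient_calibration_rejected():
    with pytest.raises(ValueError):
        fit_openloop_map([50.0, 50.0], [150.0, 150.0])
    with pytest.raises(ValueError):
        fit_openloop_map([50.0], [150.0])


def test_noisy_calibration_recovers_slope_within_3se(sensors):
    p = sensors[0]
    rng = np.random.default_rng(42)
    v_steps = np.linspace(0.9, 2.9, 10)
    cal = run_calibration(p, v_steps=v_steps, noise_sd_ohm=0.5, rng=rng)
    # regression oracle: ordinary least squares standard error of the slope
    r = cal.r_plateau
    t = cal.t_nominal
    slope, intercept = np.polyfit(r, t, 1)
    resid = t - (slope * r + intercept)
    se = np.sqrt(resid.var(ddof=2) / np.sum((r - r.mean()) ** 2))
    a_true = 1.0 / (p.r_h0_ohm * p.alpha_h_per_degc)
    assert abs(cal.a - a_true) < 3 * max(se, 1e-9) + 1e-9


def test_feed_forward_hits_targets_at_steady_state(sensors):
    from fastnose.sensor import steady_temperature
    p = sensors[0]
    cal = run_calibration(p)
    for target in (150.0, 400.0):
        v = float(cal.feed_forward(target))
        assert steady_temperature(v, p) == pytest.approx(target, abs=1.5)


# ---------------------------------------------------------------------------
# Kalman read-out
# ---------------------------------------------------------------------------

def test_kalman_converges_to_true_resistance_noise_free(sensors):
    p = sensors[0]
    T, v = 300.0, 2.0
    r_true, _, v_sense, _ = heater_electrical(T, v, p)
    state = KalmanState(estimate=np.array([30.0]), variance=np.array([100.0]))
    for _ in range(50):
        estimate_rheat(state, v, float(v_sense), 0.0, p.r_sense_ohm)
    assert state.estimate[0] == pytest.approx(float(r_true), rel=1e-6)


def test_degenerate_kalman_limits_track_measurement(sensors):
    p = sensors[0]
    state = KalmanState(estimate=np.array([10.0]), variance=np.array([1.0]),
                        q=0.0, r0=1e-15)
    r_true, _, v_sense, _ = heater_electrical(350.0, 2.2, p)
    est = estimate_rheat(state, 2.2, float(v_sense), 0.0, p.r_sense_ohm)
    assert est[0] == pytest.approx(float(r_true), rel=1e-9)


def test_kalman_variance_non_increasing_under_constant_drive():
    state = KalmanState(estimate=np.array([50.0]), variance=np.array([100.0]),
                        q=1.0, r0=0.5)
    prev = state.variance.copy()
    for _ in range(100):
        estimate_rheat(state, 2.0, 0.3, 0.0, 10.0)
        assert state.variance[0] <= prev[0] + 1e-12
        prev = state.variance.copy()


def test_kalman_skips_update_on_nonpositive_sense_voltage():
    state = KalmanState(estimate=np.array([50.0]), variance=np.array([1.0]))
    est = estimate_rheat(state, 2.0, 0.0, 0.0, 10.0)
    assert est[0] == 50.0


def test_kalman_beats_naive_division_during_dac_steps(sensors):
    """During control-voltage steps the settling transient biases the naive
    divider estimate; the transient-aware Kalman filter tracks ground truth
    with lower RMSE over the post-step samples."""
    modes = [HeaterMode(CYCLED)] * len(sensors)
    trace = simulate_hotplate(sensors, modes, 2000, seed=0)
    v_sense = trace.v_sense
    naive = np.where(v_sense > 0,
                     (trace.v_dac - v_sense) * sensors[0].r_sense_ohm
                     / np.where(v_sense > 0, v_sense, 1.0), 0.0)
    steps = np.nonzero(np.abs(np.diff(trace.t_target[0])) > 0)[0]
    post = np.unique(np.concatenate([steps + 1 + k for k in range(5)]))
    post = post[post < trace.r_true.shape[1]]
    rmse_naive = np.sqrt(np.mean((naive[:, post] - trace.r_true[:, post]) ** 2))
    rmse_kalman = np.sqrt(np.mean((trace.r_hat[:, post]
                                   - trace.r_true[:, post]) ** 2))
    assert rmse_kalman < rmse_naive


# ---------------------------------------------------------------------------
# target waveforms and closed-loop behavior
# ---------------------------------------------------------------------------

def test_cycled_waveform_has_two_periods_in_100ms():
    w = heater_cycle_waveform(HeaterMode(CYCLED), 100, fs=1000)
    assert w[0] == 150.0 and w[25] == 400.0 and w[50] == 150.0 and w[75] == 400.0
    assert np.mean(w == 400.0) == 0.5               # 50% high-phase duty


def test_constant_waveform_is_flat():
    w = heater_cycle_waveform(HeaterMode(CONSTANT), 500, fs=1000)
    assert np.all(np.diff(w) == 0.0) and w[0] == 400.0


def test_control_step_pure_feedforward_when_on_target(sensors):
    from fastnose.control import ControllerState
    p = sensors[0]
    cal = run_calibration(p)
    state = ControllerState(mode=HeaterMode(CYCLED), calibration=cal,
                            config=ControllerConfig())
    v1 = state.control_step(400.0, 400.0, 1e-3)
    assert v1 == pytest.approx(float(cal.feed_forward(400.0)))
    # persistent error accumulates into the correction at the adaptation rate
    v2 = state.control_step(400.0, 390.0, 1e-3)
    assert v2 - v1 == pytest.approx(0.1 * 10.0 * 1e-3)
    # frozen (in-stimulus, constant mode) steps do not update the correction
    v3 = state.control_step(400.0, 300.0, 1e-3, frozen=True)
    assert v3 == pytest.approx(v2)
    # clamping to the DAC range is logged, not silent
    state.correction_v = 10.0
    v4 = state.control_step(400.0, 400.0, 1e-3, frozen=True)
    assert v4 == ControllerConfig().dac_full_scale_v
    assert state.clamp_events == 1


def test_zero_adaptation_rate_reduces_to_open_loop(sensors):
    modes = [HeaterMode(CYCLED)] * len(sensors)
    a = simulate_hotplate(sensors, modes, 500, seed=0,
                          config=ControllerConfig(adaptation_rate=0.0))
    b = simulate_hotplate(sensors, modes, 500, seed=0,
                          config=ControllerConfig(closed_loop=False))
    np.testing.assert_array_equal(a.v_dac, b.v_dac)


def test_closed_loop_plateau_error_below_one_degree(sensors):
    modes = [HeaterMode(CYCLED)] * len(sensors)
    trace = simulate_hotplate(sensors, modes, 2000, seed=0)
    err = trace.t_true - trace.t_target
    settled = _settled_mask(trace.t_target[0], 1000, settle_ms=15.0)
    for level in (150.0, 400.0):
        m = settled & (trace.t_target[0] == level)
        assert np.mean(np.abs(err[:, m])) < 1.0


def test_constant_mode_freezes_dac_during_stimulus(sensors):
    modes = [HeaterMode(CONSTANT)] * len(sensors)
    trace = simulate_hotplate(sensors, modes, 3000, seed=0,
                              freeze_window=(1.0, 2.0))
    frozen = trace.v_dac[:, 1050:1950]
    assert np.all(np.var(frozen, axis=1) == 0.0)


def test_closed_loop_beats_open_loop_under_airflow_perturbation():
    res = run_control_ablation(seed=0, duration_s=4.0, perturb=(1.0, 3.0))
    assert (res["closed_loop"]["mean_abs_error_perturbed"]
            < res["open_loop"]["mean_abs_error_perturbed"])
    assert (res["closed_loop"]["mean_abs_error_overall"]
            < res["open_loop"]["mean_abs_error_overall"])
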