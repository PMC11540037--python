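"""Hotplate temperature read-out and control.

Temperature is read out electrically: the heater resistance follows
``R_heat = (V_DAC - V_sense) * R_sense / V_sense``, but the sample acquired
immediately after a control-voltage change is corrupted by DAC/amplifier
settling transients.  A scalar Kalman filter therefore tracks ``R_heat`` with
measurement variance inflated proportionally to ``|dV_DAC/dt|``, so post-step
samples are effectively ignored.

Control combines a feed-forward (open-loop) term -- a lookup of the DAC
voltage whose steady-state temperature equals the target, built during a
power-step calibration that also fits the linear resistance-to-temperature
map ``T = a * R_heat + b`` -- with a slow integral correction: the
temperature error is accumulated into the control voltage at a fixed
adaptation rate (default 0.1 V per degC per s).  In constant-heat mode the
correction (and hence the DAC code) is frozen during each stimulus and
updated only in between, to keep converter quantization transients out of
the signal band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._signal import quantize
from .sensor import SensorParams, heater_electrical, hotplate_step, steady_temperature

CYCLED = "cycled"
CONSTANT = "constant"


@dataclass(frozen=True)
class HeaterMode:
    """Target-temperature program for one sensor."""

    kind: str = CYCLED
    t_low_degc: float = 150.0
    t_high_degc: float = 400.0
    period_ms: float = 50.0
    t_const_degc: float = 400.0

    def __post_init__(self):
        if self.kind not in (CYCLED, CONSTANT):
            raise ValueError(f"unknown heater mode: {self.kind!r}")
        if self.kind == CYCLED and self.period_ms <= 0:
            raise ValueError("cycle period must be positive")

    @property
    def key(self):
        return (self.kind, self.t_low_degc, self.t_high_degc,
                self.period_ms, self.t_const_degc)


def heater_cycle_waveform(mode: HeaterMode, n: int, fs: int = 1000,
                          phase_sample: int = 0) -> np.ndarray:
    """Target temperature trajectory: cycled modes spend the first half-period
    at the low step and the second half at the high step; constant modes are
    flat."""
    if mode.kind == CONSTANT:
        return np.full(n, mode.t_const_degc)
    period = int(round(mode.period_ms / 1000.0 * fs))
    half = period // 2
    idx = (np.arange(n) + phase_sample) % period
    return np.where(idx < half, mode.t_low_degc, mode.t_high_degc)


def experiment_modes(experiment: str) -> list:
    """Per-sensor heater conditions of the three standard experiments:
    A = all eight sensors cycled 150-400 degC at 50 ms; B = sensors 1-4
    constant 400 degC, 5-8 cycled; C = as B but with 200 ms cycles on 5-8."""
    cyc = HeaterMode(CYCLED)
    const = HeaterMode(CONSTANT)
    if experiment == "A":
        return [cyc] * 8
    if experiment == "B":
        return [const] * 4 + [cyc] * 4
    if experiment == "C":
        return [const] * 4 + [HeaterMode(CYCLED, period_ms=200.0)] * 4
    raise ValueError(f"unknown experiment: {experiment!r}")


# ---------------------------------------------------------------------------
# Kalman read-out
# ---------------------------------------------------------------------------

@dataclass
class KalmanState:
    """Scalar random-walk Kalman filter over the heater resistance."""

    estimate: np.ndarray        # R_hat, Ohm (per sensor)
    variance: np.ndarray
    q: float = 10.0             # process noise, Ohm^2 per step
    r0: float = 0.5             # base measurement variance, Ohm^2
    kappa: float = 2.0          # uncertainty scaling vs |dV_DAC/dt| (s/V)

    def __post_init__(self):
        self.estimate = np.atleast_1d(np.asarray(self.estimate, dtype=float))
        self.variance = np.atleast_1d(np.asarray(self.variance, dtype=float))
        if np.any(self.variance < 0) or self.q < 0 or self.r0 < 0:
            raise ValueError("variances must be non-negative")


def estimate_rheat(state: KalmanState, v_dac, v_sense, dv_dac_dt,
                   r_sense) -> np.ndarray:
    """One predict/update step from the divider measurement.

    The raw measurement is ``z = (V_DAC - V_sense) R_sense / V_sense`` with
    variance ``r0 * (1 + kappa * |dV_DAC/dt|)``.  Channels with a
    non-positive sense voltage skip the update (predict only).
    """
    v_dac = np.atleast_1d(np.asarray(v_dac, dtype=float))
    v_sense = np.atleast_1d(np.asarray(v_sense, dtype=float))
    dv = np.atleast_1d(np.asarray(dv_dac_dt, dtype=float))
    state.variance = state.variance + state.q
    ok = v_sense > 0
    safe = np.where(ok, v_sense, 1.0)
    z = (v_dac - v_sense) * r_sense / safe
    r = state.r0 * (1.0 + state.kappa * np.abs(dv))
    gain = np.where(ok, state.variance / (state.variance + r), 0.0)
    state.estimate = state.estimate + gain * (z - state.estimate)
    state.variance = (1.0 - gain) * state.variance
    return state.estimate


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """Linear open-loop map T = a R_heat + b plus the feed-forward inverse."""

    a: float
    b: float
    v_steps: np.ndarray
    r_plateau: np.ndarray
    t_nominal: np.ndarray
    _ff: PchipInterpolator = field(repr=False, default=None)

    def temperature(self, r_heat):
        return self.a * np.asarray(r_heat) + self.b

    def feed_forward(self, t_target):
        """DAC voltage whose calibrated steady state hits ``t_target``."""
        return np.asarray(self._ff(np.asarray(t_target)), dtype=float)


def fit_openloop_map(measured_r_heat, measured_t_nominal):
    """Least-squares line through (plateau resistance, nominal temperature)
    pairs.  Rejects rank-deficient input (fewer than two distinct steps)."""
    r = np.asarray(measured_r_heat, dtype=float)
    t = np.asarray(measured_t_nominal, dtype=float)
    if r.size < 2 or np.ptp(r) <= 1e-12 * max(1.0, np.abs(r).max()):
        raise ValueError("calibration needs at least two distinct power steps")
    a, b = np.polyfit(r, t, 1)
    return float(a), float(b)


def calibrate(power_steps_v, measured_r_heat, measured_t_nominal) -> Calibration:
    """Build the open-loop model from plateau measurements at a set of DAC
    voltages, and cache the monotone feed-forward lookup V_DAC(T_target)."""
    a, b = fit_openloop_map(measured_r_heat, measured_t_nominal)
    v = np.asarray(power_steps_v, dtype=float)
    t = np.asarray(measured_t_nominal, dtype=float)
    order = np.argsort(t)
    ff = PchipInterpolator(t[order], v[order], extrapolate=True)
    return Calibration(a=a, b=b, v_steps=v,
                       r_plateau=np.asarray(measured_r_heat, dtype=float),
                       t_nominal=t, _ff=ff)


def run_calibration(params: SensorParams, ambient: float = 25.0,
                    v_steps=None, r_th_datasheet: float | None = None,
                    noise_sd_ohm: float = 0.0, rng=None) -> Calibration:
    """Power-step calibration protocol against one simulated heater.

    Each DAC step is held to its thermal plateau; the plateau resistance is
    read from the divider and matched with the datasheet's nominal
    temperature rise per unit heating power (``r_th_datasheet``, defaulting
    to the true thermal resistance).  Optional Gaussian noise on the measured
    plateau resistance models read-out error.
    """
    if v_steps is None:
        v_steps = np.geomspace(0.9, 2.95, 5)
    v_steps = np.asarray(v_steps, dtype=float)
    r_th_nom = params.r_th_degc_per_w if r_th_datasheet is None else r_th_datasheet
    r_meas, t_nom = [], []
    rng = np.random.default_rng(0) if rng is None else rng
    for v in v_steps:
        t_ss = steady_temperature(v, params, ambient)
        r_heat, _, _, p_heat = heater_electrical(t_ss, v, params, ambient)
        r = float(r_heat)
        if noise_sd_ohm > 0:
            r += rng.normal(0.0, noise_sd_ohm)
        r_meas.append(r)
        t_nom.append(ambient + float(p_heat) * r_th_nom)
    return calibrate(v_steps, r_meas, t_nom)


# ---------------------------------------------------------------------------
# closed-loop control
# ---------------------------------------------------------------------------

@dataclass
class ControllerConfig:
    adaptation_rate: float = 0.1      # V per degC per s
    kalman_q: float = 10.0
    kalman_r0: float = 0.5
    kalman_kappa: float = 2.0
    dac_bits: int = 12
    dac_full_scale_v: float = 3.0
    vsense_sigma_v: float = 2.0e-4    # sense-channel measurement noise
    settling_gain: float = 0.3        # V_sense transient per V of DAC step
    settle_ms: float = 12.0           # anti-windup: no integration right after a target step
    closed_loop: bool = True

    def __post_init__(self):
        if self.adaptation_rate < 0:
            raise ValueError("adaptation rate must be non-negative")


@dataclass
class ControllerState:
    """Per-sensor control-loop state."""

    mode: HeaterMode
    calibration: Calibration
    config: ControllerConfig
    correction_v: float = 0.0
    clamp_events: int = 0

    def control_step(self, target_t: float, measured_t: float, dt: float,
                     frozen: bool = False) -> float:
        """Feed-forward plus accumulated integral correction; in constant mode
        ``frozen=True`` suppresses the correction update during a stimulus."""
        if self.config.closed_loop and not frozen:
            self.correction_v += (self.config.adaptation_rate
                                  * (target_t - measured_t) * dt)
        v = float(self.calibration.feed_forward(target_t)) + self.correction_v
        hi = self.config.dac_full_scale_v
        if v < 0.0 or v > hi:
            self.clamp_events += 1
            v = min(max(v, 0.0), hi)
        return v


@dataclass
class HeaterTrace:
    """Result of the heater-only closed-loop co-simulation."""

    fs: int
    t_true: np.ndarray          # (S, N)
    t_meas: np.ndarray
    t_target: np.ndarray
    v_dac: np.ndarray
    v_sense: np.ndarray
    r_hat: np.ndarray
    r_true: np.ndarray
    modes: tuple
    calibrations: tuple
    clamp_events: int = 0


def simulate_hotplate(sensors, modes, n_samples: int, fs: int = 1000,
                      oversample: int = 10, ambient: float = 25.0,
                      airflow=1.0, config: ControllerConfig = None,
                      calibrations=None, warmup_s: float = 2.0,
                      freeze_window=None, seed: int = 0) -> HeaterTrace:
    """Co-simulate hotplates and their temperature control loops.

    Controllers run at the 1 kHz acquisition rate; the thermal ODE is
    integrated with ``oversample`` Euler sub-steps (0.1 ms).  ``airflow`` is a
    scalar or per-sample array scaling the thermal loss (1/R_th).
    ``freeze_window`` is an optional ``(t0_s, t1_s)`` interval, in recording
    time, during which constant-mode controllers hold their DAC code fixed
    (the in-stimulus freeze).  A warm-up covering an integer number of heater
    cycles precedes the recorded window so the cycle phase is anchored at
    t = 0.
    """
    config = ControllerConfig() if config is None else config
    S = len(sensors)
    if len(modes) != S:
        raise ValueError("one heater mode per sensor required")
    if calibrations is None:
        calibrations = [run_calibration(p, ambient) for p in sensors]
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    dt_sub = dt / oversample
    # warm-up length: integer multiple of every cycled period
    periods = [int(round(m.period_ms / 1000.0 * fs)) for m in modes
               if m.kind == CYCLED]
    base = int(np.lcm.reduce(periods)) if periods else 1
    n_warm = int(np.ceil(warmup_s * fs / base)) * base
    n_tot = n_warm + n_samples

    targets = np.stack([heater_cycle_waveform(m, n_tot, fs) for m in modes])
    # anti-windup gate: the thermal transient right after a target step is not
    # a tracking error the slow integrator should absorb
    n_settle = int(round(config.settle_ms / 1000.0 * fs))
    integrate_ok = np.ones_like(targets, dtype=bool)
    if n_settle > 0:
        stepped = np.diff(targets, axis=1) != 0
        for s, row in enumerate(stepped):
            for i in np.nonzero(row)[0]:
                integrate_ok[s, i + 1:i + 1 + n_settle] = False
    ff_v = np.stack([c.feed_forward(targets[s])
                     for s, c in enumerate(calibrations)])
    a_cal = np.array([c.a for c in calibrations])
    b_cal = np.array([c.b for c in calibrations])
    r_sense = np.array([p.r_sense_ohm for p in sensors])
    r_h0 = np.array([p.r_h0_ohm for p in sensors])
    alpha_h = np.array([p.alpha_h_per_degc for p in sensors])
    c_th = np.array([p.c_th_j_per_degc for p in sensors])
    r_th = np.array([p.r_th_degc_per_w for p in sensors])
    const_mask = np.array([m.kind == CONSTANT for m in modes])

    if np.isscalar(airflow):
        airflow_arr = np.full(n_samples, float(airflow))
    else:
        airflow_arr = np.asarray(airflow, dtype=float)
        if airflow_arr.size != n_samples:
            raise ValueError("airflow array must match n_samples")
    freeze = np.zeros(n_tot, dtype=bool)
    if freeze_window is not None:
        f0 = n_warm + int(round(freeze_window[0] * fs))
        f1 = n_warm + int(round(freeze_window[1] * fs))
        freeze[max(f0, 0):min(f1, n_tot)] = True

    # initial state: at the first target's steady point
    T = np.array([steady_temperature(ff_v[s, 0], sensors[s], ambient)
                  for s in range(S)])
    corr = np.zeros(S)
    kal = KalmanState(estimate=r_h0 * (1.0 + alpha_h * (T - ambient)),
                      variance=np.full(S, 100.0), q=config.kalman_q,
                      r0=config.kalman_r0, kappa=config.kalman_kappa)
    t_meas = a_cal * kal.estimate + b_cal
    v_prev = ff_v[:, 0].copy()
    clamps = 0
    rate = config.adaptation_rate if config.closed_loop else 0.0
    lsb = config.dac_full_scale_v / 2 ** config.dac_bits
    noise = rng.normal(0.0, config.vsense_sigma_v, (n_tot, S)) \
        if config.vsense_sigma_v > 0 else np.zeros((n_tot, S))

    out = {k: np.empty((S, n_samples)) for k in
           ("t_true", "t_meas", "t_target", "v_dac", "v_sense", "r_hat", "r_true")}

    for k in range(n_tot):
        upd = ~(const_mask & freeze[k]) & integrate_ok[:, k]
        corr = corr + np.where(upd, rate * (targets[:, k] - t_meas) * dt, 0.0)
        v = ff_v[:, k] + corr
        clamps += int(np.sum((v < 0) | (v > config.dac_full_scale_v)))
        v = np.clip(v, 0.0, config.dac_full_scale_v)
        v = np.round(v / lsb) * lsb
        dv = v - v_prev
        af = airflow_arr[min(max(k - n_warm, 0), n_samples - 1)]
        for _ in range(oversample):
            r_heat = r_h0 * (1.0 + alpha_h * (T - ambient))
            i = v / (r_heat + r_sense)
            p_heat = i * i * r_heat
            T = T + dt_sub * (p_heat - (T - ambient) * af / r_th) / c_th
        r_heat = r_h0 * (1.0 + alpha_h * (T - ambient))
        v_sense_true = v * r_sense / (r_heat + r_sense)
        v_sense_meas = v_sense_true - config.settling_gain * dv + noise[k]
        estimate_rheat(kal, v, v_sense_meas, dv / dt, r_sense)
        t_meas = a_cal * kal.estimate + b_cal
        v_prev = v
        if k >= n_warm:
            j = k - n_warm
            out["t_true"][:, j] = T
            out["t_meas"][:, j] = t_meas
            out["t_target"][:, j] = targets[:, k]
            out["v_dac"][:, j] = v
            out["v_sense"][:, j] = v_sense_meas
            out["r_hat"][:, j] = kal.estimate
            out["r_true"][:, j] = r_heat

    return HeaterTrace(fs=fs, modes=tuple(modes),
                       calibrations=tuple(calibrations),
                       clamp_events=clamps, **out)
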