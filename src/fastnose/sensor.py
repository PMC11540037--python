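"""MOx sensor and micro-hotplate physics.

The film model combines an exponential resistance-temperature baseline with a
Langmuir-style gas term:

    R = R_ref * exp(-beta * (T - T_ref)) / (1 + sum_i s_i * theta_i) ** alpha

where ``theta_i`` is the fractional surface coverage of odorant ``i``,
integrated from first-order adsorption/desorption kinetics with
Arrhenius-type rate constants

    d theta / dt = k_a(T) * c * (1 - theta) - k_d(T) * theta,
    k(T) = k0 * exp(-E / (T + 273.15)).

The hotplate is a lumped thermal mass: ``C_th dT/dt = P_heat - (T - T_amb)
* airflow / R_th`` with the heater's quasi-linear resistance-temperature law
``R_heat = R_h0 (1 + alpha_h (T - T_amb))`` and a resistive divider
(``R_sense``) for current read-out.  Converters add 12-bit DAC / 24-bit ADC
quantization, Gaussian noise and slow multiplicative baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from ._signal import first_order_lowpass, quantize

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class SensorParams:
    """Physical constants of one simulated sensor (film + hotplate)."""

    name: str
    r_ref_ohm: float
    beta_per_degc: float
    t_ref_degc: float
    sensitivity: dict                 # odorant name -> dimensionless coefficient
    alpha: float
    k_a0_per_s: float
    k_d0_per_s: float
    e_a_kelvin: float
    e_d_kelvin: float
    tau_film_ms: float
    r_h0_ohm: float
    alpha_h_per_degc: float
    c_th_j_per_degc: float
    r_th_degc_per_w: float
    r_sense_ohm: float

    def __post_init__(self):
        for attr in ("r_ref_ohm", "beta_per_degc", "alpha", "k_a0_per_s",
                     "k_d0_per_s", "e_a_kelvin", "e_d_kelvin", "tau_film_ms",
                     "r_h0_ohm", "alpha_h_per_degc", "c_th_j_per_degc",
                     "r_th_degc_per_w", "r_sense_ohm"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if any(v < 0 for v in self.sensitivity.values()):
            raise ValueError("sensitivities must be non-negative")

    def sensitivity_vector(self, odorant_names) -> np.ndarray:
        return np.array([self.sensitivity.get(n, 0.0) for n in odorant_names])


def default_sensor_array(n: int = 8, seed: int | None = None) -> list:
    """The default 8-sensor array: four base types tiled twice with
    deterministic multiplicative jitter (reproducible for a given seed)."""
    ref = resources.files("fastnose.data") / "sensor_defaults.yaml"
    doc = yaml.safe_load(ref.read_text())
    common = doc["common"]
    types = doc["types"]
    layout = doc["layout"]
    jit = doc["jitter_fraction"]
    hjit = doc["heater_jitter_fraction"]
    rng = np.random.default_rng(doc["jitter_seed"] if seed is None else seed)
    sensors = []
    for i in range(n):
        t = types[layout[i % len(layout)]]
        sens = {k: v * (1.0 + rng.uniform(-jit, jit))
                for k, v in t["sensitivity"].items()}
        sensors.append(SensorParams(
            name=f"s{i + 1}_{t['name']}",
            r_ref_ohm=t["r_ref_ohm"] * (1.0 + rng.uniform(-0.1, 0.1)),
            beta_per_degc=common["beta_per_degc"],
            t_ref_degc=common["t_ref_degc"],
            sensitivity=sens,
            alpha=common["alpha"],
            k_a0_per_s=t["k_a0_per_s"] * (1.0 + rng.uniform(-jit, jit)),
            k_d0_per_s=t["k_d0_per_s"] * (1.0 + rng.uniform(-jit, jit)),
            e_a_kelvin=common["e_a_kelvin"],
            e_d_kelvin=common["e_d_kelvin"],
            tau_film_ms=common["tau_film_ms"],
            r_h0_ohm=common["r_h0_ohm"] * (1.0 + rng.uniform(-hjit, hjit)),
            alpha_h_per_degc=common["alpha_h_per_degc"],
            c_th_j_per_degc=common["c_th_j_per_degc"],
            r_th_degc_per_w=common["r_th_degc_per_w"] * (1.0 + rng.uniform(-hjit, hjit)),
            r_sense_ohm=common["r_sense_ohm"],
        ))
    return sensors


# ---------------------------------------------------------------------------
# hotplate electro-thermal model
# ---------------------------------------------------------------------------

def heater_electrical(T, v_dac, params: SensorParams, ambient: float = 25.0):
    """Heater divider at temperature ``T``: returns (R_heat, I, V_sense, P_heat)."""
    r_heat = params.r_h0_ohm * (1.0 + params.alpha_h_per_degc * (np.asarray(T) - ambient))
    i = np.asarray(v_dac) / (r_heat + params.r_sense_ohm)
    v_sense = i * params.r_sense_ohm
    p_heat = i * i * r_heat
    return r_heat, i, v_sense, p_heat


def hotplate_step(T, v_dac, dt: float, params: SensorParams,
                  ambient: float = 25.0, airflow_factor: float = 1.0):
    """One explicit-Euler step of the lumped thermal model (``dt`` in s,
    intended for the 10 kHz internal rate)."""
    if dt > 1e-4 + 1e-12:
        raise ValueError("hotplate integration requires dt <= 0.1 ms")
    _, _, _, p_heat = heater_electrical(T, v_dac, params, ambient)
    loss = (np.asarray(T) - ambient) * airflow_factor / params.r_th_degc_per_w
    return T + dt * (p_heat - loss) / params.c_th_j_per_degc


def steady_temperature(v_dac: float, params: SensorParams,
                       ambient: float = 25.0, airflow_factor: float = 1.0) -> float:
    """Steady state of the hotplate ODE (root of power balance)."""
    from scipy.optimize import brentq
    if v_dac <= 0:
        return ambient

    def f(T):
        _, _, _, p = heater_electrical(T, v_dac, params, ambient)
        return p - (T - ambient) * airflow_factor / params.r_th_degc_per_w

    hi = ambient + (v_dac ** 2 / params.r_h0_ohm) * params.r_th_degc_per_w / airflow_factor
    return float(brentq(f, ambient, hi + 1.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# film and adsorption kinetics
# ---------------------------------------------------------------------------

def adsorption_rates(T, params: SensorParams):
    """Arrhenius rate constants (k_a, k_d) at hotplate temperature ``T`` (degC)."""
    tk = np.asarray(T, dtype=float) + KELVIN_OFFSET
    k_a = params.k_a0_per_s * np.exp(-params.e_a_kelvin / tk)
    k_d = params.k_d0_per_s * np.exp(-params.e_d_kelvin / tk)
    return k_a, k_d


def adsorption_step(coverage, concentration, T, dt: float, params: SensorParams):
    """Exact one-step update of the Langmuir kinetics for constant inputs over
    ``dt`` (s, <= 1 ms): relax toward theta* = k_a c / (k_a c + k_d)."""
    if dt > 1e-3 + 1e-12:
        raise ValueError("adsorption integration requires dt <= 1 ms")
    k_a, k_d = adsorption_rates(T, params)
    c = np.asarray(concentration, dtype=float)
    rate = k_a * c + k_d
    theta_star = np.where(rate > 0, k_a * c / np.where(rate > 0, rate, 1.0), 0.0)
    theta = theta_star + (np.asarray(coverage) - theta_star) * np.exp(-rate * dt)
    return np.clip(theta, 0.0, 1.0)


def film_resistance(T, coverage_vector, params: SensorParams,
                    odorant_names=None):
    """Instantaneous film resistance at temperature ``T`` with surface
    coverages ``coverage_vector`` (ordered like ``odorant_names`` or like
    ``params.sensitivity``)."""
    cov = np.asarray(coverage_vector, dtype=float)
    if np.any((cov < 0) | (cov > 1)):
        raise ValueError("coverages must lie in [0, 1]")
    if odorant_names is None:
        odorant_names = list(params.sensitivity)
    s = params.sensitivity_vector(odorant_names)
    load = float(np.dot(s, cov))
    denom = 1.0 + load
    if denom <= 0:
        raise ValueError("gas load drives the film denominator non-positive")
    return params.r_ref_ohm * np.exp(
        -params.beta_per_degc * (np.asarray(T) - params.t_ref_degc)) / denom ** params.alpha


def gas_response(t_true: np.ndarray, conc: np.ndarray, odorant_names,
                 sensors, fs: int = 1000, kinetics_scale=None,
                 response_scale=None, baseline_scale=None) -> np.ndarray:
    """Film resistance time series for the whole array.

    ``t_true``: (S, N) hotplate temperatures; ``conc``: (K, N) odorant
    concentrations.  Integrates the coverage kinetics with the exact
    exponential step at the acquisition rate, applies the film law and the
    film low-pass.  ``kinetics_scale`` (per sensor) scales k_a and k_d
    jointly, shifting the response time constant without moving the steady
    state -- the surface-state variability of real MOx films.
    ``response_scale`` scales each sensor's gas load (response-amplitude
    variability) and ``baseline_scale`` its clean-air baseline.  Returns
    resistances (S, N).
    """
    S, N = t_true.shape
    K = conc.shape[0]
    dt = 1.0 / fs
    sens = np.array([p.sensitivity_vector(odorant_names) for p in sensors])  # (S, K)
    if response_scale is not None:
        sens = sens * np.asarray(response_scale, dtype=float)[:, None]
    ka = np.empty((S, N))
    kd = np.empty((S, N))
    for s, p in enumerate(sensors):
        ka[s], kd[s] = adsorption_rates(t_true[s], p)
    if kinetics_scale is not None:
        scale = np.asarray(kinetics_scale, dtype=float)[:, None]
        ka = ka * scale
        kd = kd * scale
    rate = ka[:, None, :] * conc[None, :, :] + kd[:, None, :]          # (S, K, N)
    decay = np.exp(-rate * dt)
    theta_star = ka[:, None, :] * conc[None, :, :] / rate
    theta = np.zeros((S, K))
    load = np.empty((S, N))
    for n in range(N):
        theta = theta_star[:, :, n] + (theta - theta_star[:, :, n]) * decay[:, :, n]
        load[:, n] = (sens * theta).sum(axis=1)
    if np.any(1.0 + load <= 0):
        raise ValueError("gas load drives the film denominator non-positive")
    r_ref = np.array([p.r_ref_ohm for p in sensors])[:, None]
    if baseline_scale is not None:
        r_ref = r_ref * np.asarray(baseline_scale, dtype=float)[:, None]
    beta = np.array([p.beta_per_degc for p in sensors])[:, None]
    t_ref = np.array([p.t_ref_degc for p in sensors])[:, None]
    alpha = np.array([p.alpha for p in sensors])[:, None]
    r = r_ref * np.exp(-beta * (t_true - t_ref)) / (1.0 + load) ** alpha
    out = np.empty_like(r)
    for s, p in enumerate(sensors):
        out[s] = first_order_lowpass(r[s], dt, p.tau_film_ms / 1000.0)
    return out


# ---------------------------------------------------------------------------
# recording container and digitization
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Converter and noise model shared across the array."""

    gas_sigma_ohm: float = 30.0       # additive ADC-referred noise on the gas channel
    gas_full_scale_ohm: float = 1.0e7
    adc_bits: int = 24
    dac_bits: int = 12
    dac_full_scale_v: float = 3.0
    vsense_sigma_v: float = 2.0e-4
    pid_sigma: float = 0.005
    drift_per_hour: float = 0.4       # log-linear baseline drift rate


@dataclass
class Recording:
    """Lockstep 1 kHz multichannel recording of one trial."""

    fs: int
    time: np.ndarray            # (N,) seconds from recording start
    gas: np.ndarray             # (S, N) film resistance, Ohm
    temp: np.ndarray            # (S, N) measured hotplate temperature, degC
    temp_target: np.ndarray     # (S, N) commanded temperature, degC
    vdac: np.ndarray            # (S, N) heater control voltage, V
    vsense: np.ndarray          # (S, N) sense-divider voltage, V
    conc: np.ndarray            # (K, N) true odorant concentration, a.u.
    pid: np.ndarray             # (N,) PID ground-truth channel
    odorants: tuple             # names for the conc rows
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.time.size
        for name in ("gas", "temp", "temp_target", "vdac", "vsense"):
            if getattr(self, name).shape[-1] != n:
                raise ValueError(f"channel {name} is not lockstep with time")
        if self.conc.size and self.conc.shape[-1] != n:
            raise ValueError("conc channel is not lockstep with time")
        if self.pid.size != n:
            raise ValueError("pid channel is not lockstep with time")

    @property
    def n_sensors(self) -> int:
        return self.gas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def t_onset_s(self) -> float:
        return self.meta["t_onset_s"]

    @property
    def t_offset_s(self) -> float:
        return self.meta["t_onset_s"] + self.meta["duration_ms"] / 1000.0


def digitize(recording: Recording, noise: NoiseConfig = None, rng=None,
             experiment_time_s: float = 0.0) -> Recording:
    """Apply drift, converter noise and quantization to an ideal recording.

    Gas channels gain a slow multiplicative baseline drift
    ``exp(drift_per_hour * t_experiment / 3600)``, additive Gaussian noise and
    24-bit quantization over the configured full scale; heater control
    voltages are re-quantized to the 12-bit DAC grid.  Clipped sample counts
    are recorded in ``meta['clipped_samples']``, never silently dropped.
    """
    noise = NoiseConfig() if noise is None else noise
    rng = np.random.default_rng() if rng is None else rng
    t_exp_h = (experiment_time_s + recording.time) / 3600.0
    gas = recording.gas * np.exp(noise.drift_per_hour * t_exp_h)[None, :]
    if noise.gas_sigma_ohm > 0:
        gas = gas + rng.normal(0.0, noise.gas_sigma_ohm, gas.shape)
    gas, clipped_gas = quantize(gas, noise.gas_full_scale_ohm, noise.adc_bits)
    vdac, clipped_dac = quantize(recording.vdac, noise.dac_full_scale_v,
                                 noise.dac_bits)
    meta = dict(recording.meta)
    meta["clipped_samples"] = int(clipped_gas + clipped_dac)
    meta["experiment_time_s"] = experiment_time_s
    return replace(recording, gas=gas, vdac=vdac, meta=meta)
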