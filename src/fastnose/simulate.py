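"""End-to-end trial simulation: stimulus -> transport -> adsorption -> film
-> digitization, with the heater control loop running in closed loop.

The hotplate trajectory does not depend on the delivered gas (airflow is
compensated by the olfactometer), so one heater co-simulation per heater
configuration and recording length is shared across the trials of a
protocol, exactly as a physical heater runs continuously across trials.
Stimulus onsets are jittered uniformly within one heater cycle relative to
the acquisition clock: odor delivery is not synchronized with the heater
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._signal import first_order_lowpass
from . import control as ctl
from . import stimulus as stim
from .panel import OdorantPanel
from .protocol import Trial
from .sensor import NoiseConfig, Recording, default_sensor_array, gas_response

SCHEMA_VERSION = 1
OUTPUT_FS = 1000
CYCLE_JITTER_S = 0.05        # one 50 ms heater cycle


@dataclass
class SimulationConfig:
    """Everything needed to turn a protocol into recordings."""

    panel: OdorantPanel = field(default_factory=OdorantPanel.default)
    sensors: list = field(default_factory=default_sensor_array)
    modes: list = None                      # per-sensor HeaterMode
    controller: ctl.ControllerConfig = field(default_factory=ctl.ControllerConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ambient_degc: float = 25.0
    pre_s: float = 5.5                      # baseline before commanded onset
    post_s: float = 2.5                     # tail after commanded offset
    delay_ms: float = stim.DEFAULT_DELAY_MS
    rise_tau_ms: float = stim.DEFAULT_RISE_TAU_MS
    fall_tau_ms: float = stim.DEFAULT_FALL_TAU_MS
    # trial-to-trial delivery variability (flow/turbulence): multiplicative
    # amplitude jitter per odorant and Gaussian jitter on the transport delay
    housing_tau_ms: float = 20.0        # gas exchange into the (non-decapped) package
    amplitude_jitter_rel: float = 0.05
    delay_jitter_ms: float = 5.0
    kinetics_jitter_rel: float = 0.25   # per-trial, per-sensor surface-state jitter
    response_jitter_rel: float = 0.2    # per-trial, per-sensor response amplitude
    baseline_jitter_rel: float = 0.10   # per-trial, per-sensor clean-air baseline
    pid_gain: float = 1.0
    pid_tau_ms: float = 5.0

    def __post_init__(self):
        if self.modes is None:
            self.modes = ctl.experiment_modes("A")
        if len(self.modes) != len(self.sensors):
            raise ValueError("one heater mode per sensor required")


class HeaterCache:
    """Share heater co-simulations across the trials of one protocol run."""

    def __init__(self, config: SimulationConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self._traces = {}
        self._calibrations = None

    def calibrations(self):
        if self._calibrations is None:
            self._calibrations = [
                ctl.run_calibration(p, self.config.ambient_degc)
                for p in self.config.sensors]
        return self._calibrations

    def trace(self, n_samples: int, freeze_window=None) -> ctl.HeaterTrace:
        key = (tuple(m.key for m in self.config.modes), freeze_window)
        cached = self._traces.get(key)
        if cached is None or cached.t_true.shape[1] < n_samples:
            cached = ctl.simulate_hotplate(
                self.config.sensors, self.config.modes, n_samples,
                fs=OUTPUT_FS, ambient=self.config.ambient_degc,
                config=self.config.controller,
                calibrations=self.calibrations(),
                freeze_window=freeze_window, seed=self.seed)
            self._traces[key] = cached
        return cached


def _slice_trace(trace: ctl.HeaterTrace, n: int):
    return {k: getattr(trace, k)[:, :n]
            for k in ("t_true", "t_meas", "t_target", "v_dac", "v_sense")}


def simulate_trial(trial: Trial, config: SimulationConfig, seed: int,
                   heater_cache: HeaterCache | None = None,
                   freeze_stimuli: bool = True):
    """Simulate one trial into a digitized 1 kHz Recording.

    Deterministic for a given ``(trial, config, seed)``.  The commanded onset
    falls at ``pre_s`` plus a seed-derived jitter of up to one heater cycle;
    recording length is ``pre_s + jitter_max + duration + post_s``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    jitter = rng.uniform(0.0, CYCLE_JITTER_S)
    onset_s = config.pre_s + jitter
    dur_s = trial.duration_ms / 1000.0
    n = int(round((config.pre_s + CYCLE_JITTER_S + dur_s + config.post_s)
                  * OUTPUT_FS))
    total_s = n / OUTPUT_FS             # whole output samples

    schedule = stim.build_schedule(trial, config.panel, onset_s, total_s)
    # the two odor manifolds are separate delivery lines: their transport
    # delays jitter independently from trial to trial
    delays = np.maximum(0.0, config.delay_ms
                        + rng.normal(0.0, config.delay_jitter_ms, 2))
    trace = stim.transport(schedule, config.panel, delays,
                           config.rise_tau_ms, config.fall_tau_ms)
    if config.amplitude_jitter_rel > 0 and trace.conc.size:
        factors = np.exp(rng.normal(0.0, config.amplitude_jitter_rel,
                                    trace.conc.shape[0]))
        trace.conc = trace.conc * factors[:, None]
    pid = stim.pid_response(trace, config.pid_gain, config.pid_tau_ms,
                            config.noise.pid_sigma, rng)

    if heater_cache is None:
        heater_cache = HeaterCache(config, seed=0)
    freeze = None
    if freeze_stimuli and any(m.kind == ctl.CONSTANT for m in config.modes):
        # conservative in-stimulus freeze window covering any onset jitter
        freeze = (round(config.pre_s - 0.1, 6),
                  round(config.pre_s + CYCLE_JITTER_S + dur_s + 0.1, 6))
    heater = heater_cache.trace(n, freeze_window=freeze)
    chans = _slice_trace(heater, n)

    # concentration rows for every panel odorant, zeros where inactive
    conc = np.zeros((len(config.panel.names), n))
    name_to_row = {nm: i for i, nm in enumerate(config.panel.names)}
    for nm, row in zip(trace.odorants, trace.conc):
        conc[name_to_row[nm]] += row[:n]
    active = [nm for nm in config.panel.names
              if not config.panel[nm].is_blank]
    S = len(config.sensors)

    def _jitter(rel):
        return np.exp(rng.normal(0.0, rel, S)) if rel > 0 else None

    conc_at_film = conc[[name_to_row[nm] for nm in active]]
    if config.housing_tau_ms > 0:
        # the sensors keep their housings on; gas exchange into the package
        # low-passes the stimulus seen by the film (the PID sees the free
        # stream, so the recorded conc/pid channels stay unfiltered)
        conc_at_film = first_order_lowpass(
            conc_at_film, 1.0 / OUTPUT_FS, config.housing_tau_ms / 1000.0,
            y0=np.zeros(len(active)))
    gas = gas_response(chans["t_true"], conc_at_film,
                       active, config.sensors, fs=OUTPUT_FS,
                       kinetics_scale=_jitter(config.kinetics_jitter_rel),
                       response_scale=_jitter(config.response_jitter_rel),
                       baseline_scale=_jitter(config.baseline_jitter_rel))

    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": trial.kind,
        "odors": list(trial.odors),
        "duration_ms": trial.duration_ms,
        "concentration": trial.concentration,
        "frequency_hz": trial.frequency_hz,
        "t_onset_s": onset_s,
        "seed": seed,
        "heater_modes": [m.kind for m in config.modes],
        "ambient_degc": config.ambient_degc,
    }
    rec = Recording(fs=OUTPUT_FS, time=np.arange(n) / OUTPUT_FS, gas=gas,
                    temp=chans["t_meas"], temp_target=chans["t_target"],
                    vdac=chans["v_dac"], vsense=chans["v_sense"],
                    conc=conc, pid=pid, odorants=config.panel.names, meta=meta)
    return rec, rng


def simulate_recording(trial: Trial, config: SimulationConfig = None,
                       seed: int = 0, experiment_time_s: float = 0.0,
                       heater_cache: HeaterCache | None = None) -> Recording:
    """Simulate and digitize one trial (the public single-trial entry point)."""
    config = SimulationConfig() if config is None else config
    rec, rng = simulate_trial(trial, config, seed, heater_cache)
    from .sensor import digitize
    return digitize(rec, config.noise, rng, experiment_time_s)


def simulate_protocol(trials, config: SimulationConfig = None, seed: int = 0):
    """Yield digitized recordings for a sequence of trials.

    Per-trial seeds are spawned from ``seed``; experiment-clock start times
    accumulate each trial's stimulus plus recovery span, driving the slow
    baseline drift across the session.
    """
    config = SimulationConfig() if config is None else config
    cache = HeaterCache(config, seed=0)
    t_experiment = 0.0
    trials = list(trials)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(len(trials))]
    for trial, child in zip(trials, child_seeds):
        yield simulate_recording(trial, config, child, t_experiment, cache)
        t_experiment += trial.span_s
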