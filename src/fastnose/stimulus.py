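"""Olfactometer model: valve schedules, gas transport and delivery fidelity.

The olfactometer has two valve manifolds.  Manifold A carries the first odor
valve plus a mineral-oil carrier valve that is open whenever no trial is
running; manifold B mirrors it with the second odor valve and a compensation
valve.  Valve commands are gated ("shattered") by a 500 Hz PWM whose duty
cycle sets the delivered concentration, and each manifold's carrier opens
exactly when its odor valve is closed, so the total expected open fraction is
conserved sample-by-sample (flow compensation).

Valve schedules are built on a 10 kHz master clock (20 samples per shatter
period); gas transport to the sensing site is modelled as a pure delay plus
an asymmetric first-order filter (fast rise, slow purge), then decimated to
the 1 kHz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._signal import asymmetric_lowpass, block_mean, first_order_lowpass
from .protocol import ANTICORR_TRAIN, CORR_TRAIN, PULSE, Trial

MASTER_RATE_HZ = 10_000
OUTPUT_RATE_HZ = 1_000
SHATTER_HZ = 500
# two manifolds, each with one always-open carrier at rest
BASELINE_OPEN_FRACTION = 2.0

DEFAULT_DELAY_MS = 10.0
DEFAULT_RISE_TAU_MS = 5.0
DEFAULT_FALL_TAU_MS = 30.0


@dataclass
class ValveSchedule:
    """Binary open/closed traces for the four valves at the master rate."""

    fs: int
    onset_sample: int
    offset_sample: int
    shatter_frequency: float
    duty_cycle: float
    valves: dict            # name -> bool array; keys: odor_a, odor_b, carrier, compensation
    odorant_map: dict       # valve name -> odorant name (or None)

    @property
    def n_samples(self) -> int:
        return next(iter(self.valves.values())).size

    def total_open(self) -> np.ndarray:
        """Instantaneous number of open valves."""
        return np.sum([v.astype(float) for v in self.valves.values()], axis=0)

    def open_fraction(self, bin_ms: float = 2.0) -> np.ndarray:
        """Expected total open fraction per ``bin_ms`` bin (flow bookkeeping)."""
        k = int(round(bin_ms / 1000.0 * self.fs))
        return block_mean(self.total_open(), k)


def _pwm_mask(n: int, fs: int, duty: float, shatter_hz: float = SHATTER_HZ) -> np.ndarray:
    """500 Hz PWM gate: within each shatter period the first ``duty`` fraction
    of samples is open."""
    period = fs / shatter_hz
    if abs(period - round(period)) > 1e-9:
        raise ValueError("master rate must be a multiple of the shatter rate")
    period = int(round(period))
    on = int(round(duty * period))
    return (np.arange(n) % period) < on


def build_schedule(trial: Trial, panel, onset_s: float, total_s: float,
                   fs: int = MASTER_RATE_HZ,
                   shatter_hz: float = SHATTER_HZ) -> ValveSchedule:
    """Construct the four valve traces for one trial.

    Pulses shatter a single odor valve at ``duty = concentration%`` for the
    stimulus duration.  Correlated trains open both odor valves on the same
    half-cycle of the modulation square wave; anticorrelated trains shift the
    second valve's on-phase by half a period, so the two on-phase indicators
    are disjoint and tile the stimulus.  Carriers open on the sample-wise
    complement of their manifold's odor valve within the stimulus, keeping the
    total open fraction at the pre-trial level exactly.
    """
    for name in trial.odors:
        if name not in panel:
            raise ValueError(f"unknown odorant: {name!r}")
    n = int(round(total_s * fs))
    onset = int(round(onset_s * fs))
    dur = int(round(trial.duration_ms / 1000.0 * fs))
    offset = onset + dur
    if onset < 0 or offset > n:
        raise ValueError("stimulus does not fit inside the schedule")
    duty = trial.concentration / 100.0

    stim = np.zeros(n, dtype=bool)
    stim[onset:offset] = True
    pwm = _pwm_mask(n, fs, duty, shatter_hz)

    odor_a = np.zeros(n, dtype=bool)
    odor_b = np.zeros(n, dtype=bool)
    if trial.kind == PULSE:
        odor_a = stim & pwm
        name_a, name_b = trial.odors[0], None
    else:
        # first-half / second-half phase indicator of the modulation cycle
        i = np.arange(n)
        phase = ((i - onset) * trial.frequency_hz / fs) % 1.0 < 0.5
        odor_a = stim & phase & pwm
        if trial.kind == CORR_TRAIN:
            odor_b = stim & phase & pwm
        elif trial.kind == ANTICORR_TRAIN:
            odor_b = stim & ~phase & pwm
        name_a, name_b = trial.odors
    # within the stimulus each carrier is the exact complement of its
    # manifold's odor valve; outside it is fully open
    carrier = np.where(stim, ~odor_a, True).astype(bool)
    compensation = np.where(stim, ~odor_b, True).astype(bool)

    return ValveSchedule(
        fs=fs,
        onset_sample=onset,
        offset_sample=offset,
        shatter_frequency=shatter_hz,
        duty_cycle=duty,
        valves={
            "odor_a": odor_a,
            "odor_b": odor_b,
            "carrier": carrier,
            "compensation": compensation,
        },
        odorant_map={"odor_a": name_a, "odor_b": name_b,
                     "carrier": None, "compensation": None},
    )


@dataclass
class ConcentrationTrace:
    """Per-odorant gas-phase concentration at the sensing site (a.u., 1 kHz)."""

    fs: int
    odorants: tuple
    conc: np.ndarray        # (n_odorants, n) >= 0
    onset_sample: int
    offset_sample: int
    delay_ms: float
    rise_tau_ms: float
    fall_tau_ms: float

    @property
    def n_samples(self) -> int:
        return self.conc.shape[1]

    def total(self) -> np.ndarray:
        return self.conc.sum(axis=0)


def transport(schedule: ValveSchedule, panel,
              delay_ms: float = DEFAULT_DELAY_MS,
              rise_tau_ms: float = DEFAULT_RISE_TAU_MS,
              fall_tau_ms: float = DEFAULT_FALL_TAU_MS,
              out_fs: int = OUTPUT_RATE_HZ) -> ConcentrationTrace:
    """Physicalize valve openings into concentration traces at the sensor.

    Each odor valve trace is first averaged over each shatter period (the
    500 Hz pulses mix to their duty mean in the delivery line -- the reason
    shattering preserves temporal fidelity), then delayed by ``delay_ms``
    (a scalar, or one value per odor manifold),
    relaxed through the asymmetric first-order filter (fast rise, slow
    purge) and scaled by the odorant's relative headspace strength; the
    blank scales to zero.  The result is decimated to the 1 kHz acquisition
    rate by block averaging.
    """
    delays = np.broadcast_to(np.asarray(delay_ms, dtype=float), (2,))
    if np.any(delays < 0):
        raise ValueError("transport delay must be non-negative")
    if rise_tau_ms < 0 or fall_tau_ms < 0:
        raise ValueError("time constants must be non-negative")
    fs = schedule.fs
    k = fs // out_fs
    period = int(round(fs / schedule.shatter_frequency))
    names, rows = [], []
    for valve_name, dly in zip(("odor_a", "odor_b"), delays):
        odorant = schedule.odorant_map[valve_name]
        if odorant is None:
            continue
        d = int(round(dly / 1000.0 * fs))
        x = schedule.valves[valve_name].astype(float)
        env = np.repeat(block_mean(x, period), period)
        if env.size < x.size:       # trailing partial shatter period
            env = np.concatenate((env, x[env.size:]))
        x = env
        if d:
            x = np.concatenate((np.zeros(d), x[:-d]))
        y = asymmetric_lowpass(x, 1.0 / fs, rise_tau_ms / 1000.0,
                               fall_tau_ms / 1000.0)
        y = y * panel.relative_strength(odorant)
        names.append(odorant)
        rows.append(block_mean(y, k))
    conc = np.array(rows) if rows else np.zeros((0, schedule.n_samples // k))
    return ConcentrationTrace(
        fs=out_fs,
        odorants=tuple(names),
        conc=conc,
        onset_sample=schedule.onset_sample // k,
        offset_sample=schedule.offset_sample // k,
        delay_ms=float(np.mean(delays)),
        rise_tau_ms=rise_tau_ms,
        fall_tau_ms=fall_tau_ms,
    )


def pid_response(trace: ConcentrationTrace, gain: float = 1.0,
                 pid_tau_ms: float = 5.0, noise_sd: float = 0.005,
                 rng=None) -> np.ndarray:
    """Photoionization-detector ground-truth channel.

    The PID sees the summed odorant concentration through its own first-order
    response, plus white measurement noise.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if trace.conc.size:
        total = gain * trace.total()
    else:
        total = np.zeros(trace.n_samples)
    y = first_order_lowpass(total, 1.0 / trace.fs, pid_tau_ms / 1000.0, y0=total[0])
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        y = y + rng.normal(0.0, noise_sd, y.size)
    return y


@dataclass
class FidelityResult:
    values: np.ndarray          # per-pulse fidelity, NaN where undefined
    mean: float
    sd: float
    undefined: np.ndarray       # bool mask of flagged pulses

    @property
    def any_undefined(self) -> bool:
        return bool(self.undefined.any())


def fidelity(pid_trace: np.ndarray, pulse_onsets, pulse_offsets,
             baseline_window: slice, rel_tol: float = 1e-9) -> FidelityResult:
    """Per-pulse delivery fidelity: (peak - following trough) / (peak - baseline).

    ``pulse_onsets``/``pulse_offsets`` are sample indices of the commanded
    square pulses; the peak is searched within each pulse, the trough between
    the pulse's offset and the next pulse's onset (or an equal span after the
    last pulse).  The baseline is the mean over ``baseline_window``, which must
    precede the first pulse.  A pulse whose peak does not rise above baseline
    has undefined fidelity and is flagged (NaN).
    """
    pid_trace = np.asarray(pid_trace, dtype=float)
    onsets = np.asarray(pulse_onsets, dtype=int)
    offsets = np.asarray(pulse_offsets, dtype=int)
    if onsets.size == 0 or onsets.size != offsets.size:
        raise ValueError("need at least one pulse with matching onsets/offsets")
    if (baseline_window.stop or 0) > onsets[0]:
        raise ValueError("baseline window must precede the first pulse")
    baseline = float(np.mean(pid_trace[baseline_window]))
    scale = max(np.ptp(pid_trace), abs(baseline), 1.0)
    values = np.full(onsets.size, np.nan)
    undefined = np.zeros(onsets.size, dtype=bool)
    for i, (t0, t1) in enumerate(zip(onsets, offsets)):
        t_next = onsets[i + 1] if i + 1 < onsets.size else min(
            pid_trace.size, t1 + max(t1 - t0, 1))
        peak = float(np.max(pid_trace[t0:t1 + 1]))
        trough = float(np.min(pid_trace[t1:t_next + 1]))
        if peak - baseline <= rel_tol * scale:
            undefined[i] = True
        else:
            values[i] = (peak - trough) / (peak - baseline)
    valid = values[~undefined]
    mean = float(np.mean(valid)) if valid.size else float("nan")
    sd = float(np.std(valid)) if valid.size else float("nan")
    return FidelityResult(values=values, mean=mean, sd=sd, undefined=undefined)
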