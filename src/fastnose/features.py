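"""Feature extraction: phase-locked windows, baseline normalization, window
labelling, spectral triplets and PID onset/offset bounds.

Phase-locked features chop the gas channels into 50 ms chunks aligned with
the heater cycles.  The normalized variant applies, per sensor, a log
transform followed by max scaling to both the window at time ``t`` and a
pre-stimulus baseline window (``t_pre = -5 s``), and takes their vector
difference:

    g_s = log(w_t) / max(log(w_t)) - log(w_pre) / max(log(w_pre))

which removes the first-order sensor baseline and is exactly invariant under
power-law rescaling of the resistance.

Spectral features, for constant-temperature sensors, log-transform and
differentiate the resistance over the stimulus window (plus a ``b = 100 ms``
allowance for transport delay and sensor lag), take the DFT, and keep the
(frequency, magnitude, phase) triplet of the dominant non-DC peak per sensor
-- a 12-vector for four sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor import Recording

CYCLE_MS = 50.0
LABEL_ODOR = "odor"
LABEL_BLANK = "blank"
LABEL_REJECTED = "rejected"
DEFAULT_DELAY_MS = 10.0
DEFAULT_RECOVERY_MARGIN_MS = 300.0
T_PRE_MS = -5000.0

VARIANTS = ("raw_const", "basesub_const", "raw_cycled", "normalized_cycled")


class FeatureError(ValueError):
    """Raised when a window violates the preconditions of an extractor."""


def feature_columns(table) -> list:
    """Names of the feature-vector columns (``v0``, ``v1``, ...) of a table."""
    return [c for c in table.columns
            if c.startswith("v") and c[1:].isdigit()]


def snap_to_cycle(t_abs_ms: float, cycle_ms: float = CYCLE_MS) -> float:
    """Nearest heater-cycle boundary at or before ``t_abs_ms`` (recording
    time; the cycle grid is anchored at t = 0)."""
    return np.floor(t_abs_ms / cycle_ms) * cycle_ms


def extract_window(recording: Recording, sensor: int, t_ms: float,
                   tau_ms: float = CYCLE_MS, snap: bool = True):
    """Raw ``tau_ms`` window of one gas channel starting at ``t_ms`` relative
    to stimulus onset.  For cycled sensors the start is snapped to the heater
    cycle grid; the residual phase rho = t - snapped start is returned
    alongside.  Windows are half-open ``[t, t + tau)``."""
    t_abs = recording.t_onset_s * 1000.0 + t_ms
    start = snap_to_cycle(t_abs) if snap else t_abs
    rho = t_abs - start
    i0 = int(round(start / 1000.0 * recording.fs))
    n = int(round(tau_ms / 1000.0 * recording.fs))
    if i0 < 0 or i0 + n > recording.n_samples:
        raise FeatureError("window out of recording range")
    return recording.gas[sensor, i0:i0 + n].copy(), rho


def _scaled_log(w: np.ndarray) -> np.ndarray:
    if np.any(w <= 0):
        raise FeatureError("resistances must be positive for the log transform")
    lw = np.log(w)
    m = np.max(lw)
    if m == 0:
        raise FeatureError("degenerate window: max(log) is zero")
    return lw / m


def normalize_window(w_t: np.ndarray, w_pre: np.ndarray) -> np.ndarray:
    """Baseline-normalized cycled-heater feature.

    Both windows are 2-D ``(n_sensors, tau_samples)``; per sensor the scaled
    logs are differenced and the rows concatenated.  Identical windows give
    the zero vector; so does any power-law rescaling ``w_t = w_pre ** g``.
    """
    w_t = np.atleast_2d(np.asarray(w_t, dtype=float))
    w_pre = np.atleast_2d(np.asarray(w_pre, dtype=float))
    if w_t.shape != w_pre.shape:
        raise FeatureError("windows must share sensor set and duration")
    rows = [_scaled_log(a) - _scaled_log(b) for a, b in zip(w_t, w_pre)]
    return np.concatenate(rows)


def window_starts(t_onset_ms: float, span_ms: float = 2000.0,
                  tau_ms: float = CYCLE_MS) -> np.ndarray:
    """Cycle-grid window starts (absolute ms) tiling the post-onset span,
    beginning at the cycle boundary at or before the onset."""
    first = snap_to_cycle(t_onset_ms)
    return np.arange(first, t_onset_ms + span_ms - tau_ms / 2, tau_ms)


def label_windows(t_onset_ms: float, t_offset_ms: float, starts,
                  tau_ms: float = CYCLE_MS, d_ms: float = DEFAULT_DELAY_MS,
                  recovery_margin_ms: float = DEFAULT_RECOVERY_MARGIN_MS):
    """Assign each window exactly one of odor / blank / rejected.

    With the upper-bound stimulus delay ``d``: windows fully inside
    ``[t_onset + d, t_offset + d)`` carry the stimulus odor; windows entirely
    before onset, or starting at least ``recovery_margin`` after the delayed
    offset, are blank; anything straddling a transition is rejected
    (excluded from training, retained for evaluation).
    """
    starts = np.asarray(starts, dtype=float)
    ends = starts + tau_ms
    labels = np.full(starts.size, LABEL_REJECTED, dtype=object)
    odor = (starts >= t_onset_ms + d_ms) & (ends <= t_offset_ms + d_ms)
    blank = (ends <= t_onset_ms) | (starts >= t_offset_ms + d_ms + recovery_margin_ms)
    labels[odor] = LABEL_ODOR
    labels[blank & ~odor] = LABEL_BLANK
    return labels


def windowed_features(recording: Recording, sensors,
                      variant: str = "normalized_cycled",
                      span_ms: float = 2000.0, tau_ms: float = CYCLE_MS,
                      t_pre_ms: float = T_PRE_MS,
                      d_ms: float = DEFAULT_DELAY_MS,
                      recovery_margin_ms: float = DEFAULT_RECOVERY_MARGIN_MS,
                      starts_rel_ms=None) -> pd.DataFrame:
    """Per-window feature table for one trial.

    Rows: one per 50 ms window on the cycle grid (either tiling
    ``[onset, onset + span)`` or at explicit ``starts_rel_ms`` offsets
    relative to onset).  Columns: window timing, phase rho, the Algorithm-1
    label (blank trials are all blank), and the feature vector ``v0..``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    fs = recording.fs
    onset_ms = recording.t_onset_s * 1000.0
    offset_ms = recording.t_offset_s * 1000.0
    if starts_rel_ms is None:
        starts = window_starts(onset_ms, span_ms, tau_ms)
    else:
        starts = np.array([snap_to_cycle(onset_ms + t) for t in starts_rel_ms])
    odor_name = recording.meta["odors"][0]
    is_blank_trial = odor_name == "blank"
    labels = label_windows(onset_ms, offset_ms, starts, tau_ms, d_ms,
                           recovery_margin_ms)
    if is_blank_trial:
        labels = np.full(starts.size, LABEL_BLANK, dtype=object)

    n = int(round(tau_ms / 1000.0 * fs))
    pre_start = snap_to_cycle(onset_ms + t_pre_ms)
    ip = int(round(pre_start / 1000.0 * fs))
    w_pre = recording.gas[np.asarray(sensors), ip:ip + n]

    rows = []
    for start, label in zip(starts, labels):
        i0 = int(round(start / 1000.0 * fs))
        if i0 < 0 or i0 + n > recording.n_samples:
            continue
        w_t = recording.gas[np.asarray(sensors), i0:i0 + n]
        if variant == "raw_const" or variant == "raw_cycled":
            vec = w_t.ravel()
        elif variant == "basesub_const":
            vec = (w_t - w_pre).ravel()
        else:
            vec = normalize_window(w_t, w_pre)
        y = odor_name if label == LABEL_ODOR else label
        rows.append({"t_ms": start - onset_ms, "rho_ms": onset_ms - snap_to_cycle(onset_ms),
                     "variant": variant, "label": y,
                     **{f"v{j}": v for j, v in enumerate(vec)}})
    return pd.DataFrame(rows)


@dataclass
class SpectralFeature:
    """Dominant (frequency, magnitude, phase) triplet per sensor."""

    frequencies_hz: np.ndarray
    magnitudes: np.ndarray
    phases_rad: np.ndarray
    flagged: np.ndarray         # per-sensor: True where the spectrum was empty

    @property
    def vector(self) -> np.ndarray:
        return np.column_stack(
            (self.frequencies_hz, self.magnitudes, self.phases_rad)).ravel()


def spectral_triplets(recording: Recording, sensors=(0, 1, 2, 3),
                      b_ms: float = 100.0, log_transform: bool = True,
                      channel: str = "gas") -> SpectralFeature:
    """Dominant-peak spectral feature over ``[t_onset, t_offset + b]``.

    Per sensor the trace is (optionally) log transformed, differentiated
    (first difference scaled by the sampling rate), and Fourier transformed;
    among the positive-frequency bins the maximum-magnitude triplet is kept,
    ties resolved toward the lowest frequency.  An all-constant trace yields
    a zero, flagged triplet.  For hotplate-temperature or PID variants the
    log transform is omitted (``channel='temp'``/``'pid'``).
    """
    fs = recording.fs
    i0 = int(round(recording.t_onset_s * fs))
    i1 = int(round((recording.t_offset_s + b_ms / 1000.0) * fs))
    if channel == "gas":
        data = recording.gas[np.asarray(sensors), i0:i1]
    elif channel == "temp":
        data = recording.temp[np.asarray(sensors), i0:i1]
    elif channel == "pid":
        data = np.tile(recording.pid[i0:i1], (len(sensors), 1))
    else:
        raise ValueError(f"unknown channel {channel!r}")
    freqs_out, mags, phases, flags = [], [], [], []
    for row in data:
        x = row.astype(float)
        if log_transform:
            if np.any(x <= 0):
                raise FeatureError("log transform requires positive samples")
            x = np.log(x)
        dx = np.diff(x) * fs
        spec = np.fft.rfft(dx)
        freqs = np.fft.rfftfreq(dx.size, 1.0 / fs)
        mag = np.abs(spec)
        mag[0] = 0.0                      # DC excluded from peak selection
        if not np.any(mag > 0):
            freqs_out.append(0.0); mags.append(0.0); phases.append(0.0)
            flags.append(True)
            continue
        k = int(np.argmax(mag))           # argmax takes the lowest bin on ties
        freqs_out.append(float(freqs[k]))
        mags.append(float(mag[k]))
        phases.append(float(np.angle(spec[k])))
        flags.append(False)
    return SpectralFeature(np.array(freqs_out), np.array(mags),
                           np.array(phases), np.array(flags))


@dataclass
class OnsetOffsetBounds:
    onset_bound_ms: float       # upper bound: commanded onset -> detection
    offset_bound_ms: float      # lower bound: commanded offset -> purge
    threshold: float
    detected: bool


def pid_onset_offset(pid: np.ndarray, t_onset_ms: float, t_offset_ms: float,
                     fs: int = 1000, k_sigma: float = 4.0,
                     baseline_ms: float = 1000.0,
                     sustain_ms: float = 20.0) -> OnsetOffsetBounds:
    """4-sigma bounds on stimulus delay and purge time from the PID channel.

    The threshold is baseline mean + ``k_sigma`` baseline SDs over the
    ``baseline_ms`` preceding onset.  The onset bound is the first crossing
    after the commanded onset; the offset bound is the first time after the
    commanded offset at which the trace stays below threshold for
    ``sustain_ms`` (a sustained return, so isolated noise excursions in the
    tail do not inflate the purge estimate).  A trace that never crosses is
    flagged undetected.
    """
    pid = np.asarray(pid, dtype=float)
    i_on = int(round(t_onset_ms / 1000.0 * fs))
    i_off = int(round(t_offset_ms / 1000.0 * fs))
    nb = int(round(baseline_ms / 1000.0 * fs))
    if i_on - nb < 0:
        raise ValueError("need at least the baseline window before onset")
    base = pid[i_on - nb:i_on]
    thr = float(np.mean(base) + k_sigma * np.std(base))
    above = pid >= thr
    post = np.nonzero(above[i_on:])[0]
    if post.size == 0:
        return OnsetOffsetBounds(float("nan"), float("nan"), thr, False)
    onset_bound = post[0] / fs * 1000.0
    k = max(1, int(round(sustain_ms / 1000.0 * fs)))
    tail = above[i_off:]
    below_run = np.convolve((~tail).astype(int), np.ones(k, dtype=int),
                            mode="valid")
    sustained = np.nonzero(below_run == k)[0]
    offset_bound = (sustained[0] / fs * 1000.0) if sustained.size \
        else tail.size / fs * 1000.0
    return OnsetOffsetBounds(onset_bound, offset_bound, thr, True)
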