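"""Low-level signal primitives shared across the simulator.

All filters use the exact zero-order-hold discretisation of the underlying
first-order ODE, so that steady-state ripple of filtered square waves matches
the closed-form expressions to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter


def first_order_lowpass(x: np.ndarray, dt: float, tau: float, y0=None) -> np.ndarray:
    """Exact ZOH discretisation of ``tau * dy/dt = x - y`` along the last axis.

    ``y[n]`` is the state at the end of sample interval ``n`` during which the
    input held the value ``x[n]``.  ``tau <= 0`` returns a copy (zero-lag limit).
    """
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        return x.copy()
    a = np.exp(-dt / tau)
    if y0 is None:
        y0 = x[..., 0]
    zi = np.broadcast_to(a * np.asarray(y0, dtype=float),
                         x.shape[:-1]).reshape(x.shape[:-1] + (1,))
    y, _ = lfilter([1.0 - a], [1.0, -a], x, axis=-1, zi=zi)
    return y


def asymmetric_lowpass(x: np.ndarray, dt: float, tau_rise: float,
                       tau_fall: float, y0: float = 0.0) -> np.ndarray:
    """First-order relaxation with separate rise/fall time constants.

    Exact for piecewise-constant input: within each constant segment the output
    relaxes exponentially toward the segment value, with ``tau_rise`` when the
    target lies above the current state and ``tau_fall`` otherwise.  A zero
    time constant snaps instantly.
    """
    x = np.asarray(x, dtype=float)
    if tau_rise < 0 or tau_fall < 0:
        raise ValueError("time constants must be non-negative")
    n = x.size
    y = np.empty(n)
    change = np.nonzero(np.diff(x))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    cur = float(y0)
    for s0, s1 in zip(starts, ends):
        v = x[s0]
        tau = tau_rise if v > cur else tau_fall
        if tau <= 0:
            y[s0:s1] = v
            cur = v
        else:
            expo = np.exp(-dt * np.arange(1, s1 - s0 + 1) / tau)
            y[s0:s1] = v + (cur - v) * expo
            cur = y[s1 - 1]
    return y


def quantize(x: np.ndarray, full_scale: float, bits: int, lo: float = 0.0):
    """Uniform mid-tread quantization of ``x`` to ``bits`` bits over
    ``[lo, full_scale]``.  Returns ``(quantized, n_clipped)``; clipping is
    reported, never silent."""
    x = np.asarray(x, dtype=float)
    step = (full_scale - lo) / (2 ** bits)
    clipped = np.clip(x, lo, full_scale)
    n_clipped = int(np.sum((x < lo) | (x > full_scale)))
    q = np.round((clipped - lo) / step) * step + lo
    return q, n_clipped


def block_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Decimate by averaging consecutive blocks of ``k`` samples (last axis)."""
    x = np.asarray(x, dtype=float)
    n = (x.shape[-1] // k) * k
    return x[..., :n].reshape(*x.shape[:-1], -1, k).mean(axis=-1)
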