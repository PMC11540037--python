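"""Valve schedules, flow conservation, gas transport and delivery fidelity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastnose._signal import first_order_lowpass
from fastnose.protocol import Trial
from fastnose.stimulus import (BASELINE_OPEN_FRACTION, build_schedule,
                               fidelity, pid_response, transport)


def test_full_pulse_opens_odor_valve_for_exact_duration(panel):
    sched = build_schedule(Trial("pulse", ("IA",), 1000, 100.0), panel,
                           onset_s=1.0, total_s=3.0)
    odor = sched.valves["odor_a"]
    assert odor.sum() == 10_000                      # 1000 ms at 10 kHz
    assert odor[sched.onset_sample:sched.offset_sample].all()
    # carrier reduced in exact complement
    assert not sched.valves["carrier"][sched.onset_sample:sched.offset_sample].any()


def test_duty_cycle_sets_open_fraction(panel):
    sched = build_schedule(Trial("pulse", ("IA",), 1000, 40.0), panel,
                           onset_s=1.0, total_s=3.0)
    stim = slice(sched.onset_sample, sched.offset_sample)
    assert sched.valves["odor_a"][stim].mean() == pytest.approx(0.4)


def test_anticorrelated_phases_are_disjoint_and_tile(panel):
    trial = Trial("anticorr_train", ("IA", "EB"), 1000, 100.0, 20.0)
    sched = build_schedule(trial, panel, onset_s=1.0, total_s=3.0)
    a, b = sched.valves["odor_a"], sched.valves["odor_b"]
    stim = slice(sched.onset_sample, sched.offset_sample)
    assert not (a & b).any()                         # pointwise product zero
    assert (a[stim] | b[stim]).all()                 # union covers stimulus
    # 20 on-phases of 25 ms each per valve
    edges = np.diff(a[stim].astype(int))
    assert (edges == 1).sum() + a[stim][0] == 20
    first = np.nonzero(a[stim])[0]
    assert first[249] - first[0] == 249              # one 25 ms phase


def test_correlated_indicators_identical(panel):
    trial = Trial("corr_train", ("IA", "EB"), 1000, 100.0, 20.0)
    sched = build_schedule(trial, panel, onset_s=1.0, total_s=3.0)
    np.testing.assert_array_equal(sched.valves["odor_a"],
                                  sched.valves["odor_b"])


def test_zero_duration_leaves_carrier_untouched(panel):
    sched = build_schedule(Trial("pulse", ("IA",), 0, 100.0), panel,
                           onset_s=1.0, total_s=2.0)
    assert not sched.valves["odor_a"].any()
    assert sched.valves["carrier"].all()


def test_unknown_odor_rejected(panel):
    with pytest.raises(ValueError):
        build_schedule(Trial("pulse", ("nonesuch",), 100, 100.0), panel,
                       onset_s=1.0, total_s=2.0)


@settings(max_examples=20, deadline=None)
@given(st.sampled_from(["pulse", "corr_train", "anticorr_train"]),
       st.sampled_from([20.0, 40.0, 60.0, 100.0]),
       st.sampled_from([2.0, 5.0, 10.0, 20.0, 40.0, 60.0]))
def test_flow_conservation_per_2ms_bin(kind, conc, freq):
    panel = _panel()
    if kind == "pulse":
        trial = Trial(kind, ("IA",), 1000, conc)
    else:
        trial = Trial(kind, ("IA", "EB"), 1000, conc, freq)
    sched = build_schedule(trial, panel, onset_s=0.5, total_s=2.5)
    frac = sched.open_fraction(bin_ms=2.0)
    assert np.max(np.abs(frac - BASELINE_OPEN_FRACTION)) < 1e-9


def _panel():
    from fastnose.panel import OdorantPanel
    return OdorantPanel.default()


def test_transport_zero_tau_zero_delay_is_delayed_copy(panel):
    sched = build_schedule(Trial("pulse", ("EB",), 1000, 100.0), panel,
                           onset_s=1.0, total_s=3.0)
    trace = transport(sched, panel, delay_ms=0, rise_tau_ms=0, fall_tau_ms=0)
    expected = np.zeros(3000)
    expected[1000:2000] = 1.0                        # EB has unit strength
    np.testing.assert_allclose(trace.conc[0], expected, atol=1e-12)


def test_transport_delay_shifts_trace(panel):
    sched = build_schedule(Trial("pulse", ("EB",), 1000, 100.0), panel,
                           onset_s=1.0, total_s=3.0)
    trace = transport(sched, panel, delay_ms=10, rise_tau_ms=0, fall_tau_ms=0)
    assert trace.conc[0][1005] == 0.0
    assert trace.conc[0][1010] == 1.0
    with pytest.raises(ValueError):
        transport(sched, panel, delay_ms=-1)


def test_purge_time_matches_exponential_decay(panel):
    """4-sigma purge bound equals the closed-form crossing of the fall tail."""
    from fastnose.features import pid_onset_offset
    sched = build_schedule(Trial("pulse", ("EB",), 1000, 100.0), panel,
                           onset_s=2.0, total_s=5.0)
    rng = np.random.default_rng(0)
    trace = transport(sched, panel, delay_ms=0, rise_tau_ms=1e-9,
                      fall_tau_ms=150.0)
    noise_sd = 0.005
    pid = pid_response(trace, pid_tau_ms=1e-9, noise_sd=noise_sd, rng=rng)
    res = pid_onset_offset(pid, t_onset_ms=2000, t_offset_ms=3000)
    # noiseless threshold crossing; the sustained-return detector can only
    # fire after it, biased upward by at most ~ln(2) tau (threshold is
    # 4 sigma, a sustained return needs ~2 sigma of margin)
    t_star = 150.0 * np.log(1.0 / (4 * noise_sd))    # A = 1 for EB
    assert t_star - 10.0 <= res.offset_bound_ms <= t_star + 0.8 * 150.0


def test_train_modulation_depth_matches_filter_ripple(panel):
    """Equal rise/fall taus: peak-to-trough depth of a filtered square train
    equals the closed-form ripple A(1-q)/(1+q), q = exp(-half/tau)."""
    trial = Trial("corr_train", ("EB", "blank"), 2000, 100.0, 20.0)
    sched = build_schedule(trial, panel, onset_s=0.5, total_s=3.0)
    tau = 40.0
    trace = transport(sched, panel, delay_ms=0, rise_tau_ms=tau,
                      fall_tau_ms=tau)
    x = trace.conc[0]
    steady = x[2200:2500]                            # final cycles
    q = np.exp(-25.0 / tau)
    depth = (1 - q) / (1 + q)
    # 1 kHz block-average read-out biases peak/trough by ~dt/(2 tau)
    assert np.ptp(steady) == pytest.approx(depth, rel=6e-2)


def test_fidelity_of_ideal_square_train_is_one():
    fs = 1000
    pid = np.zeros(4000)
    onsets = np.arange(1000, 3000, 100)
    offsets = onsets + 50
    for t0, t1 in zip(onsets, offsets):
        pid[t0:t1] = 2.0
    res = fidelity(pid, onsets, offsets, slice(0, 1000))
    assert not res.any_undefined
    np.testing.assert_allclose(res.values, 1.0)
    assert res.mean == pytest.approx(1.0) and res.sd == pytest.approx(0.0)


def test_fidelity_constant_trace_is_flagged():
    pid = np.full(2000, 3.0)
    res = fidelity(pid, [1000, 1200], [1100, 1300], slice(0, 500))
    assert res.undefined.all()
    assert np.isnan(res.values).all()


def test_fidelity_matches_first_order_ripple_closed_form():
    """60 Hz square train through a 20 ms filter: fidelity = 1 - exp(-h/tau)."""
    fs = 12_000
    half = 100                                       # 8.33 ms at 12 kHz
    tau = 0.020
    n_pulses = 30
    x = np.r_[np.zeros(2 * fs // 10),
              np.tile(np.r_[np.ones(half), np.zeros(half)], n_pulses)]
    y = first_order_lowpass(x, 1.0 / fs, tau, y0=0.0)
    onsets = 2 * fs // 10 + np.arange(n_pulses) * 2 * half
    res = fidelity(y, onsets, onsets + half, slice(0, fs // 10))
    expected = 1.0 - np.exp(-half / fs / tau)
    np.testing.assert_allclose(res.values[-5:], expected, atol=1e-6)


@settings(max_examples=20, deadline=None)
@given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
def test_fidelity_is_affine_invariant(scale, offset):
    rng = np.random.default_rng(7)
    pid = np.zeros(3000)
    onsets = np.arange(1000, 2500, 150)
    for t0 in onsets:
        pid[t0:t0 + 75] = rng.uniform(1.0, 2.0)
    base = fidelity(pid, onsets, onsets + 75, slice(0, 900))
    scaled = fidelity(scale * pid + offset, onsets, onsets + 75, slice(0, 900))
    np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)


def test_pid_of_blank_trial_is_noise_only(panel, rng):
    sched = build_schedule(Trial("pulse", ("blank",), 1000, 100.0), panel,
                           onset_s=1.0, total_s=3.0)
    trace = transport(sched, panel)
    pid = pid_response(trace, noise_sd=0.005, rng=rng)
    assert abs(pid.mean()) < 0.001 and pid.std() == pytest.approx(0.005, rel=0.1)
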