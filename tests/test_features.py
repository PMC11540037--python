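"""Phase-locked windows, baseline normalization, window labelling and
spectral triplet features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastnose.features import (FeatureError, LABEL_BLANK, LABEL_ODOR,
                               LABEL_REJECTED, extract_window, label_windows,
                               normalize_window, pid_onset_offset,
                               spectral_triplets, window_starts,
                               windowed_features)
from fastnose.sensor import Recording


def _mock_recording(gas, t_onset_s=1.0, duration_ms=1000.0, odors=("IA",),
                    fs=1000):
    gas = np.atleast_2d(gas)
    n = gas.shape[1]
    z = np.zeros((gas.shape[0], n))
    return Recording(fs=fs, time=np.arange(n) / fs, gas=gas, temp=z.copy(),
                     temp_target=z.copy(), vdac=z.copy(), vsense=z.copy(),
                     conc=np.zeros((1, n)), pid=np.zeros(n),
                     odorants=("IA",),
                     meta={"odors": list(odors), "duration_ms": duration_ms,
                           "t_onset_s": t_onset_s})


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_on_cycle_boundary_has_zero_phase():
    rec = _mock_recording(np.arange(3000.0) + 1.0, t_onset_s=1.0)
    w, rho = extract_window(rec, 0, 0.0)
    assert rho == 0.0 and w.size == 50
    np.testing.assert_array_equal(w, rec.gas[0, 1000:1050])


def test_window_snaps_to_cycle_grid():
    rec = _mock_recording(np.arange(3000.0) + 1.0, t_onset_s=1.017)
    w, rho = extract_window(rec, 0, 0.0)
    assert rho == pytest.approx(17.0)
    np.testing.assert_array_equal(w, rec.gas[0, 1000:1050])


def test_adjacent_windows_tile_the_grid_disjointly():
    rec = _mock_recording(np.arange(3000.0) + 1.0, t_onset_s=1.0)
    w0, _ = extract_window(rec, 0, 0.0)
    w1, _ = extract_window(rec, 0, 50.0)
    assert w0[-1] + 1 == w1[0]


def test_out_of_range_window_rejected():
    rec = _mock_recording(np.ones(100), t_onset_s=0.05)
    with pytest.raises(FeatureError):
        extract_window(rec, 0, 200.0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_identical_windows_normalize_to_zero():
    w = np.exp(np.random.default_rng(0).uniform(8, 12, (2, 50)))
    np.testing.assert_allclose(normalize_window(w, w), 0.0, atol=1e-15)


def test_hand_computed_power_scaling_example():
    """w_pre = (e, e^2), w_t = (e^2, e^4): both scaled logs are (0.5, 1)."""
    w_pre = np.array([[np.e, np.e ** 2]])
    w_t = np.array([[np.e ** 2, np.e ** 4]])
    np.testing.assert_allclose(normalize_window(w_t, w_pre), 0.0, atol=1e-14)


def test_scalar_rescaling_is_not_cancelled():
    w = np.exp(np.random.default_rng(1).uniform(8, 12, (1, 50)))
    g = normalize_window(3.0 * w, w)
    assert np.linalg.norm(g) > 1e-6


@settings(max_examples=40, deadline=None)
@given(st.floats(0.2, 5.0))
def test_power_law_rescaling_invariance(gamma):
    rng = np.random.default_rng(9)
    w_pre = np.exp(rng.uniform(6, 12, (2, 50)))
    w_t = np.exp(rng.uniform(6, 12, (2, 50)))
    base = normalize_window(w_t, w_pre)
    scaled = normalize_window(w_t ** gamma, w_pre ** gamma)
    np.testing.assert_allclose(scaled, base, atol=1e-10)
    np.testing.assert_allclose(normalize_window(w_pre ** gamma, w_pre), 0.0,
                               atol=1e-10)


def test_nonpositive_resistance_rejected():
    w = np.ones((1, 50))
    w[0, 3] = -1.0
    with pytest.raises(FeatureError):
        normalize_window(w, np.ones((1, 50)))


# ---------------------------------------------------------------------------
# labelling (independent brute-force oracle)
# ---------------------------------------------------------------------------

def _brute_force_labels(onset, offset, starts, tau, d, margin):
    out = []
    for s in starts:
        e = s + tau
        if s >= onset + d and e <= offset + d:
            out.append(LABEL_ODOR)
        elif e <= onset or s >= offset + d + margin:
            out.append(LABEL_BLANK)
        else:
            out.append(LABEL_REJECTED)
    return np.array(out, dtype=object)


@pytest.mark.parametrize("duration,rho", [(1000.0, 0.0), (1000.0, 17.0),
                                          (500.0, 33.0), (100.0, 5.0),
                                          (10.0, 0.0), (10.0, 42.0),
                                          (20.0, 25.0)])
def test_labelling_matches_brute_force(duration, rho):
    onset = 5000.0 + rho
    starts = window_starts(onset, span_ms=2000.0)
    got = label_windows(onset, onset + duration, starts)
    want = _brute_force_labels(onset, onset + duration, starts, 50.0, 10.0,
                               300.0)
    np.testing.assert_array_equal(got, want)
    # exhaustive and exclusive
    assert set(got) <= {LABEL_ODOR, LABEL_BLANK, LABEL_REJECTED}


def test_second_pulse_grid_counts():
    """1 s pulse on a cycle-aligned grid with d = 10 ms: 19 odor windows and
    two rejected transition windows."""
    onset = 5000.0
    starts = window_starts(onset, span_ms=2000.0)
    labels = label_windows(onset, onset + 1000.0, starts)
    assert (labels == LABEL_ODOR).sum() == 19
    assert labels[0] == LABEL_REJECTED              # onset transition
    # onset window + offset window + six 50 ms purge-margin windows
    assert (labels == LABEL_REJECTED).sum() == 8
    assert (labels == LABEL_BLANK).sum() == 13


def test_ten_ms_pulse_yields_no_odor_training_windows():
    onset = 5000.0
    for rho in (0.0, 10.0, 35.0):
        starts = window_starts(onset + rho, span_ms=2000.0)
        labels = label_windows(onset + rho, onset + rho + 10.0, starts)
        assert (labels == LABEL_ODOR).sum() == 0


def test_blank_trial_windows_all_blank(blank_recording):
    tab = windowed_features(blank_recording, (4, 5, 6, 7),
                            "normalized_cycled", span_ms=2000.0)
    assert (tab["label"] == LABEL_BLANK).all()


def test_window_feature_dimension(pulse_recording):
    from fastnose.features import feature_columns
    tab = windowed_features(pulse_recording, (4, 5, 6, 7),
                            "normalized_cycled", span_ms=2000.0)
    assert len(feature_columns(tab)) == 4 * 50


# ---------------------------------------------------------------------------
# spectral triplets
# ---------------------------------------------------------------------------

def test_bin_centered_tone_recovered_exactly():
    fs, n = 1000, 1100
    t = np.arange(n) / fs
    m = 20                                  # bin index after differencing
    f0 = m * fs / (n - 1)
    gas = np.exp(0.05 * np.sin(2 * np.pi * f0 * t) + 10.0)
    rec = _mock_recording(np.tile(gas, (4, 1)), t_onset_s=0.0,
                          duration_ms=1000.0)
    sf = spectral_triplets(rec, sensors=(0, 1, 2, 3))
    np.testing.assert_allclose(sf.frequencies_hz, f0, rtol=1e-12)
    assert sf.vector.size == 12
    # first difference of sin(w t) is a cosine sampled at half-sample offset
    expected_phase = 2 * np.pi * f0 * 0.5 / fs
    np.testing.assert_allclose(sf.phases_rad, expected_phase, atol=1e-9)


def test_constant_signal_is_flagged_zero_feature():
    rec = _mock_recording(np.full((4, 1100), 100.0), t_onset_s=0.0)
    sf = spectral_triplets(rec)
    assert sf.flagged.all()
    np.testing.assert_array_equal(sf.vector, 0.0)


def test_correlated_vs_anticorrelated_phase_differs_by_pi():
    """Two sensors with opposite odor preference: in-phase trains give equal
    dominant-peak phases, half-cycle-shifted trains differ by ~pi."""
    fs, n = 1000, 1100
    t = np.arange(n) / fs
    f0 = 5.0
    mod = 0.2 * np.sin(2 * np.pi * f0 * t)
    corr = np.stack([np.exp(mod + 10), np.exp(mod + 10)])
    anti = np.stack([np.exp(mod + 10), np.exp(-mod + 10)])
    ph_corr = spectral_triplets(_mock_recording(corr, 0.0),
                                sensors=(0, 1)).phases_rad
    ph_anti = spectral_triplets(_mock_recording(anti, 0.0),
                                sensors=(0, 1)).phases_rad
    d_corr = np.angle(np.exp(1j * (ph_corr[0] - ph_corr[1])))
    d_anti = np.angle(np.exp(1j * (ph_anti[0] - ph_anti[1])))
    assert abs(d_corr) < 0.1
    assert abs(abs(d_anti) - np.pi) < 0.1


def test_dc_bin_never_selected():
    fs, n = 1000, 1100
    gas = np.exp(np.linspace(10, 11, n))        # pure drift ~ DC + low bins
    sf = spectral_triplets(_mock_recording(gas, 0.0), sensors=(0,))
    assert sf.frequencies_hz[0] > 0.0


# ---------------------------------------------------------------------------
# PID onset/offset bounds
# ---------------------------------------------------------------------------

def test_delayed_step_onset_bound():
    rng = np.random.default_rng(0)
    pid = rng.normal(0, 1e-4, 5000)
    pid[2010:3000] += 1.0                       # 10 ms delayed step
    res = pid_onset_offset(pid, 2000.0, 3000.0)
    assert res.detected
    assert res.onset_bound_ms == pytest.approx(10.0, abs=1.0)


def test_pure_noise_flags_no_detection():
    rng = np.random.default_rng(1)
    pid = rng.normal(0, 1e-3, 5000)
    res = pid_onset_offset(pid, 2000.0, 3000.0)
    assert not res.detected
    assert np.isnan(res.onset_bound_ms)
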