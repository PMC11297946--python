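"""dF/F correction, z-scoring, PETH construction and AUC quantification."""

import numpy as np
import pytest

from shuttlekit import photometry as ph
from shuttlekit.session_io import PhotometryTrace
from shuttlekit.synthetic_data import (PhotometryModel, SessionConfig,
                                       generate_session, transient_kernel)


def _trace(signal, iso, rate=100.0):
    return PhotometryTrace(rate, 0.0, np.asarray(signal, float),
                           np.asarray(iso, float))


# ---------------------------------------------------------------------------
# isosbestic fit & dF/F
# ---------------------------------------------------------------------------

def test_fit_recovers_exact_affine_map():
    iso = np.linspace(1.0, 2.0, 500)
    slope, intercept = ph.fit_isosbestic(_trace(2.0 * iso + 3.0, iso))
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(3.0)


def test_identity_channels_give_zero_dff():
    iso = 1.0 + 0.1 * np.sin(np.linspace(0, 20, 2000))
    dff = ph.compute_dff(_trace(iso, iso))
    assert dff.fit[0] == pytest.approx(1.0)
    assert dff.fit[1] == pytest.approx(0.0, abs=1e-12)
    assert np.nanmax(np.abs(dff.dff)) < 1e-12


def test_fit_recovers_generator_map_under_noise(quiet_pm):
    pm = PhotometryModel(noise_sd=0.004, motion_artifact_sd=0.0,
                         ws_amp_avoidance=0.0, ws_amp_escape=0.0,
                         preshuttle_dip_amp=0.0, rebound_amp=0.0)
    session, _ = generate_session(SessionConfig(n_trials=5, seed=21), pm)
    slope, _ = ph.fit_isosbestic(session.photometry)
    assert slope == pytest.approx(1.0 / pm.iso_gain, rel=0.01)


def test_constant_isosbestic_is_degenerate():
    with pytest.raises(ph.DegenerateFitError):
        ph.fit_isosbestic(_trace(np.arange(10.0), np.ones(10)))


def test_dff_pointwise_values():
    dff = ph.compute_dff(_trace([110.0, 100.0], [100.0, 100.0]), fit=(1.0, 0.0))
    np.testing.assert_allclose(dff.dff, [0.10, 0.0])


def test_nonpositive_fitted_control_masked():
    dff = ph.compute_dff(_trace([1.0, 1.0, 1.0], [1.0, -2.0, 1.0]), fit=(1.0, 0.0))
    assert dff.n_masked == 1
    assert np.isnan(dff.dff[1])


def test_transient_free_session_dff_stays_small():
    """Without transients, |dF/F| stays within a noise-scale bound (the
    generator's noise_sd over the fitted control, plus artifact mismatch;
    bound frozen at 6x that scale from a seeded reference draw)."""
    pm = PhotometryModel(ws_amp_avoidance=0.0, ws_amp_escape=0.0,
                         preshuttle_dip_amp=0.0, rebound_amp=0.0)
    session, _ = generate_session(SessionConfig(n_trials=5, seed=31), pm)
    dff = ph.compute_dff(session.photometry)
    noise_scale = pm.noise_sd * np.sqrt(1 + (1 / pm.iso_gain) ** 2) / pm.baseline_f
    assert np.nanmax(np.abs(dff.dff)) < 6.0 * noise_scale


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def test_zscore_standardizes_against_baseline():
    base = np.array([-1.0, 1.0])  # mean 0, sd 1
    z = ph.zscore(np.array([2.0, 0.0]), base)
    np.testing.assert_allclose(z, [2.0, 0.0])


def test_zscore_shift_invariance_of_transients():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 1, 200)
    sig = np.concatenate([base, base.mean() + np.array([5.0])])
    z1 = ph.zscore(sig, base)
    z2 = ph.zscore(sig + 10.0, base + 10.0)
    np.testing.assert_allclose(z1, z2, atol=1e-9)


def test_zscore_zero_sd_errors():
    with pytest.raises(ValueError):
        ph.zscore(np.ones(5), np.ones(10))


# ---------------------------------------------------------------------------
# PETH
# ---------------------------------------------------------------------------

def _flat_dff(n=6000, rate=100.0):
    rng = np.random.default_rng(0)
    t = np.arange(n) / rate
    return ph.DFFTrace(t, rng.normal(0, 0.01, n), (1.0, 0.0))


def test_peth_shape_one_event():
    peth = ph.build_peth(_flat_dff(), np.array([30.0]), "ws_onset", window=(2.0, 2.0))
    assert peth.matrix.shape == (1, 400)
    assert peth.time[0] == pytest.approx(-2.0)


def test_peth_zero_events_empty():
    peth = ph.build_peth(_flat_dff(), np.array([]), "ws_onset")
    assert peth.n_trials == 0


def test_peth_drops_edge_events():
    peth = ph.build_peth(_flat_dff(), np.array([0.5, 30.0]), "ws_onset",
                         window=(2.0, 2.0))
    assert peth.n_trials == 1


def test_peth_locked_transient_peaks_near_zero(full_session):
    cfg, session, gt = full_session
    pm = PhotometryModel()
    dff = ph.compute_dff(session.photometry)
    ws = session.events.of_kind("WS")
    labels = [{"outcome": o} for o in gt.trial_outcomes]
    peth = ph.build_peth(dff, ws["onset_s"].to_numpy(), "ws_onset", labels=labels)
    avoid = np.array([lab["outcome"] == "avoidance" for lab in peth.labels])
    mean = peth.matrix[avoid].mean(axis=0)
    t_peak = peth.time[np.argmax(mean)]
    # kernel peak time for rise 0.2 s / decay 1.5 s is ~0.46 s
    assert 0.0 < t_peak < 1.0
    kern = transient_kernel(peth.time, pm.transient_rise_tau, pm.transient_decay_tau)
    assert np.corrcoef(mean, kern)[0, 1] >= 0.95


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _peth_from_rows(rows, window=(2.0, 2.0), rate=100.0):
    return ph.PETH("ws_onset", window, np.atleast_2d(np.asarray(rows, float)),
                   rate, [{} for _ in range(np.atleast_2d(rows).shape[0])])


def test_unit_z_gives_unit_bin_auc():
    rows = np.ones(400)
    auc = ph.binned_auc(_peth_from_rows(rows))
    np.testing.assert_allclose(auc.values[0][:-1], 1.0, atol=1e-9)
    # final bin misses its right edge sample (0.99 s of support)
    assert auc.values[0][-1] == pytest.approx(0.99)


def test_triangle_bin_auc_half():
    rate = 100
    tri = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
    row = np.concatenate([tri, np.zeros(400 - tri.size)])
    auc = ph.binned_auc(_peth_from_rows(row))
    assert auc.values[0][0] == pytest.approx(0.5, abs=1e-6)


def test_binned_auc_additivity():
    rng = np.random.default_rng(9)
    row = rng.normal(size=1000)
    peth = _peth_from_rows(row, window=(5.0, 5.0), rate=100.0)
    auc = ph.binned_auc(peth)
    whole = np.trapezoid(row, dx=0.01)
    assert auc.values.sum() == pytest.approx(whole, abs=1e-9)


def test_epoch_auc_zero_signal():
    t = np.arange(1000) / 100.0
    out = ph.epoch_auc(np.zeros(1000), t, {"pre": (0, 3), "during": (3, 6),
                                           "post": (6, 9)})
    assert all(v == pytest.approx(0.0) for v in out.values())


def test_epoch_auc_rejects_overlap():
    t = np.arange(1000) / 100.0
    with pytest.raises(ValueError):
        ph.epoch_auc(np.zeros(1000), t, {"pre": (0, 5), "during": (4, 6)})


def test_opto_suppression_and_rebound_ordering():
    cfg = SessionConfig(n_trials=8, seed=13, opto_light=True)
    session, _ = generate_session(cfg)
    dff = ph.compute_dff(session.photometry)
    opto = session.events.of_kind("OPTO")
    pre_vals, during_vals, post_vals = [], [], []
    for _, row in opto.iterrows():
        on, off = row["onset_s"], row["offset_s"]
        base = dff.dff[(dff.t >= on - 5) & (dff.t < on)]
        if base.size < 100:  # pre-light window outside the trace (first trial)
            continue
        z = ph.zscore(dff.dff, base)
        out = ph.epoch_auc(z, dff.t, {"pre": (on - 5, on), "during": (on, off),
                                      "post2": (off, off + 2)})
        pre_vals.append(out["pre"])
        during_vals.append(out["during"])
        post_vals.append(out["post2"])
    assert np.mean(during_vals) < np.mean(pre_vals)
    assert np.mean(post_vals) > np.mean(pre_vals)


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def test_avoidance_rows_sorted_by_latency():
    matrix = np.zeros((3, 40))
    labels = [{"outcome": "avoidance", "latency": lat} for lat in (5.0, 2.0, 9.0)]
    peth = ph.PETH("ws_onset", (2.0, 2.0), matrix, 10.0, labels)
    np.testing.assert_array_equal(ph.order_heatmap(peth), [1, 0, 2])


def test_escape_rows_sorted_by_ws_delta():
    rate, window = 10.0, (2.0, 2.0)
    deltas = [-1.0, 2.0, 0.0]
    matrix = np.stack([np.concatenate([np.zeros(20), np.full(20, d)])
                       for d in deltas])
    labels = [{"outcome": "escape"}] * 3
    peth = ph.PETH("ws_onset", window, matrix, rate, labels)
    np.testing.assert_array_equal(ph.order_heatmap(peth), [0, 2, 1])


def test_single_row_identity_and_missing_latency_last():
    matrix = np.zeros((1, 40))
    peth = ph.PETH("ws_onset", (2.0, 2.0), matrix, 10.0,
                   [{"outcome": "avoidance", "latency": 1.0}])
    np.testing.assert_array_equal(ph.order_heatmap(peth), [0])
    matrix = np.zeros((2, 40))
    peth = ph.PETH("ws_onset", (2.0, 2.0), matrix, 10.0,
                   [{"outcome": "avoidance", "latency": None},
                    {"outcome": "avoidance", "latency": 3.0}])
    np.testing.assert_array_equal(ph.order_heatmap(peth), [1, 0])
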