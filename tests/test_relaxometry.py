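"""T2 fitting: exact recovery, degeneracy, filtering, oracle agreement."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from pclt2.io import T2Map
from pclt2.relaxometry import FitConfig, fit_t2_pixelwise, summarize_roi

from .conftest import make_volume


def decay_volume(s0, t2, echo_times, shape=(1, 1, 1), noise=None, rng=None):
    te = np.asarray(echo_times)
    n = int(np.prod(shape))
    clean = s0 * np.exp(-te[:, None] / t2)
    sig = np.broadcast_to(clean, (len(te), n)).copy()
    if noise:
        sig = np.abs(sig + rng.normal(0, noise, sig.shape))
    return make_volume(sig.reshape((len(te),) + tuple(shape)))


@pytest.mark.parametrize("s0,t2", [(1000.0, 40.0), (50.0, 12.5), (777.0, 150.0)])
def test_noiseless_recovery_is_exact(s0, t2, echo_times):
    m = fit_t2_pixelwise(decay_volume(s0, t2, echo_times))
    assert m.t2.ravel()[0] == pytest.approx(t2, abs=1e-6)
    assert m.s0.ravel()[0] == pytest.approx(s0, rel=1e-6)
    assert m.r2_adj.ravel()[0] == pytest.approx(1.0, abs=1e-9)
    assert m.valid.all()


def test_constant_signal_is_degenerate_invalid(echo_times):
    vol = make_volume(np.full((5, 1, 1, 1), 500.0))
    m = fit_t2_pixelwise(vol)
    assert not m.valid.any()
    assert np.isnan(m.t2).all()


def test_scale_equivariance(echo_times):
    rng = np.random.default_rng(3)
    v1 = decay_volume(900.0, 35.0, echo_times, (1, 5, 5), noise=15.0, rng=rng)
    v2 = make_volume(v1.signal * 7.5)
    m1 = fit_t2_pixelwise(v1)
    m2 = fit_t2_pixelwise(v2)
    np.testing.assert_allclose(m2.t2, m1.t2, rtol=1e-6)
    np.testing.assert_allclose(m2.s0, 7.5 * m1.s0, rtol=1e-6)
    np.testing.assert_allclose(m2.r2_adj, m1.r2_adj, rtol=1e-8)


def test_raising_threshold_never_gains_valid_voxels(echo_times):
    rng = np.random.default_rng(7)
    vol = decay_volume(1000.0, 30.0, echo_times, (1, 30, 30), noise=120.0, rng=rng)
    counts = [
        int(fit_t2_pixelwise(vol, cfg=FitConfig(r2_threshold=thr)).valid.sum())
        for thr in (0.5, 0.9, 0.99)
    ]
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[0] > counts[2]  # the noisy batch actually straddles the gates


def test_matches_per_voxel_curve_fit_oracle(echo_times):
    """Vectorized LM agrees with scipy's independent per-voxel optimizer."""
    rng = np.random.default_rng(11)
    te = np.asarray(echo_times)
    vol = decay_volume(1000.0, 45.0, echo_times, (1, 6, 8), noise=25.0, rng=rng)
    m = fit_t2_pixelwise(vol)
    sig = vol.signal.reshape(5, -1)
    for i in range(sig.shape[1]):
        y = sig[:, i]
        popt, _ = curve_fit(lambda t, a, b: a * np.exp(-t / b), te, y,
                            p0=[y[0], 40.0], maxfev=10000)
        assert m.t2.ravel()[i] == pytest.approx(popt[1], abs=0.1)


def test_monte_carlo_estimator_recovery(echo_times):
    """10k noisy decays: small bias, high validity; pure noise rejected."""
    rng = np.random.default_rng(42)
    vol = decay_volume(1000.0, 35.0, echo_times, (1, 100, 100), noise=20.0, rng=rng)
    m = fit_t2_pixelwise(vol)
    assert abs(np.nanmean(m.t2) - 35.0) < 1.0
    assert m.valid.mean() >= 0.95

    noise = make_volume(np.abs(rng.normal(0, 20.0, (5, 1, 100, 100))))
    mn = fit_t2_pixelwise(noise)
    assert (~mn.valid).mean() >= 0.99


def test_roi_outside_voxels_left_invalid(echo_times):
    vol = decay_volume(800.0, 50.0, echo_times, (1, 4, 4))
    roi = np.zeros((1, 4, 4), bool)
    roi[0, :2] = True
    m = fit_t2_pixelwise(vol, roi)
    assert m.valid[roi].all()
    assert not m.valid[~roi].any()
    assert np.isnan(m.t2[~roi]).all()


def _toy_map(values, valid):
    t2 = np.asarray(values, float)[None, None, :]
    v = np.asarray(valid, bool)[None, None, :]
    return T2Map(t2=t2, s0=np.ones_like(t2), r2_adj=np.ones_like(t2),
                 valid=v, voxel_spacing=(3.2, 0.4, 0.4))


def test_summarize_roi_hand_arithmetic():
    m = _toy_map([30.0, 34.0, 36.0, 40.0], [1, 1, 1, 1])
    roi = np.ones((1, 1, 4), bool)
    s = summarize_roi(m, roi)
    assert s.mean == pytest.approx(35.0)
    assert s.median == pytest.approx(35.0)
    assert s.n_valid == 4
    assert s.hist_counts.sum() == 4
    assert s.hist_edges[0] == 0.0 and s.hist_edges[-1] == pytest.approx(80.0)


def test_summarize_roi_uses_only_valid_voxels():
    m = _toy_map([30.0, 34.0, 900.0, 900.0], [1, 1, 0, 0])
    s = summarize_roi(m, np.ones((1, 1, 4), bool))
    assert s.mean == pytest.approx(32.0)
    assert s.n_valid == 2 and s.n_total == 4


def test_summarize_roi_empty_sentinel_and_errors():
    m = _toy_map([30.0, 34.0], [0, 0])
    with pytest.warns(UserWarning, match="no valid"):
        s = summarize_roi(m, np.ones((1, 1, 2), bool))
    assert s.empty and np.isnan(s.mean)
    with pytest.raises(ValueError, match="empty"):
        summarize_roi(m, np.zeros((1, 1, 2), bool))


def test_too_few_echoes_rejected():
    vol = make_volume(np.ones((2, 1, 1, 1)), echo_times=[10.0, 20.0])
    with pytest.raises(ValueError, match="echoes"):
        fit_t2_pixelwise(vol)
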