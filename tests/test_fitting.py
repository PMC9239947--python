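"""Least-squares inversion: initialization, round trips, oracle checks."""

import dataclasses
import math

import numpy as np
import pytest

from mdmefit import FitOptions, fit_maps, fit_signal, init_estimates
from mdmefit.fitting import DEFAULT_BOUNDS
from mdmefit.phantom import NoiseModel, build_phantom, default_layout, simulate_acquisition
from mdmefit.signal import SignalSample, SignalSet, mdme_signal_arrays

from conftest import magnitude_signal_set


def _grid_sse(y, p, t1g, t2g, b1g):
    """SSE over a (T1, T2, B1) grid with M0 solved in closed form per point."""
    te = np.repeat([p.te1_ms, p.te2_ms], 4)
    ti = np.tile(p.delay_times_ms, 2)
    T1, T2, B1 = np.meshgrid(t1g, t2g, b1g, indexing="ij")
    shape = np.abs(mdme_signal_arrays(
        T1[..., None], T2[..., None], 1.0, B1[..., None],
        te, ti, p.tr_ms, p.flip_excitation_deg, p.flip_saturation_deg))
    m0 = np.sum(shape * y, axis=-1) / np.sum(shape ** 2, axis=-1)
    sse = np.sum((m0[..., None] * shape - y) ** 2, axis=-1)
    return sse, m0


def grid_search_oracle(y, p, n_coarse=(60, 60, 21), n_zoom=15, zoom_stages=3):
    """Independent brute-force minimizer: coarse grid + basin refinement.

    The magnitude model can have near-degenerate secondary minima in the
    (T1, B1) trade-off, so every per-B1-slice coarse optimum is treated as a
    candidate basin and refined by shrinking grids; the best refined point
    wins.  Returns the minimizer, its per-parameter final spacings, and its
    SSE.  Uses only forward-model evaluations (no derivatives, no solver).
    """
    lo_t1, hi_t1 = DEFAULT_BOUNDS["t1_ms"]
    lo_t2, hi_t2 = DEFAULT_BOUNDS["t2_ms"]
    lo_b1, hi_b1 = DEFAULT_BOUNDS["b1"]
    t1g = np.geomspace(lo_t1, hi_t1, n_coarse[0])
    t2g = np.geomspace(lo_t2, hi_t2, n_coarse[1])
    b1g = np.linspace(lo_b1, hi_b1, n_coarse[2])
    sse, _ = _grid_sse(y, p, t1g, t2g, b1g)
    # one candidate basin per B1 slice
    candidates = []
    for k in range(len(b1g)):
        i, j = np.unravel_index(np.argmin(sse[:, :, k]), sse[:, :, k].shape)
        candidates.append((t1g[i], t2g[j], b1g[k]))

    # refinement: shrink a local grid around each candidate
    w_t1 = math.log(t1g[1] / t1g[0]) * 2     # half-widths, +/- 2 coarse spacings
    w_t2 = math.log(t2g[1] / t2g[0]) * 2
    w_b1 = (b1g[1] - b1g[0]) * 2
    best = (np.inf, None, None)
    for (c1, c2, cb) in candidates:
        h1, h2, hb = w_t1, w_t2, w_b1
        for _ in range(zoom_stages):
            g1 = np.clip(np.exp(np.linspace(math.log(c1) - h1, math.log(c1) + h1,
                                            n_zoom)), lo_t1, hi_t1)
            g2 = np.clip(np.exp(np.linspace(math.log(c2) - h2, math.log(c2) + h2,
                                            n_zoom)), lo_t2, hi_t2)
            gb = np.clip(np.linspace(cb - hb, cb + hb, n_zoom), lo_b1, hi_b1)
            s, m0 = _grid_sse(y, p, g1, g2, gb)
            i, j, k = np.unravel_index(np.argmin(s), s.shape)
            c1, c2, cb = g1[i], g2[j], gb[k]
            shrink = 4.0 / (n_zoom - 1)      # keep +/- 2 new spacings
            h1, h2, hb = h1 * shrink, h2 * shrink, hb * shrink
        if s[i, j, k] < best[0]:
            best = (s[i, j, k], (c1, c2, m0[i, j, k], cb),
                    (c1 * 2 * h1, c2 * 2 * h2, 2 * hb))
    sse_min, params, spacing = best
    return params, spacing, sse_min


def test_init_t2_exact_for_noise_free_gm(etl1):
    s = magnitude_signal_set(1100.0, 139.0, 400.0, etl1)
    init = init_estimates(s, etl1)
    assert not init.fallback
    assert init.t2_ms == pytest.approx(139.0, rel=0.01)
    assert init.t1_ms == pytest.approx(1100.0, rel=0.25)
    assert init.m0 == pytest.approx(400.0, rel=0.25)


def test_init_flags_degenerate_equal_echoes(etl1):
    flat = SignalSet(tuple(
        SignalSample(te, ti, 100.0)
        for te in (etl1.te1_ms, etl1.te2_ms) for ti in etl1.delay_times_ms))
    init = init_estimates(flat, etl1)
    assert init.fallback
    lo, hi = DEFAULT_BOUNDS["t2_ms"]
    assert init.t2_ms == pytest.approx(0.5 * (lo + hi))


def test_init_scale_equivariance(etl1):
    a = init_estimates(magnitude_signal_set(1100.0, 139.0, 40.0, etl1), etl1)
    b = init_estimates(magnitude_signal_set(1100.0, 139.0, 400.0, etl1), etl1)
    assert b.t2_ms == pytest.approx(a.t2_ms, rel=1e-12)
    assert b.t1_ms == pytest.approx(a.t1_ms, rel=1e-12)
    assert b.m0 == pytest.approx(10.0 * a.m0, rel=1e-12)


@pytest.mark.parametrize("label", ["GM", "WM", "CSF"])
def test_noise_free_round_trip_recovers_truth(etl1, vial_truths, label):
    t1, t2, m0 = vial_truths[label]
    r = fit_signal(magnitude_signal_set(t1, t2, m0, etl1), etl1)
    assert r.converged
    assert r.t1_ms == pytest.approx(t1, rel=1e-6)
    assert r.t2_ms == pytest.approx(t2, rel=1e-6)
    assert r.m0 == pytest.approx(m0, rel=1e-6)
    assert r.b1 == pytest.approx(1.0, abs=1e-6)
    assert r.residual_norm < 1e-9 * m0


def test_b1_identifiable_from_recovery_shape(etl1):
    s = magnitude_signal_set(1100.0, 139.0, 400.0, etl1, b1=0.9)
    r = fit_signal(s, etl1)
    assert r.b1 == pytest.approx(0.9, abs=1e-4)
    assert r.t1_ms == pytest.approx(1100.0, rel=1e-4)
    (got_t1, _t2, _m0, got_b1), (dt1, _dt2, db1), _sse = grid_search_oracle(
        np.abs(s.intensities), etl1)
    assert abs(got_b1 - 0.9) <= db1
    assert abs(got_t1 - 1100.0) <= dt1


def test_fit_matches_grid_search_oracle_on_random_draws(etl1):
    rng = np.random.default_rng(2024)
    for _ in range(20):
        t1 = 10 ** rng.uniform(math.log10(300), math.log10(3500))
        t2 = 10 ** rng.uniform(math.log10(40), math.log10(min(t1, 2000)))
        m0 = rng.uniform(100.0, 900.0)
        b1 = rng.uniform(0.75, 1.25)
        s = magnitude_signal_set(t1, t2, m0, etl1, b1=b1)
        r = fit_signal(s, etl1)
        (gt1, gt2, gm0, gb1), (dt1, dt2, db1), sse_oracle = grid_search_oracle(
            np.abs(s.intensities), etl1)
        assert abs(r.t1_ms - gt1) <= dt1
        assert abs(r.t2_ms - gt2) <= dt2
        assert abs(r.b1 - gb1) <= db1
        # the continuous solver is at least as good as the exhaustive search
        assert 8 * r.residual_norm ** 2 <= sse_oracle + 1e-9
        assert r.t1_ms == pytest.approx(t1, rel=1e-5)
        assert r.t2_ms == pytest.approx(t2, rel=1e-5)


def test_median_fit_unbiased_at_low_noise(etl1, vial_truths):
    t1, t2, m0 = vial_truths["GM"]
    clean = np.abs(magnitude_signal_set(t1, t2, m0, etl1).intensities)
    sigma = 0.01 * clean.max()
    rng = np.random.default_rng(99)
    t1s, t2s = [], []
    for _ in range(200):
        y = np.hypot(clean + rng.normal(0, sigma, 8), rng.normal(0, sigma, 8))
        s = SignalSet(tuple(
            SignalSample(v.te_ms, v.ti_ms, yi) for v, yi in
            zip(magnitude_signal_set(t1, t2, m0, etl1).samples, y)))
        r = fit_signal(s, etl1)
        t1s.append(r.t1_ms)
        t2s.append(r.t2_ms)
    assert abs(np.median(t1s) / t1 - 1) < 0.005
    assert abs(np.median(t2s) / t2 - 1) < 0.005


def test_very_long_t2_is_less_precise_than_short(etl1, vial_truths):
    """Relative spread of fitted T2 at matched SNR: CSF >> GM.

    With echo times of 18.9/94.4 ms the decay between echoes of a 1790 ms
    T2 medium is tiny, so its T2 estimate is intrinsically noisier than for
    T2 = 139 ms - the known weakness of sparse multi-echo relaxometry for
    fluids.
    """
    rng = np.random.default_rng(7)
    rel_sd = {}
    for label in ("GM", "CSF"):
        t1, t2, _ = vial_truths[label]
        clean = np.abs(magnitude_signal_set(t1, t2, 500.0, etl1).intensities)
        sigma = 0.01 * clean.max()  # matched SNR
        fits = []
        for _ in range(200):
            y = np.hypot(clean + rng.normal(0, sigma, 8), rng.normal(0, sigma, 8))
            s = SignalSet(tuple(
                SignalSample(v.te_ms, v.ti_ms, yi) for v, yi in
                zip(magnitude_signal_set(t1, t2, 500.0, etl1).samples, y)))
            fits.append(fit_signal(s, etl1).t2_ms)
        rel_sd[label] = np.std(fits) / t2
    assert rel_sd["CSF"] > rel_sd["GM"]


def test_all_zero_signals_flagged_not_fitted(etl1):
    zero = SignalSet(tuple(
        SignalSample(te, ti, 0.0)
        for te in (etl1.te1_ms, etl1.te2_ms) for ti in etl1.delay_times_ms))
    r = fit_signal(zero, etl1)
    assert not r.converged and r.n_iter == 0
    assert math.isnan(r.t1_ms)


def test_fix_b1_option(etl1, vial_truths):
    t1, t2, m0 = vial_truths["WM"]
    r = fit_signal(magnitude_signal_set(t1, t2, m0, etl1),
                   etl1, FitOptions(fix_b1=True))
    assert r.b1 == 1.0
    assert r.t1_ms == pytest.approx(t1, rel=1e-6)
    assert r.t2_ms == pytest.approx(t2, rel=1e-6)


def test_fit_maps_noise_free_uniform_and_deterministic(etl1):
    layout = default_layout(image_size=40)
    truth = build_phantom(layout, 40)
    stack = simulate_acquisition(truth, etl1, NoiseModel(sigma_ref=0.0, kind="none"))
    maps = fit_maps(stack, etl1, fov_mm=layout.fov_mm)
    for k, tissue in enumerate(truth.tissues, start=1):
        sel = truth.label_map == k
        assert np.all(np.isfinite(maps.t1_map[sel]))
        assert maps.t1_map[sel] == pytest.approx(tissue.t1_ms, rel=1e-6)
        assert maps.t2_map[sel] == pytest.approx(tissue.t2_ms, rel=1e-6)
    assert np.all(np.isnan(maps.t1_map[truth.label_map == 0]))
    assert np.all(maps.converged_mask[truth.label_map > 0])

    again = fit_maps(stack, etl1, fov_mm=layout.fov_mm)
    assert np.array_equal(maps.t1_map, again.t1_map, equal_nan=True)


def test_fit_maps_all_background_is_empty(etl1):
    stack = np.zeros((8, 16, 16))
    maps = fit_maps(stack, etl1)
    assert not maps.converged_mask.any()
    assert np.all(np.isnan(maps.t1_map))


def test_fit_maps_rejects_bad_shape(etl1):
    with pytest.raises(ValueError, match="shape"):
        fit_maps(np.zeros((7, 16, 16)), etl1)
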