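"""Decay fitting, trace averaging and smoothing.

The independent oracle for the nonlinear fit is a brute-force grid search
over the decay rate: for each candidate k the amplitude and offset are the
exact linear least-squares solution, so the grid minimizes the same RSS
as the fit without sharing any code path with it.
"""

import numpy as np
import pytest

import plimox as px
from plimox.plim_core import fit_decay, _decay_samples

T_BODY = 36.7


def _make_trace(k, i0=1.0, offset=0.05, cfg=None, noise=0.0, rng=None):
    t = cfg.time_axis
    tr = np.empty(cfg.n_time)
    pulse = t < cfg.pulse_duration
    tr[pulse] = i0 + offset
    td = t[~pulse] - cfg.pulse_duration
    tr[~pulse] = i0 * np.exp(-k * td) + offset
    if noise > 0:
        tr = tr + rng.normal(0.0, noise, tr.shape)
    return tr


def grid_search_oracle(trace, cfg, k_grid):
    """Best (k, rss) over a rate grid; amplitude/offset solved linearly."""
    td, idx = _decay_samples(cfg)
    y = trace[idx]
    best_k, best_rss = np.nan, np.inf
    for k in k_grid:
        design = np.column_stack([np.exp(-k * td), np.ones_like(td)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((design @ coef - y) ** 2).sum())
        if rss < best_rss:
            best_k, best_rss = k, rss
    return best_k, best_rss


class TestIntensityImage:
    def test_constant_plateau_mean(self, acq_noiseless):
        tr = _make_trace(30e3, i0=0.7, offset=0.05, cfg=acq_noiseless)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        stack = px.TraceStack(data=data, config=acq_noiseless,
                              temperature=T_BODY)
        np.testing.assert_allclose(px.intensity_image(stack), 0.75)

    def test_pulse_sample_count(self):
        cfg = px.AcquisitionConfig(pulse_duration=10e-6, sampling_rate=5e6)
        assert cfg.n_pulse_samples == 50

    def test_background_pixel_reads_baseline(self, acq_noiseless):
        tr = px.simulate_trace(50.0, T_BODY, 0.0, acq_noiseless)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        stack = px.TraceStack(data=data, config=acq_noiseless,
                              temperature=T_BODY)
        np.testing.assert_allclose(px.intensity_image(stack),
                                   acq_noiseless.pmt_baseline)


class TestAveraging:
    def test_mean_of_identical_stacks_is_identity(self, phantom_small,
                                                  sectioning_wide,
                                                  acq_small_noiseless):
        s = px.simulate_acquisition(phantom_small, sectioning_wide,
                                    acq_small_noiseless, seed=0)
        avg = px.average_acquisitions([s, s, s])
        np.testing.assert_allclose(avg.data, s.data, rtol=1e-15)

    def test_single_stack_identity(self, phantom_small, sectioning_wide,
                                   acq_small_noiseless):
        s = px.simulate_acquisition(phantom_small, sectioning_wide,
                                    acq_small_noiseless, seed=0)
        np.testing.assert_array_equal(px.average_acquisitions([s]).data,
                                      s.data)

    def test_variance_reduction(self):
        """Monte-Carlo: averaging n i.i.d. Gaussian stacks cuts the residual
        variance by 1/n over >=100 pixels."""
        cfg = px.AcquisitionConfig(grid_shape=(12, 12), sampling_rate=1e6,
                                   noise_a=4e-4, noise_b=0.0)
        ph = px.Phantom(grid_shape=(12, 12), pixel_pitch=2.0, vessels=(
            px.VesselSpec(1, "arteriole",
                          np.array([[12.0, 0.0], [12.0, 24.0]]),
                          30.0, 10.0, 60.0),),
            background_intensity=0.0, temperature=T_BODY)
        sec = px.SectioningModel(focal_depth=10.0)
        from dataclasses import replace
        noiseless = px.simulate_acquisition(ph, sec,
                                            replace(cfg, noise_model="none"),
                                            seed=0)
        n = 4
        stacks = [px.simulate_acquisition(ph, sec, cfg, seed=s)
                  for s in range(n)]
        avg = px.average_acquisitions(stacks)
        resid = avg.data - noiseless.data
        var = resid.var()
        assert var == pytest.approx(4e-4 / n, rel=0.1)

    def test_mismatched_stacks_rejected(self, acq_noiseless):
        tr = _make_trace(30e3, cfg=acq_noiseless)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        a = px.TraceStack(data=data, config=acq_noiseless, temperature=T_BODY)
        other_cfg = px.AcquisitionConfig(grid_shape=(8, 8),
                                         noise_model="none",
                                         pmt_baseline=0.1)
        b = px.TraceStack(data=data.copy(), config=other_cfg,
                          temperature=T_BODY)
        with pytest.raises(ValueError):
            px.average_acquisitions([a, b])


class TestSmoothing:
    def _stack_from_image(self, img, cfg):
        data = np.broadcast_to(img, (cfg.n_time,) + img.shape).copy()
        return px.TraceStack(data=data, config=cfg, temperature=T_BODY)

    @pytest.fixture
    def cfg5(self):
        return px.AcquisitionConfig(grid_shape=(5, 5), sampling_rate=1e6,
                                    noise_model="none")

    def test_constant_stack_unchanged(self, cfg5):
        stack = self._stack_from_image(np.full((5, 5), 3.3), cfg5)
        np.testing.assert_allclose(px.spatial_smooth_3x3(stack).data, 3.3)

    def test_interior_impulse_response(self, cfg5):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        sm = px.spatial_smooth_3x3(self._stack_from_image(img, cfg5))
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        np.testing.assert_allclose(sm.data[0], expected)

    def test_corner_uses_shrunken_window(self, cfg5):
        img = np.zeros((5, 5))
        img[0, 0] = 4.0
        sm = px.spatial_smooth_3x3(self._stack_from_image(img, cfg5))
        assert sm.data[0, 0, 0] == pytest.approx(1.0)

    def test_interior_mass_conserved(self):
        """Smoothing conserves the spatial sum when no mass touches the
        border (interior-exact conservation)."""
        cfg = px.AcquisitionConfig(grid_shape=(16, 16), sampling_rate=1e6,
                                   noise_model="none")
        rng = np.random.default_rng(3)
        img = np.zeros((16, 16))
        img[2:-2, 2:-2] = rng.random((12, 12))
        sm = px.spatial_smooth_3x3(self._stack_from_image(img, cfg))
        assert sm.data[0].sum() == pytest.approx(img.sum(), rel=1e-12)


class TestFitDecay:
    def test_noiseless_recovery(self, acq_noiseless):
        tr = _make_trace(30e3, i0=1.0, offset=0.05, cfg=acq_noiseless)
        fit = fit_decay(tr, acq_noiseless)
        assert fit.success
        assert fit.k == pytest.approx(30e3, rel=1e-8)
        assert fit.tau == 1.0 / fit.k
        assert fit.offset == pytest.approx(0.05, abs=1e-8)

    def test_constant_trace_fails(self, acq_noiseless):
        fit = fit_decay(np.full(acq_noiseless.n_time, 0.2), acq_noiseless)
        assert not fit.success
        assert np.isnan(fit.k) and np.isnan(fit.tau)

    def test_monotone_in_injected_rate(self, acq_noiseless):
        ks = np.linspace(27e3, 75e3, 15)
        fitted = [fit_decay(_make_trace(k, cfg=acq_noiseless),
                            acq_noiseless).k for k in ks]
        assert np.all(np.diff(fitted) > 0)

    def test_matches_grid_oracle_noiseless(self, acq_noiseless):
        """Fit agrees with the brute-force RSS grid search on 50 random
        noiseless traces to within the grid resolution."""
        rng = np.random.default_rng(42)
        k_grid = np.arange(25e3, 80e3, 50.0)
        for _ in range(50):
            k = rng.uniform(27e3, 75e3)
            i0 = rng.uniform(0.3, 1.5)
            off = rng.uniform(0.0, 0.2)
            tr = _make_trace(k, i0=i0, offset=off, cfg=acq_noiseless)
            fit = fit_decay(tr, acq_noiseless)
            k_oracle, _ = grid_search_oracle(tr, acq_noiseless, k_grid)
            assert fit.success
            assert abs(fit.k - k_oracle) <= 50.0

    def test_noisy_median_bias_vs_oracle(self, acq_noiseless):
        """Under configured noise the fit's median rate error does not
        exceed the grid-search oracle's (plus one grid step)."""
        rng = np.random.default_rng(7)
        k_true = 40e3
        k_grid = np.arange(30e3, 55e3, 100.0)
        errs_fit, errs_oracle = [], []
        for _ in range(200):
            tr = _make_trace(k_true, cfg=acq_noiseless, noise=0.01, rng=rng)
            fit = fit_decay(tr, acq_noiseless)
            assert fit.success
            k_o, _ = grid_search_oracle(tr, acq_noiseless, k_grid)
            errs_fit.append(abs(fit.k - k_true) / k_true)
            errs_oracle.append(abs(k_o - k_true) / k_true)
        assert (np.median(errs_fit)
                <= np.median(errs_oracle) + 100.0 / k_true)

    def test_too_few_samples_rejected(self):
        cfg = px.AcquisitionConfig(grid_shape=(4, 4), pixel_dwell=30e-6,
                                   pulse_duration=10e-6, sampling_rate=1e6,
                                   guard_interval=12e-6, noise_model="none")
        with pytest.raises(ValueError, match="samples"):
            fit_decay(np.ones(cfg.n_time), cfg)


class TestFitMap:
    def test_smoothing_preserves_constant_rate_region(self):
        """A uniform-rate region is a fixed point: averaging identical
        exponentials changes nothing."""
        cfg = px.AcquisitionConfig(grid_shape=(8, 8), sampling_rate=1e6,
                                   noise_model="none")
        tr = _make_trace(35e3, cfg=cfg)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        stack = px.TraceStack(data=data, config=cfg, temperature=T_BODY)
        rmap = px.fit_map(stack, smoothing=True)
        assert rmap.success_mask.all()
        np.testing.assert_allclose(rmap.k_image, 35e3, rtol=1e-7)

    def test_background_pixels_fail(self, phantom_small, sectioning_wide,
                                    acq_small_noiseless):
        label, _, _ = px.render_scene(phantom_small, sectioning_wide)
        stack = px.simulate_acquisition(phantom_small, sectioning_wide,
                                        acq_small_noiseless, seed=0)
        rmap = px.fit_map(stack, smoothing=False)
        assert not rmap.success_mask[label == 0].any()
        assert np.isnan(rmap.k_image[label == 0]).all()

    def test_noisy_parameter_recovery(self):
        """>=95% of vessel pixels recover the injected rate within +-10%
        on a seeded noisy acquisition."""
        pcfg = px.PhantomConfig(grid_shape=(64, 64), n_capillaries=6)
        ph = px.generate_phantom(pcfg, seed=2)
        sec = px.SectioningModel(focal_depth=35.0, sectioning_sigma=40.0)
        cfg = px.AcquisitionConfig(grid_shape=(64, 64))
        stack = px.simulate_acquisition(ph, sec, cfg, seed=2)
        label, _, po2 = px.render_scene(ph, sec)
        rmap = px.fit_map(stack, smoothing=True)
        vessel = (label > 0) & rmap.success_mask
        assert vessel.sum() > 0.9 * (label > 0).sum()
        k_true = 1.0 / np.asarray(px.lifetime_from_po2(po2[vessel],
                                                       ph.temperature))
        rel = np.abs(rmap.k_image[vessel] - k_true) / k_true
        assert (rel < 0.10).mean() >= 0.95


class TestAverageVesselTrace:
    def test_mask_of_identical_traces(self, acq_noiseless):
        tr = _make_trace(30e3, cfg=acq_noiseless)
        data = np.tile(tr[:, None, None], (1, 8, 8))
        stack = px.TraceStack(data=data, config=acq_noiseless,
                              temperature=T_BODY)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        np.testing.assert_allclose(px.average_vessel_trace(stack, mask), tr)

    def test_mixed_rates_bracketed(self, acq_noiseless):
        k1, k2 = 30e3, 60e3
        data = np.zeros((acq_noiseless.n_time, 8, 8))
        data[:, :, :4] = _make_trace(k1, cfg=acq_noiseless)[:, None, None]
        data[:, :, 4:] = _make_trace(k2, cfg=acq_noiseless)[:, None, None]
        stack = px.TraceStack(data=data, config=acq_noiseless,
                              temperature=T_BODY)
        fit = fit_decay(px.average_vessel_trace(stack, np.ones((8, 8), bool)),
                        acq_noiseless)
        assert k1 < fit.k < k2

    def test_empty_mask_rejected(self, acq_noiseless):
        data = np.zeros((acq_noiseless.n_time, 8, 8))
        stack = px.TraceStack(data=data, config=acq_noiseless,
                              temperature=T_BODY)
        with pytest.raises(ValueError, match="empty"):
            px.average_vessel_trace(stack, np.zeros((8, 8), bool))
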