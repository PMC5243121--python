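"""Phantom generator: AIF shape, Tofts forward model, determinism, truth maps."""

import numpy as np
import pytest

from dcesub.phantom import (
    ALTERNATE_ACQUISITION,
    AcquisitionConfig,
    AifModel,
    PhantomGeometry,
    TissueParams,
    generate_aif,
    generate_phantom,
    tofts_forward,
)


class TestAif:
    def test_degenerate_peak_rejected(self):
        with pytest.raises(ValueError):
            AifModel(peak_enhancement=0.0)

    def test_onset_beyond_scan_rejected(self):
        model = AifModel(onset_time_s=300.0)
        with pytest.raises(ValueError, match="aif-onset-out-of-range"):
            generate_aif(model, AcquisitionConfig())

    def test_pre_onset_samples_zero(self):
        curve = generate_aif(AifModel(onset_time_s=30.0), AcquisitionConfig(dt_seconds=3.0))
        assert np.all(curve[:10] == 0.0)

    def test_peak_normalization(self):
        curve = generate_aif(AifModel(peak_enhancement=2.5), AcquisitionConfig())
        assert abs(curve.max() - 2.5) < 1e-6

    def test_gamma_variate_mode_matches_analytic(self):
        # pure gamma-variate (no washout): mode is alpha*beta after onset.
        alpha, beta, onset = 3.0, 4.0, 30.0
        model = AifModel(
            onset_time_s=onset, alpha=alpha, beta_s=beta, washout_weight=0.0
        )
        cfg = AcquisitionConfig(dt_seconds=3.0, n_frames=60)
        curve = generate_aif(model, cfg)
        t_argmax = cfg.times_s[np.argmax(curve)]
        # brute-force oracle: dense grid over an independently written formula
        tt = np.linspace(0.0, cfg.times_s[-1], 200001)
        rel = np.clip(tt - onset, 0, None)
        dense = rel**alpha * np.exp(-rel / beta)
        t_dense = tt[np.argmax(dense)]
        assert abs(t_dense - (onset + alpha * beta)) < 0.01
        # discretized to the nearest sample
        assert t_argmax == pytest.approx(
            cfg.dt_seconds * round(t_dense / cfg.dt_seconds), abs=1e-9
        )


class TestToftsForward:
    def test_no_exchange_gives_zero(self):
        cfg = AcquisitionConfig()
        aif = generate_aif(AifModel(), cfg)
        out = tofts_forward(aif, TissueParams(0.0, 0.0, 0.0), cfg)
        assert np.all(out == 0.0)

    def test_pure_plasma_scales_aif(self):
        cfg = AcquisitionConfig()
        aif = generate_aif(AifModel(), cfg)
        out = tofts_forward(aif, TissueParams(0.1, 0.0, 0.0), cfg)
        np.testing.assert_allclose(out, 0.1 * aif, rtol=0, atol=1e-15)

    def test_matches_dense_grid_convolution(self):
        # boxcar plasma curve: coarse trapezoid vs dt/100 brute-force within 1%
        cfg = AcquisitionConfig(n_frames=40, dt_seconds=3.0)
        t = cfg.times_s
        aif = ((t >= 30) & (t < 90)).astype(float) * 2.0
        vp, ktrans, kep = 0.05, 0.2, 0.5
        out = tofts_forward(aif, TissueParams(vp, ktrans, kep), cfg)

        fine = np.arange(0, t[-1] + 1e-9, cfg.dt_seconds / 100.0)
        aif_fine = np.interp(fine, t, aif)
        fine_min = fine / 60.0
        expect = np.empty_like(t)
        for i, ti in enumerate(t):
            m = fine <= ti + 1e-12
            tau = fine_min[m]
            integrand = aif_fine[m] * np.exp(-kep * (ti / 60.0 - tau))
            expect[i] = vp * np.interp(ti, fine, aif_fine) + ktrans * np.trapezoid(
                integrand, tau
            )
        scale = np.abs(expect).max()
        assert np.abs(out - expect).max() < 0.01 * scale

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(0.1, -0.3, 0.5)
        with pytest.raises(ValueError):
            TissueParams(1.2, 0.3, 0.5)

    @pytest.mark.parametrize("vp_pair", [(0.01, 0.05), (0.05, 0.2)])
    def test_enhancement_monotone_in_vp(self, vp_pair):
        cfg = AcquisitionConfig()
        aif = generate_aif(AifModel(), cfg)
        lo = tofts_forward(aif, TissueParams(vp_pair[0], 0.2, 0.5), cfg)
        hi = tofts_forward(aif, TissueParams(vp_pair[1], 0.2, 0.5), cfg)
        assert np.all(hi >= lo)


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = generate_phantom(AcquisitionConfig(noise_sd_rel=0.02), seed=3)
        b = generate_phantom(AcquisitionConfig(noise_sd_rel=0.02), seed=3)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[3].bv_percent, b[3].bv_percent)

    def test_noise_free_background_flat(self):
        series, tumor, artery, _ = generate_phantom(
            AcquisitionConfig(noise_sd_rel=0.0), seed=3, s0=100.0
        )
        bg = ~(tumor | artery)
        assert np.all(series.data[bg] == 100.0)

    def test_labeled_fraction_matches_blob_construction(self, phantom_002):
        truth = phantom_002["truth"]
        tumor = phantom_002["tumor"]
        labeled_frac = np.mean(truth.label_map[tumor] == 0)
        assert labeled_frac == pytest.approx(truth.lbv_fraction, abs=0.02)
        # and the label map is exactly the thresholded BV map inside the tumor
        np.testing.assert_array_equal(
            truth.label_map[tumor],
            (truth.bv_percent[tumor] >= truth.bv_threshold_percent).astype(np.int8),
        )

    def test_artery_tumor_overlap_rejected(self):
        geom = PhantomGeometry(artery_origin=(18, 18, 6), artery_size=(3, 3, 3))
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(AcquisitionConfig(), geometry=geom, seed=3)

    def test_artery_carries_aif(self):
        series, _, artery, truth = generate_phantom(
            AcquisitionConfig(noise_sd_rel=0.0), seed=3, s0=100.0
        )
        one_voxel = series.data[artery][0]
        np.testing.assert_allclose(one_voxel, 100.0 * (1.0 + truth.aif_curve), rtol=1e-12)

    def test_parameter_maps_identical_across_dialects(self):
        _, _, _, native = generate_phantom(AcquisitionConfig(), seed=11)
        _, _, _, alt = generate_phantom(ALTERNATE_ACQUISITION, seed=11)
        np.testing.assert_array_equal(native.vp, alt.vp)
        np.testing.assert_array_equal(native.label_map, alt.label_map)
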