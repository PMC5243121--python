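"""Normalization, AIF extraction, windowing and resampling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcesub.phantom import DceSeries
from dcesub.preprocess import (
    Aif,
    estimate_baseline,
    extract_aif,
    normalize_curve,
    resample_curve,
    window_curve,
    windows_from_series,
)


class TestBaseline:
    def test_constant_curve(self):
        assert estimate_baseline(np.full(60, 100.0), 10) == 100.0

    def test_mean_of_pre_onset_frames(self):
        curve = np.r_[90.0, 100.0, 110.0, np.full(30, 500.0)]
        assert estimate_baseline(curve, 3) == pytest.approx(100.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.full(60, 100.0), 2)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="nonpositive-baseline"):
            estimate_baseline(np.zeros(60), 5)


class TestNormalize:
    def test_flat_curve_maps_to_zero(self):
        out = normalize_curve(np.full(32, 100.0), 100.0, 2.5)
        np.testing.assert_array_equal(out, 0.0)

    def test_hand_arithmetic(self):
        # (150 - 100) / 100 / 2.5 = 0.2
        out = normalize_curve(np.array([150.0]), 100.0, 2.5)
        assert out[0] == pytest.approx(0.2)

    def test_nonpositive_aif_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_curve(np.full(8, 1.0), 1.0, 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, scale):
        # multiplying all signals (tissue and AIF alike) by c leaves dS_N unchanged
        rng = np.random.default_rng(7)
        curve = 100.0 + 50.0 * rng.random(32)
        s0, aif_max = 100.0, 2.5
        base = normalize_curve(curve, s0, aif_max)
        scaled = normalize_curve(scale * curve, scale * s0, aif_max)
        np.testing.assert_allclose(scaled, base, rtol=1e-12, atol=1e-12)


class TestExtractAif:
    def test_recovers_phantom_onset(self, small_noise_free):
        aif = small_noise_free["aif"]
        assert aif.onset_index == small_noise_free["truth"].aif_onset_index

    def test_recovers_phantom_peak(self, small_noise_free):
        aif = small_noise_free["aif"]
        true_peak = small_noise_free["truth"].aif_curve.max()
        assert aif.peak_enhancement == pytest.approx(true_peak, rel=1e-6)

    def test_manual_override_passthrough(self, small_noise_free):
        aif = extract_aif(
            small_noise_free["series"],
            small_noise_free["artery"],
            onset_index=7,
            peak_enhancement=3.3,
        )
        assert aif.onset_index == 7
        assert aif.peak_enhancement == 3.3

    def test_flat_series_rejected(self):
        series = DceSeries(np.full((4, 4, 4, 40), 100.0), 3.0, (1.0, 1.0, 1.0))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True
        with pytest.raises(ValueError, match="aif-not-found"):
            extract_aif(series, mask)

    def test_empty_mask_rejected(self, small_noise_free):
        empty = np.zeros_like(small_noise_free["artery"])
        with pytest.raises(ValueError, match="aif-not-found"):
            extract_aif(small_noise_free["series"], empty)


class TestWindow:
    def test_sixty_frames_onset_ten(self):
        series = np.arange(60.0)
        win = window_curve(series, 10)
        assert len(win) == 32
        np.testing.assert_array_equal(win, np.arange(10.0, 42.0))

    def test_overrun_rejected(self):
        with pytest.raises(ValueError, match="window-overrun"):
            window_curve(np.arange(60.0), 40)

    def test_onset_alignment_equivariance(self):
        # shifting the series and the onset by k yields an identical window
        rng = np.random.default_rng(3)
        series = rng.random(80)
        k = 5
        shifted = np.r_[np.zeros(k), series]
        np.testing.assert_array_equal(
            window_curve(series, 12), window_curve(shifted, 12 + k)
        )


class TestResample:
    def test_identity_resample(self):
        curve = np.sin(np.linspace(0, 3, 40))
        out = resample_curve(curve, 3.0, 3.0)
        np.testing.assert_allclose(out, curve, atol=1e-12)

    def test_linear_ramp_exact(self):
        curve = np.arange(32.0) * 7.7  # value == time
        out = resample_curve(curve, 7.7, 4.1)
        t_out = np.arange(len(out)) * 4.1
        np.testing.assert_allclose(out, t_out, atol=1e-9)

    def test_output_length_arithmetic(self):
        # 32 frames at 7.7 s span 238.7 s -> floor(238.7/4.1)+1 = 59 samples
        out = resample_curve(np.zeros(32), 7.7, 4.1)
        assert len(out) == 59

    def test_dt_out_beyond_span_rejected(self):
        with pytest.raises(ValueError):
            resample_curve(np.zeros(8), 1.0, 100.0)


class TestWindowsFromSeries:
    def test_shapes_and_indices(self, small_noise_free):
        win = windows_from_series(
            small_noise_free["series"], small_noise_free["tumor"], small_noise_free["aif"]
        )
        assert win.values.shape == (int(small_noise_free["tumor"].sum()), 32)
        assert win.voxel_indices.shape[1] == 3
        assert win.excluded == []

    def test_aif_self_normalization(self, small_noise_free):
        # the artery's own normalized peak is 1 by construction
        win = windows_from_series(
            small_noise_free["series"], small_noise_free["artery"], small_noise_free["aif"]
        )
        assert win.values.max() == pytest.approx(1.0, abs=1e-9)
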