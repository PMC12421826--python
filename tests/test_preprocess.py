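"""Flat-field correction, frame averaging, and image conditioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecitools import (
    CapacitanceSeries,
    ChannelOffsetEstimate,
    DielectricParams,
    Phantom,
    SensorGeometry,
    average_frames,
    draw_channel_offsets,
    estimate_channel_offsets,
    flat_field_correct,
    forward_capacitance,
    suppress_periodic_pattern,
    upsample_presentation,
    window_average,
)


def _blank_frame(geometry, offsets=None, noise_sd=0.0, seed=0):
    ph = Phantom(np.zeros(geometry.shape), np.zeros(geometry.shape, int))
    params = DielectricParams(noise_sd_fF=noise_sd, channel_offsets_fF=offsets)
    return forward_capacitance(ph, params, geometry, seed=seed)


class TestChannelOffsets:
    def test_noiseless_recovery_is_exact(self, small_geometry):
        offs = np.array([3.0, -1.0, 0.5, 2.0, -4.0, 1.5, -0.5, -1.5])
        frame = _blank_frame(small_geometry, offsets=offs)
        est = estimate_channel_offsets(frame)
        np.testing.assert_allclose(est.offsets_fF, offs - offs.mean(), atol=1e-12)

    def test_constant_frame_gives_zero_offsets(self, small_geometry):
        est = estimate_channel_offsets(_blank_frame(small_geometry))
        np.testing.assert_array_equal(est.offsets_fF, 0.0)

    def test_estimates_sum_to_zero(self):
        est = ChannelOffsetEstimate(np.array([1.0, 2.0, 7.0]))
        assert abs(est.offsets_fF.sum()) < 1e-9

    def test_recovery_under_noise_matches_median_standard_error(self, full_geometry):
        # oracle: SE of the median of n iid normals = 1.2533*sigma/sqrt(n),
        # here n = 64*256 pixels per channel; Monte Carlo over 100 seeds
        se = 1.2533 / np.sqrt(64 * 256)
        errors = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            offs = draw_channel_offsets(rng, 8)
            frame = _blank_frame(full_geometry, offsets=offs, noise_sd=1.0, seed=2000 + s)
            est = estimate_channel_offsets(frame)
            errors.append(np.abs(est.offsets_fF - (offs - offs.mean())))
        errors = np.concatenate(errors)
        assert np.sqrt(np.mean(errors**2)) < 1.2 * se
        assert np.mean(errors < 3 * se) >= 0.99

    def test_masked_estimation_ignores_biomass(self, small_geometry):
        from ecitools import make_colony_phantom

        # compact colony leaving bare background in every channel block
        phantom = make_colony_phantom(
            small_geometry, n_blobs=2, smoothness_px=6, seed=12
        )
        assert all(
            ((phantom.thickness_um == 0) & (small_geometry.channel_of_pixel == k)).any()
            for k in range(8)
        )
        offs = np.array([5.0, -3.0, 1.0, 0.0, 2.0, -2.0, 4.0, -7.0])
        params = DielectricParams(noise_sd_fF=0.0, channel_offsets_fF=offs)
        frame = forward_capacitance(phantom, params, small_geometry)
        est = estimate_channel_offsets(frame, phantom.thickness_um == 0)
        np.testing.assert_allclose(est.offsets_fF, offs - offs.mean(), atol=1e-12)

    def test_channel_without_masked_pixels_rejected(self, small_geometry):
        frame = _blank_frame(small_geometry)
        mask = np.zeros(small_geometry.shape, bool)
        mask[:, :16] = True  # only channel 0 covered
        with pytest.raises(ValueError, match="channel"):
            estimate_channel_offsets(frame, mask)


class TestFlatFieldCorrect:
    def test_zero_offsets_identity(self, small_geometry):
        frame = _blank_frame(small_geometry, noise_sd=1.0, seed=1)
        out = flat_field_correct(frame, ChannelOffsetEstimate(np.zeros(8)))
        np.testing.assert_array_equal(out.values, frame.values)

    def test_estimate_then_correct_removes_channel_structure(self, small_geometry):
        offs = np.array([3.0, -1.0, 0.5, 2.0, -4.0, 1.5, -0.5, -1.5])
        frame = _blank_frame(small_geometry, offsets=offs)
        corrected = flat_field_correct(frame, estimate_channel_offsets(frame))
        chan = small_geometry.channel_of_pixel
        medians = [np.median(corrected.values[chan == k]) for k in range(8)]
        assert np.ptp(medians) < 1e-9

    def test_correction_is_idempotent(self, small_geometry):
        offs = np.array([3.0, -1.0, 0.5, 2.0, -4.0, 1.5, -0.5, -1.5])
        frame = _blank_frame(small_geometry, offsets=offs)
        corrected = flat_field_correct(frame, estimate_channel_offsets(frame))
        re_est = estimate_channel_offsets(corrected)
        assert np.abs(re_est.offsets_fF).max() < 1e-9

    def test_global_mean_preserved(self, small_geometry):
        frame = _blank_frame(
            small_geometry,
            offsets=np.array([3.0, -1.0, 0.5, 2.0, -4.0, 1.5, -0.5, -1.5]),
            noise_sd=1.0,
            seed=3,
        )
        corrected = flat_field_correct(frame, estimate_channel_offsets(frame))
        assert abs(corrected.values.mean() - frame.values.mean()) < 1e-9


class TestFrameAveraging:
    def _series(self, geometry, values, period=20.0):
        return CapacitanceSeries(
            values, np.arange(values.shape[0]) * period, geometry
        )

    def test_identical_frames_average_to_themselves(self, small_geometry):
        frame = np.full(small_geometry.shape, 7.0)
        series = self._series(small_geometry, np.stack([frame] * 5))
        np.testing.assert_array_equal(average_frames(series, 5).values, frame)

    def test_n_equals_one_returns_first_frame(self, small_geometry):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 1, size=(3, *small_geometry.shape))
        series = self._series(small_geometry, vals)
        out = average_frames(series, 1)
        np.testing.assert_array_equal(out.values, vals[0])
        assert out.timestamp_s == 0.0

    def test_hundred_frame_average_suppresses_noise_tenfold(self):
        # sampling-theory oracle: residual SD ~ sigma/sqrt(100) on >=10^4 px
        geom = SensorGeometry(n_rows=64, n_cols=256)
        rng = np.random.default_rng(7)
        vals = rng.normal(100.0, 1.0, size=(100, 64, 256))
        series = self._series(geom, vals)
        residual_sd = (average_frames(series, 100).values - 100.0).std()
        assert 0.08 <= residual_sd <= 0.12

    def test_window_average_counts_and_mean_preservation(self, small_geometry):
        rng = np.random.default_rng(2)
        vals = rng.normal(100, 1, size=(13, *small_geometry.shape))
        times = np.arange(13) * 600.0  # 10-min cadence over ~2 h
        series = CapacitanceSeries(vals, times, small_geometry)
        out = window_average(series, 1.0)
        assert len(out) == 3  # two full 6-frame windows + the t=120min frame
        np.testing.assert_allclose(out.values[0], vals[:6].mean(axis=0))
        np.testing.assert_allclose(out.values[1], vals[6:12].mean(axis=0))
        assert np.all(np.diff(out.times_s) > 0)

    def test_window_larger_than_span_gives_global_mean(self, small_geometry):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, size=(5, *small_geometry.shape))
        series = self._series(small_geometry, vals)
        out = window_average(series, 10.0)
        assert len(out) == 1
        np.testing.assert_allclose(out.values[0], vals.mean(axis=0))

    def test_empty_windows_skipped(self, small_geometry):
        vals = np.zeros((3, *small_geometry.shape))
        series = CapacitanceSeries(vals, [0.0, 600.0, 4 * 3600.0], small_geometry)
        out = window_average(series, 1.0)
        assert len(out) == 2

    @settings(max_examples=20, deadline=None)
    @given(window_h=st.floats(0.2, 5.0))
    def test_window_average_preserves_global_mean(self, window_h):
        geom = SensorGeometry(n_rows=8, n_cols=16)
        rng = np.random.default_rng(11)
        vals = rng.normal(100, 5, size=(12, 8, 16))
        series = CapacitanceSeries(vals, np.arange(12) * 600.0, geom)
        out = window_average(series, window_h)
        # each window's frame is the mean of its members; the weighted mean
        # over windows equals the global mean
        weights = np.array(
            [
                np.sum(
                    np.floor((series.times_s - series.times_s[0]) / (window_h * 3600))
                    == k
                )
                for k in np.unique(
                    np.floor((series.times_s - series.times_s[0]) / (window_h * 3600))
                )
            ]
        )
        global_mean = np.average(out.values.mean(axis=(1, 2)), weights=weights)
        assert abs(global_mean - vals.mean()) < 1e-9


class TestPeriodicSuppression:
    def test_grid_sinusoid_removed(self):
        img = 50.0 + 3.0 * np.sin(2 * np.pi * np.arange(128) / 8.0)[None, :] * np.ones(
            (128, 1)
        )
        out = suppress_periodic_pattern(img, grid_period_px=8.0, notch_width=0.02)
        assert np.abs(out - 50.0).max() < 0.01 * 3.0

    def test_clean_image_untouched(self):
        # all energy at low frequencies, far from the grid harmonics
        x = np.arange(64)
        img = (
            5.0
            + np.sin(2 * np.pi * x / 64.0)[None, :]
            + np.cos(2 * np.pi * 2 * x / 64.0)[:, None]
        )
        out = suppress_periodic_pattern(img, grid_period_px=8.0, notch_width=0.002)
        np.testing.assert_allclose(out, img, rtol=1e-6, atol=1e-6)

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100, 5, size=(64, 96))
        out = suppress_periodic_pattern(img, 8.0, 0.02)
        assert abs(out.mean() - img.mean()) < 1e-9

    def test_linear_and_idempotent(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 64, 64))
        f = lambda im: suppress_periodic_pattern(im, 8.0, 0.02)
        np.testing.assert_allclose(f(a + 2 * b), f(a) + 2 * f(b), atol=1e-10)
        np.testing.assert_allclose(f(f(a)), f(a), atol=1e-10)


class TestUpsample:
    def test_factor_16_quadruples_each_axis(self):
        out = upsample_presentation(np.zeros((100, 100)), 16)
        assert out.shape == (400, 400)

    def test_constant_image_stays_constant(self):
        out = upsample_presentation(np.full((10, 20), 3.5), 4)
        np.testing.assert_allclose(out, 3.5)

    def test_factor_one_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(upsample_presentation(img, 1), img)

    def test_non_square_factor_rejected(self):
        with pytest.raises(ValueError, match="square"):
            upsample_presentation(np.zeros((4, 4)), 8)
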