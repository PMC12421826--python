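"""Species segmentation, pellicle segmentation, and region tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecitools import (
    CapacitanceFrame,
    CapacitanceSeries,
    DielectricParams,
    PellicleScenario,
    RegionLabels,
    SensorGeometry,
    SpeciesTexture,
    fit_slope,
    forward_capacitance,
    histogram_overlap,
    make_two_species_phantom,
    region_histograms,
    segment_pellicle_frame,
    segment_species,
    simulate_pellicle_timelapse,
    track_regions,
    two_species_dielectric,
)

NOISE_SD = 1.0


def _two_species_frame(geometry, seed, delta_a=40.0, delta_b=47.0):
    a = SpeciesTexture(delta_c_fF=delta_a)
    b = SpeciesTexture(delta_c_fF=delta_b)
    ph = make_two_species_phantom(geometry, a, b, boundary_seed=seed)
    params = two_species_dielectric(a, b, DielectricParams(noise_sd_fF=NOISE_SD))
    frame = forward_capacitance(ph, params, geometry, seed=100 + seed)
    return frame, ph


def _accuracy(labels, truth):
    assigned = labels.labels > 0
    return max(
        np.mean((labels.labels == truth)[assigned]),
        np.mean((labels.labels == (3 - truth))[assigned]),
    )


class TestSpeciesSegmentation:
    def test_accuracy_at_five_sigma_contrast_over_seeds(self, small_geometry):
        # deficit gap 7 fF > 5 * noise SD at saturated thickness
        accs = [
            _accuracy(
                segment_species(_two_species_frame(small_geometry, s)[0]),
                _two_species_frame(small_geometry, s)[1].species,
            )
            for s in range(20)
        ]
        assert min(accs) >= 0.95

    def test_uniform_frame_degenerate(self, small_geometry):
        frame = CapacitanceFrame(
            np.full(small_geometry.shape, 90.0), 0.0, small_geometry
        )
        labels = segment_species(frame)
        assert labels.degenerate
        assert len(labels.classes) == 1

    def test_pure_noise_frame_degenerate(self, small_geometry):
        rng = np.random.default_rng(0)
        frame = CapacitanceFrame(
            rng.normal(100, 1, small_geometry.shape), 0.0, small_geometry
        )
        assert segment_species(frame).degenerate

    def test_swapping_deficits_swaps_classes_not_boundary(self):
        geom = SensorGeometry(n_rows=128, n_cols=256)
        frame_ab, ph = _two_species_frame(geom, 3, 40.0, 50.0)
        frame_ba, _ = _two_species_frame(geom, 3, 50.0, 40.0)
        lab_ab = segment_species(frame_ab)
        lab_ba = segment_species(frame_ba)
        # boundary band (unassigned) is nearly unchanged
        b1, b2 = lab_ab.labels == 0, lab_ba.labels == 0
        iou = (b1 & b2).sum() / max((b1 | b2).sum(), 1)
        assert iou >= 0.9
        # class assignment flips: the low-capacitance class changes side
        both = (lab_ab.labels > 0) & (lab_ba.labels > 0)
        assert np.mean((lab_ab.labels == 3 - lab_ba.labels)[both]) > 0.95

    @settings(max_examples=15, deadline=None)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-50.0, 50.0))
    def test_affine_rescaling_invariance(self, a, b):
        geom = SensorGeometry(n_rows=32, n_cols=64)
        frame, _ = _two_species_frame(geom, 1)
        scaled = CapacitanceFrame(a * frame.values + b, 0.0, geom)
        np.testing.assert_array_equal(
            segment_species(frame).labels, segment_species(scaled).labels
        )

    def test_area_conservation(self, small_geometry):
        frame, _ = _two_species_frame(small_geometry, 5)
        labels = segment_species(frame)
        total = sum(labels.area(i) for i in range(3))
        assert total == small_geometry.n_pixels


class TestRegionHistograms:
    def test_identity_overlap_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 2, 5000)
        assert histogram_overlap(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        assert histogram_overlap(np.zeros(100), np.ones(100) * 10) == 0.0

    def test_identical_generator_regions_overlap_high(self):
        geom = SensorGeometry(n_rows=128, n_cols=256)
        a, b = SpeciesTexture(), SpeciesTexture()
        ph = make_two_species_phantom(geom, a, b, boundary_seed=2)
        params = two_species_dielectric(a, b, DielectricParams(noise_sd_fF=NOISE_SD))
        frame = forward_capacitance(ph, params, geom, seed=3)
        labels = RegionLabels(ph.species, ["a", "b"])
        hist = region_histograms(frame, labels)
        assert hist.overlap > 0.9

    def test_distinct_regions_overlap_low(self, small_geometry):
        frame, ph = _two_species_frame(small_geometry, 4)
        hist = region_histograms(frame, RegionLabels(ph.species, ["a", "b"]))
        assert hist.overlap < 0.3


@pytest.fixture(scope="module")
def scenario_run():
    geom = SensorGeometry(n_rows=64, n_cols=128)
    sc = PellicleScenario(
        lag_h=12, duration_h=72, frame_interval_min=60, growth_rate_per_h=0.01,
        seed=4,
    )
    series, truth = simulate_pellicle_timelapse(
        sc, DielectricParams(noise_sd_fF=NOISE_SD), geom
    )
    return sc, series, truth


class TestPellicleSegmentation:
    def test_accuracy_after_establishment(self, scenario_run):
        sc, series, truth = scenario_run
        prev = None
        for k in range(len(series)):
            lab = segment_pellicle_frame(series[k], prev_labels=prev)
            prev = lab if not lab.degenerate else None
            if series.times_h[k] >= sc.lag_h + 2:
                assert np.mean(lab.labels == truth[k]) >= 0.90

    def test_pre_lag_area_negligible(self, scenario_run):
        sc, series, _ = scenario_run
        for k in range(len(series)):
            if series.times_h[k] < sc.lag_h:
                lab = segment_pellicle_frame(series[k])
                frac = np.mean(lab.labels == 1)
                assert frac <= 0.02

    def test_global_drift_invariance(self, scenario_run):
        _, series, _ = scenario_run
        frame = series[40]
        shifted = CapacitanceFrame(
            frame.values + 17.3, frame.timestamp_s, frame.geometry
        )
        np.testing.assert_array_equal(
            segment_pellicle_frame(frame).labels,
            segment_pellicle_frame(shifted).labels,
        )

    def test_pellicle_class_adjacent_to_interface(self, scenario_run):
        _, series, _ = scenario_run
        lab = segment_pellicle_frame(series[-1])
        assert lab.classes[0] == "pellicle"
        assert np.mean(lab.labels[:, 0] == 1) > 0.9  # depth 0 is pellicle


class TestTracking:
    def test_single_pixel_region_variance_zero_flagged(self, small_geometry):
        vals = np.zeros((1, *small_geometry.shape))
        series = CapacitanceSeries(vals, [0.0], small_geometry)
        arr = np.full(small_geometry.shape, 2, dtype=np.int32)
        arr[0, 0] = 1
        ts = track_regions(series, [RegionLabels(arr, ["pellicle", "media"])])
        row = ts.table[ts.table["region"] == "pellicle"].iloc[0]
        assert row["var_fF2"] == 0.0
        assert bool(row["n_flag"])

    def test_area_fractions_sum_to_one(self, small_geometry):
        frame, _ = _two_species_frame(small_geometry, 6)
        labels = segment_species(frame)
        series = CapacitanceSeries(frame.values[None], [0.0], small_geometry)
        ts = track_regions(series, [labels])
        assert ts.table["area_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_pellicle_trends_on_ground_truth_labels(self):
        # >=50 frames: variance slope > 0 and mean slope < 0 at p < 0.01,
        # media variance slope indistinguishable from 0
        geom = SensorGeometry(n_rows=64, n_cols=128)
        sc = PellicleScenario(
            lag_h=12, duration_h=72, frame_interval_min=60, growth_rate_per_h=0.01,
            seed=4,
        )
        series, truth = simulate_pellicle_timelapse(
            sc, DielectricParams(noise_sd_fF=NOISE_SD), geom
        )
        labels = [
            RegionLabels(np.where(truth[k] == 1, 1, 2), ["pellicle", "media"])
            for k in range(len(series))
        ]
        ts = track_regions(series, labels)
        var_slope, var_p, _ = fit_slope(ts, "pellicle", "var_fF2")
        mean_slope, mean_p, _ = fit_slope(ts, "pellicle", "mean_fF")
        _, _, media_t = fit_slope(ts, "media", "var_fF2")
        assert var_slope > 0 and var_p < 0.01
        assert mean_slope < 0 and mean_p < 0.01
        assert abs(media_t) < 2

    def test_depth_profile_shape_and_contrast(self):
        geom = SensorGeometry(n_rows=64, n_cols=128)
        sc = PellicleScenario(
            lag_h=6, duration_h=48, frame_interval_min=60, growth_rate_per_h=0.01,
            seed=4,
        )
        series, truth = simulate_pellicle_timelapse(
            sc, DielectricParams(noise_sd_fF=NOISE_SD), geom
        )
        labels = [
            RegionLabels(np.where(truth[k] == 1, 1, 2), ["pellicle", "media"])
            for k in range(len(series))
        ]
        ts = track_regions(series, labels)
        assert len(ts.depth_profile) == geom.n_cols
        colonized = truth[-1][0] == 1
        prof = ts.depth_profile["mean_fF"].to_numpy()
        assert prof[colonized].mean() < prof[~colonized].mean()

    def test_seed_averaged_pellicle_mean_non_increasing_hourly(self):
        # window-averaged pellicle means, averaged over 10 seeds, after onset
        from ecitools import window_average

        geom = SensorGeometry(n_rows=32, n_cols=64)
        means = []
        for seed in range(10):
            sc = PellicleScenario(
                lag_h=6, duration_h=48, frame_interval_min=10,
                growth_rate_per_h=0.015, seed=seed,
            )
            series, truth = simulate_pellicle_timelapse(
                sc, DielectricParams(noise_sd_fF=NOISE_SD), geom
            )
            windowed = window_average(series, 1.0)
            truth_w = truth[::6][: len(windowed)]
            per_frame = [
                series_vals[m == 1].mean()
                for series_vals, m in zip(windowed.values, truth_w)
                if (m == 1).any()
            ]
            means.append(per_frame)
        n = min(len(m) for m in means)
        avg = np.mean([m[:n] for m in means], axis=0)
        assert np.all(np.diff(avg) <= 1e-9)
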