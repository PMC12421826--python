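"""Run configuration and the end-to-end pipeline stages.

``run_pipeline`` chains the package's stages for four modes:

* ``simulate``  — generate every synthetic fixture (colony frames + matched
  confocal stack, two-species frame, pellicle time-lapse) with ground truth.
* ``calibrate`` — correct the colony frames, extract thickness from the
  confocal stack, and build the capacitance-vs-thickness calibration.
* ``species``   — segment the two-species frame and report histograms.
* ``pellicle``  — correct, window-average, segment, and track the pellicle
  time-lapse.

Every run writes a JSON report carrying the package version, the full
config (hashable and round-trippable), the seed, and the stage's summary
numbers, so any run can be re-executed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calibrate import (
    align_to_sensor_grid,
    build_calibration,
    detect_plateau,
    detect_surface_plane,
    fit_screening_depth,
    thickness_from_stack,
)
from .frames import CapacitanceSeries
from .geometry import Excitation, SensorGeometry
from .io import (
    read_capacitance_series,
    read_confocal_stack,
    read_labels,
    write_capacitance_series,
    write_confocal_stack,
    write_labels,
)
from .preprocess import (
    average_frames,
    estimate_channel_offsets,
    flat_field_correct,
    window_average,
)
from .segment import (
    RegionLabels,
    fit_slope,
    region_histograms,
    segment_pellicle_frame,
    segment_species,
    track_regions,
)
from .synth import (
    DielectricParams,
    PellicleScenario,
    Phantom,
    SpeciesTexture,
    draw_channel_offsets,
    forward_capacitance,
    make_colony_phantom,
    make_two_species_phantom,
    render_confocal_stack,
    simulate_pellicle_timelapse,
    two_species_dielectric,
)

__all__ = ["PhantomConfig", "ConfocalConfig", "SegmentationConfig", "RunConfig",
           "run_pipeline", "PIPELINE_MODES"]


@dataclass
class PhantomConfig:
    n_blobs: int = 6
    max_thickness_um: float = 33.2
    smoothness_px: float = 18.0
    n_frames: int = 10


@dataclass
class ConfocalConfig:
    z_step_um: float = 1.514
    n_z: int = 26
    lateral_oversample: int = 7
    surface_plane_index: int = 2
    noise_sd: float = 20.0


@dataclass
class SegmentationConfig:
    blur_sigma_px: float = 2.0
    min_hole_px: int = 25
    boundary_erosion_px: int = 3
    min_component_px: int = 16
    pellicle_blur_sigma_px: float = 1.0


@dataclass
class RunConfig:
    """All pipeline parameters with their package defaults.

    Serialises losslessly to/from JSON (``to_dict`` / ``from_dict``); the
    SHA-256 of the canonical JSON is the config hash written to reports.
    """

    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    dielectric: DielectricParams = field(default_factory=DielectricParams)
    offset_sd_fF: float = 5.0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    confocal: ConfocalConfig = field(default_factory=ConfocalConfig)
    species_a: SpeciesTexture = field(default_factory=SpeciesTexture)
    species_b: SpeciesTexture = field(
        default_factory=lambda: SpeciesTexture(delta_c_fF=47.0)
    )
    pellicle: PellicleScenario = field(default_factory=PellicleScenario)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    window_hours: float = 1.0
    plateau_epsilon_frac: float = 0.02
    seed: int = 0
    out_dir: str = "eci_out"

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        def as_dict(dc):
            return {
                f.name: conv(getattr(dc, f.name))
                for f in dataclasses.fields(dc)
            }

        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                d[f.name] = as_dict(v)
                if isinstance(v, SensorGeometry):
                    d[f.name]["excitation"] = as_dict(v.excitation)
            else:
                d[f.name] = conv(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo = dict(d.pop("geometry"))
        geo["excitation"] = Excitation(**geo.get("excitation", {}))
        if geo.get("channel_map") is not None:
            geo["channel_map"] = np.asarray(geo["channel_map"])
        die = dict(d.pop("dielectric"))
        if isinstance(die.get("delta_c_fF"), list):
            die["delta_c_fF"] = np.asarray(die["delta_c_fF"])
        if die.get("channel_offsets_fF") is not None:
            die["channel_offsets_fF"] = np.asarray(die["channel_offsets_fF"])
        return cls(
            geometry=SensorGeometry(**geo),
            dielectric=DielectricParams(**die),
            phantom=PhantomConfig(**d.pop("phantom")),
            confocal=ConfocalConfig(**d.pop("confocal")),
            species_a=SpeciesTexture(**d.pop("species_a")),
            species_b=SpeciesTexture(**d.pop("species_b")),
            pellicle=PellicleScenario(**d.pop("pellicle")),
            segmentation=SegmentationConfig(**d.pop("segmentation")),
            **d,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _report(config: RunConfig, mode: str, out: Path, summary: dict) -> dict:
    report = {
        "software": "ecitools",
        "version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "summary": summary,
    }
    (out / f"report_{mode}.json").write_text(json.dumps(report, indent=2))
    return report


def _mode_simulate(config: RunConfig, out: Path) -> dict:
    geom = config.geometry
    rng = np.random.default_rng(config.seed)
    offsets = draw_channel_offsets(rng, geom.n_channels, config.offset_sd_fF)
    params = replace(config.dielectric, channel_offsets_fF=offsets)

    # blank pre-load reference frame: medium only, same offsets (the offset
    # correction can use it instead of in-image statistics)
    blank = Phantom(np.zeros(geom.shape), np.zeros(geom.shape, dtype=int))
    ref = forward_capacitance(blank, params, geom, seed=int(rng.integers(2**31)))
    write_capacitance_series(
        CapacitanceSeries(ref.values[None], [0.0], geom),
        out / "reference_frame.tif",
        out / "reference_times.csv",
    )

    phantom = make_colony_phantom(
        geom,
        n_blobs=config.phantom.n_blobs,
        max_thickness_um=config.phantom.max_thickness_um,
        smoothness_px=config.phantom.smoothness_px,
        seed=config.seed,
    )
    frames = [
        forward_capacitance(
            phantom,
            params,
            geom,
            seed=int(rng.integers(2**31)),
            timestamp_s=k * geom.frame_period_s,
        )
        for k in range(config.phantom.n_frames)
    ]
    series = CapacitanceSeries.from_frames(frames)
    write_capacitance_series(series, out / "colony_series.tif", out / "colony_times.csv")
    write_labels(phantom.species, out / "colony_truth_labels.tif")
    tifffile.imwrite(
        str(out / "colony_truth_thickness.tif"),
        phantom.thickness_um.astype(np.float32),
    )

    stack = render_confocal_stack(
        phantom,
        geom,
        z_step_um=config.confocal.z_step_um,
        n_z=config.confocal.n_z,
        lateral_oversample=config.confocal.lateral_oversample,
        surface_plane_index=config.confocal.surface_plane_index,
        noise_sd=config.confocal.noise_sd,
        seed=int(rng.integers(2**31)),
    )
    write_confocal_stack(stack, out / "confocal_stack.tif", out / "confocal_voxels.json")

    sp_phantom = make_two_species_phantom(
        geom, config.species_a, config.species_b, boundary_seed=config.seed
    )
    sp_params = two_species_dielectric(
        config.species_a, config.species_b, replace(config.dielectric,
                                                    channel_offsets_fF=offsets)
    )
    sp_frame = forward_capacitance(
        sp_phantom, sp_params, geom, seed=int(rng.integers(2**31))
    )
    write_capacitance_series(
        CapacitanceSeries(sp_frame.values[None], [0.0], geom),
        out / "species_frame.tif",
        out / "species_times.csv",
    )
    write_labels(sp_phantom.species, out / "species_truth_labels.tif")

    pel_scenario = replace(config.pellicle, seed=config.seed)
    pel_series, pel_truth = simulate_pellicle_timelapse(pel_scenario, params, geom)
    write_capacitance_series(
        pel_series, out / "pellicle_series.tif", out / "pellicle_times.csv"
    )
    write_labels(pel_truth, out / "pellicle_truth_labels.tif")

    return {
        "channel_offsets_fF": offsets.tolist(),
        "colony_max_thickness_um": float(phantom.thickness_um.max()),
        "n_colony_frames": len(series),
        "n_pellicle_frames": len(pel_series),
        "files": sorted(p.name for p in out.iterdir()),
    }


def _offset_estimate(out: Path, geom, fallback_mask=None, frame=None):
    """Channel offsets from the blank reference frame, else from ``frame``."""
    ref_path = out / "reference_frame.tif"
    if ref_path.exists():
        ref = read_capacitance_series(ref_path, out / "reference_times.csv", geom)
        return estimate_channel_offsets(ref[0])
    if frame is None:
        raise FileNotFoundError(f"no reference frame at {ref_path}")
    try:
        return estimate_channel_offsets(frame, fallback_mask)
    except ValueError:
        return estimate_channel_offsets(frame)


def _mode_calibrate(config: RunConfig, out: Path) -> dict:
    geom = config.geometry
    series = read_capacitance_series(
        out / "colony_series.tif", out / "colony_times.csv", geom
    )
    averaged = average_frames(series, len(series))

    stack = read_confocal_stack(
        out / "confocal_stack.tif", out / "confocal_voxels.json"
    )
    surface = detect_surface_plane(stack, geom)
    hi_map = thickness_from_stack(stack, surface)
    tmap = align_to_sensor_grid(hi_map, geom)

    # estimate readout offsets on the blank reference frame if available,
    # falling back to confocal-confirmed biomass-free pixels
    est = _offset_estimate(out, geom, fallback_mask=tmap.thickness_um == 0,
                           frame=averaged)
    corrected = flat_field_correct(averaged, est)
    curve = build_calibration(corrected, tmap)
    curve.plateau_onset_um = detect_plateau(curve, config.plateau_epsilon_frac)
    c0, d, lam = fit_screening_depth(curve)
    curve.to_dataframe().to_csv(out / "calibration.csv", index=False)
    return {
        "surface_plane": surface,
        "n_levels": int(tmap.n_levels),
        "max_level_index": int(tmap.max_level_index),
        "correlation": curve.correlation,
        "plateau_onset_um": curve.plateau_onset_um,
        "fit_c_medium_fF": c0,
        "fit_delta_c_fF": d,
        "fit_screening_depth_um": lam,
    }


def _mode_species(config: RunConfig, out: Path) -> dict:
    geom = config.geometry
    series = read_capacitance_series(
        out / "species_frame.tif", out / "species_times.csv", geom
    )
    frame = series[0]
    corrected = flat_field_correct(frame, _offset_estimate(out, geom, frame=frame))
    seg = config.segmentation
    labels = segment_species(
        corrected,
        blur_sigma_px=seg.blur_sigma_px,
        min_hole_px=seg.min_hole_px,
        boundary_erosion_px=seg.boundary_erosion_px,
    )
    hist = region_histograms(corrected, labels)
    write_labels(labels.labels, out / "species_labels.tif")
    df = pd.DataFrame({"bin_left_fF": hist.bin_edges[:-1],
                       "bin_right_fF": hist.bin_edges[1:]})
    for name, counts in hist.counts.items():
        df[name] = counts
    df.to_csv(out / "species_histograms.csv", index=False)
    summary = {
        "degenerate": labels.degenerate,
        "overlap_coefficient": hist.overlap,
        "areas_px": {name: labels.area(i + 1) for i, name in enumerate(labels.classes)},
        "unassigned_px": labels.area(0),
    }
    truth_path = out / "species_truth_labels.tif"
    if truth_path.exists() and not labels.degenerate:
        truth = read_labels(truth_path)
        assigned = labels.labels > 0
        acc = max(
            float(np.mean((labels.labels == truth)[assigned])),
            float(np.mean((labels.labels == (3 - truth))[assigned])),
        )
        summary["pixel_accuracy_vs_truth"] = acc
    return summary


def _mode_pellicle(config: RunConfig, out: Path) -> dict:
    geom = config.geometry
    series = read_capacitance_series(
        out / "pellicle_series.tif", out / "pellicle_times.csv", geom
    )
    est = _offset_estimate(out, geom, frame=series[0])  # t=0 is biomass-free
    corrected = CapacitanceSeries(
        series.values
        - est.offsets_fF[geom.channel_of_pixel]
        + est.offsets_fF[geom.channel_of_pixel].mean(),
        series.times_s,
        geom,
    )
    windowed = window_average(corrected, config.window_hours)
    seg = config.segmentation
    labels_per_frame: list[RegionLabels] = []
    prev: RegionLabels | None = None
    for k in range(len(windowed)):
        lab = segment_pellicle_frame(
            windowed[k],
            prev_labels=prev,
            blur_sigma_px=seg.pellicle_blur_sigma_px,
            min_hole_px=seg.min_hole_px,
            min_component_px=seg.min_component_px,
        )
        labels_per_frame.append(lab)
        prev = lab if not lab.degenerate else None
    ts = track_regions(windowed, labels_per_frame)
    ts.table.to_csv(out / "pellicle_timeseries.csv", index=False)
    ts.depth_profile.to_csv(out / "pellicle_depth_profile.csv", index=False)
    write_labels(labels_per_frame[-1].labels, out / "pellicle_final_labels.tif")
    summary: dict = {"n_windows": len(windowed)}
    pel = ts.table[ts.table["region"] == "pellicle"]
    if (pel["area_px"] > 0).sum() >= 3:
        for col, key in (("var_fF2", "variance"), ("mean_fF", "mean")):
            slope, p, t = fit_slope(ts, "pellicle", col)
            summary[f"pellicle_{key}_slope_per_h"] = slope
            summary[f"pellicle_{key}_slope_p"] = p
        slope, p, t = fit_slope(ts, "media", "var_fF2")
        summary["media_variance_slope_per_h"] = slope
        summary["media_variance_slope_t"] = t
    summary["final_pellicle_area_fraction"] = float(
        pel["area_fraction"].iloc[-1] if len(pel) else 0.0
    )
    return summary


PIPELINE_MODES = {
    "simulate": _mode_simulate,
    "calibrate": _mode_calibrate,
    "species": _mode_species,
    "pellicle": _mode_pellicle,
}


def run_pipeline(config: RunConfig, mode: str) -> dict:
    """Execute one pipeline stage; returns the JSON report as a dict."""
    if mode not in PIPELINE_MODES:
        raise ValueError(
            f"unknown mode '{mode}'; valid modes: {sorted(PIPELINE_MODES)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = PIPELINE_MODES[mode](config, out)
    return _report(config, mode, out, summary)
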