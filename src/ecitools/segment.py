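"""Region segmentation and time-lapse statistics for capacitance images.

Two segmentation paths:

* **Species path** — a flat-field-corrected frame containing two colonies
  with distinct capacitance signatures is split by Gaussian blur + Otsu
  threshold, holes are closed, and an eroded band along the class boundary
  is left unassigned (boundary pixels mix both populations).

* **Pellicle path** — week-long time-lapses of a pellicle growing across
  the sensor, where media enrichment drifts both background and foreground
  levels.  Each frame is detrended by subtracting its own robust (median)
  baseline, then thresholded; once a pellicle is established, the threshold
  is seeded from the previous frame's class means, which keeps the
  segmentation stable as absolute levels drift.

Both paths report per-region areas, means, and unbiased variances; the
pellicle path additionally yields depth profiles (statistics over the short
axis at each depth below the liquid-air interface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, erosion, remove_small_holes, remove_small_objects

from .frames import CapacitanceFrame, CapacitanceSeries

__all__ = [
    "RegionLabels",
    "RegionTimeSeries",
    "RegionHistograms",
    "segment_species",
    "region_histograms",
    "histogram_overlap",
    "segment_pellicle_frame",
    "track_regions",
    "fit_slope",
]

#: depth runs along the long (column) axis; index 0 = liquid-air interface
DEPTH_AXIS = 1


@dataclass
class RegionLabels:
    """Per-pixel region classes; 0 = unassigned (boundary band).

    ``classes[i]`` names label ``i + 1``.  ``degenerate`` flags frames whose
    histogram showed no second mode, in which case a single class covers the
    whole frame.
    """

    labels: np.ndarray
    classes: list[str]
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    def area(self, label: int) -> int:
        return int(np.sum(self.labels == label))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _ashman_d(values: np.ndarray, split: float) -> float:
    """Bimodality of a sample split at a threshold (Ashman's D).

    A unimodal Gaussian split anywhere near its mode gives D ~ 3.7
    regardless of scale; genuinely two-class data gives much larger values.
    """
    lo = values[values <= split]
    hi = values[values > split]
    if lo.size < 2 or hi.size < 2:
        return 0.0
    s2 = 0.5 * (lo.var() + hi.var())
    if s2 <= 0:
        return np.inf
    return float(np.sqrt(2.0) * abs(hi.mean() - lo.mean()) / np.sqrt(s2))


#: Otsu splits below this bimodality are treated as single-class frames
_DEGENERATE_D = 5.0


def _otsu_split(blurred: np.ndarray) -> tuple[float, bool]:
    """Otsu threshold with a degeneracy guard; returns (threshold, ok)."""
    if np.ptp(blurred) == 0:
        return float(blurred.flat[0]), False
    thr = float(threshold_otsu(blurred))
    return thr, _ashman_d(blurred.ravel(), thr) >= _DEGENERATE_D


def segment_species(
    frame: CapacitanceFrame,
    blur_sigma_px: float = 2.0,
    min_hole_px: int = 25,
    boundary_erosion_px: int = 3,
) -> RegionLabels:
    """Split a flat-field-corrected frame into two species regions.

    Gaussian blur -> Otsu threshold -> hole closing -> per-class erosion,
    with the eroded boundary band left unassigned (label 0).  Label 1 is the
    lower-capacitance class, label 2 the higher.  If the blurred histogram
    is unimodal the result is a single class with ``degenerate=True``.

    The decision is purely rank-based on the blurred image, so the result
    is invariant to any affine rescaling ``a*C + b`` (a > 0) of the input.
    """
    values = frame.values
    blurred = gaussian_filter(values, blur_sigma_px) if blur_sigma_px > 0 else values
    thr, ok = _otsu_split(blurred)
    if not ok:
        return RegionLabels(
            np.ones(values.shape, dtype=np.int32), ["region"], degenerate=True
        )
    low = blurred <= thr
    low = closing(low, disk(2))
    # fill holes strictly smaller than min_hole_px, in both classes
    low = remove_small_holes(low, max_size=min_hole_px - 1)
    low = ~remove_small_holes(~low, max_size=min_hole_px - 1)
    labels = np.zeros(values.shape, dtype=np.int32)
    if boundary_erosion_px > 0:
        selem = disk(boundary_erosion_px)
        labels[erosion(low, selem)] = 1
        labels[erosion(~low, selem)] = 2
    else:
        labels[low] = 1
        labels[~low] = 2
    return RegionLabels(labels, ["species_low_c", "species_high_c"])


def histogram_overlap(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_bins: int = 64,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Overlap coefficient OVL = sum(min(p_a, p_b)) of two samples.

    1 means identical binned distributions, 0 disjoint supports.
    """
    values_a = np.asarray(values_a).ravel()
    values_b = np.asarray(values_b).ravel()
    if value_range is None:
        lo = min(values_a.min(), values_b.min())
        hi = max(values_a.max(), values_b.max())
        value_range = (float(lo), float(hi))
    pa, edges = np.histogram(values_a, bins=n_bins, range=value_range)
    pb, _ = np.histogram(values_b, bins=n_bins, range=value_range)
    pa = pa / max(pa.sum(), 1)
    pb = pb / max(pb.sum(), 1)
    return float(np.minimum(pa, pb).sum())


@dataclass
class RegionHistograms:
    """Per-region capacitance histograms on a shared bin grid."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    overlap: float


def region_histograms(
    frame: CapacitanceFrame, labels: RegionLabels, n_bins: int = 64
) -> RegionHistograms:
    """Histogram each labelled region over the frame's value range.

    ``overlap`` is the OVL between the first two classes (or 1.0 for a
    single-class result).
    """
    values = frame.values
    rng = (float(values.min()), float(values.max()))
    counts: dict[str, np.ndarray] = {}
    edges = np.histogram_bin_edges(values, bins=n_bins, range=rng)
    for i, name in enumerate(labels.classes, start=1):
        counts[name], _ = np.histogram(values[labels.mask(i)], bins=edges)
    if len(labels.classes) >= 2:
        ovl = histogram_overlap(
            values[labels.mask(1)], values[labels.mask(2)], n_bins, rng
        )
    else:
        ovl = 1.0
    return RegionHistograms(edges, counts, ovl)


def segment_pellicle_frame(
    frame: CapacitanceFrame,
    prev_labels: RegionLabels | None = None,
    blur_sigma_px: float = 1.0,
    min_hole_px: int = 25,
    min_component_px: int = 16,
) -> RegionLabels:
    """Segment one pellicle time-lapse frame into {pellicle, media}.

    The frame is detrended by subtracting its own median (invariant to the
    global drift that media enrichment causes), lightly blurred, then
    thresholded: at the midpoint of the previous frame's class means when
    ``prev_labels`` provides both classes, else by guarded Otsu.  Binary
    closing fills small holes and despeckling removes components below
    ``min_component_px``.  The pellicle is the lower-capacitance class,
    which sits adjacent to depth 0 (the liquid-air interface).
    """
    detrended = frame.values - np.median(frame.values)
    blurred = (
        gaussian_filter(detrended, blur_sigma_px) if blur_sigma_px > 0 else detrended
    )
    thr: float | None = None
    if prev_labels is not None and not prev_labels.degenerate:
        m_pel = prev_labels.mask(1)
        m_med = prev_labels.mask(2)
        if m_pel.any() and m_med.any():
            thr = 0.5 * (blurred[m_pel].mean() + blurred[m_med].mean())
    if thr is None:
        thr, ok = _otsu_split(blurred)
        if not ok:
            return RegionLabels(
                np.full(frame.values.shape, 2, dtype=np.int32),
                ["pellicle", "media"],
                degenerate=True,
            )
    pellicle = blurred <= thr
    pellicle = closing(pellicle, disk(2))
    pellicle = remove_small_holes(pellicle, max_size=min_hole_px - 1)
    pellicle = remove_small_objects(pellicle, max_size=min_component_px - 1)
    labels = np.where(pellicle, 1, 2).astype(np.int32)
    return RegionLabels(labels, ["pellicle", "media"])


@dataclass
class RegionTimeSeries:
    """Per-frame region statistics plus a final-frame depth profile.

    ``table`` columns: time_h, region, area_px, area_fraction, mean_fF,
    var_fF2, n_flag (True where the variance is reported as 0 because the
    region held fewer than 2 pixels).  ``depth_profile`` columns:
    depth_index, mean_fF, sd_fF, var_fF2 — statistics over the short axis of
    the final frame at each depth below the interface.
    """

    table: pd.DataFrame
    depth_profile: pd.DataFrame


def track_regions(
    series: CapacitanceSeries, labels_per_frame: list[RegionLabels] | np.ndarray
) -> RegionTimeSeries:
    """Area / mean / unbiased-variance time series for labelled regions.

    Accepts :class:`RegionLabels` per frame or a raw integer label stack
    (ground truth).  Unassigned pixels (label 0) are tracked under the
    region name ``"unassigned"`` so area fractions sum to 1 per frame.
    """
    n_frames = len(series)
    if len(labels_per_frame) != n_frames:
        raise ValueError("one label map per frame required")
    rows = []
    n_px = series.geometry.n_pixels
    for k in range(n_frames):
        lab = labels_per_frame[k]
        if isinstance(lab, RegionLabels):
            arr, names = lab.labels, lab.classes
        else:
            arr = np.asarray(lab)
            names = [f"region_{i}" for i in range(1, int(arr.max(initial=1)) + 1)]
        t_h = float(series.times_s[k]) / 3600.0
        frame_vals = series.values[k]
        regions = [(0, "unassigned")] if (arr == 0).any() else []
        regions += list(enumerate(names, start=1))
        for label_value, name in regions:
            sel = frame_vals[arr == label_value]
            n = sel.size
            rows.append(
                {
                    "time_h": t_h,
                    "region": name,
                    "area_px": n,
                    "area_fraction": n / n_px,
                    "mean_fF": float(sel.mean()) if n else np.nan,
                    "var_fF2": float(sel.var(ddof=1)) if n > 1 else 0.0,
                    "n_flag": n < 2,
                }
            )
    table = pd.DataFrame(rows)
    # area conservation check (regions + unassigned partition the grid)
    sums = table.groupby("time_h")["area_px"].sum()
    if not np.all(sums.to_numpy() == n_px):
        raise AssertionError("region areas do not partition the grid")

    final = series.values[-1]
    profile = pd.DataFrame(
        {
            "depth_index": np.arange(final.shape[DEPTH_AXIS]),
            "mean_fF": final.mean(axis=0),
            "sd_fF": final.std(axis=0, ddof=1),
            "var_fF2": final.var(axis=0, ddof=1),
        }
    )
    return RegionTimeSeries(table, profile)


def fit_slope(
    timeseries: RegionTimeSeries, region: str, column: str
) -> tuple[float, float, float]:
    """Linear trend of a region statistic vs time.

    Returns ``(slope_per_h, p_value, t_stat)`` from ordinary least squares;
    frames where the region is empty are dropped.
    """
    tbl = timeseries.table
    sub = tbl[(tbl["region"] == region) & (tbl["area_px"] > 0)]
    if len(sub) < 3:
        raise ValueError(f"too few frames with region '{region}'")
    res = stats.linregress(sub["time_h"].to_numpy(), sub[column].to_numpy())
    t_stat = res.slope / res.stderr if res.stderr > 0 else np.inf
    return float(res.slope), float(res.pvalue), float(t_stat)
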