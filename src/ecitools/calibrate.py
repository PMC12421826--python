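"""Confocal-anchored thickness extraction and capacitance calibration.

Pipeline: locate the sensor surface inside a confocal z-stack via the
periodic electrode reflections, convert the segmented stack into a per-pixel
biomass thickness map (quantized to the confocal z-step), block-average it
down to the sensor grid, and tabulate capacitance statistics per thickness
level.  The calibration curve characterises the sensor's depth sensitivity,
including the ionic-screening plateau at large thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.filters import threshold_otsu

from .frames import CapacitanceFrame
from .geometry import SensorGeometry

__all__ = [
    "ConfocalStack",
    "ThicknessMap",
    "CalibrationCurve",
    "SurfaceNotFoundError",
    "detect_surface_plane",
    "thickness_from_stack",
    "align_to_sensor_grid",
    "build_calibration",
    "detect_plateau",
    "fit_screening_depth",
    "quantize_thickness",
]


class SurfaceNotFoundError(RuntimeError):
    """No z-slice shows the electrode-reflection signature."""


@dataclass
class ConfocalStack:
    """3D fluorescence stack, axis order ``(z, y, x)``.

    ``voxel_size_um`` is ``(x, y, z)`` in micrometres per voxel (defaults
    match a 25x confocal scan of the array: 1.428, 1.428, 1.514).
    ``surface_plane`` caches the detected sensor-surface z index.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.428, 1.428, 1.514)
    surface_plane: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ConfocalStack requires a (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")

    @property
    def z_step_um(self) -> float:
        return float(self.voxel_size_um[2])


@dataclass
class ThicknessMap:
    """Per-pixel biomass thickness in um, quantized to the confocal z-step."""

    thickness_um: np.ndarray
    z_step_um: float

    def __post_init__(self) -> None:
        self.thickness_um = np.asarray(self.thickness_um, dtype=np.float64)
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")

    @property
    def n_levels(self) -> int:
        """Count of distinct nonzero thickness levels present."""
        vals = np.unique(self.thickness_um)
        return int(np.sum(vals > 0))

    @property
    def max_level_index(self) -> int:
        return int(round(float(self.thickness_um.max()) / self.z_step_um))


def quantize_thickness(thickness_um, z_step_um: float):
    """Quantize thickness to the z-step lattice by rounding."""
    return np.round(np.asarray(thickness_um, dtype=np.float64) / z_step_um) * z_step_um


# ---------------------------------------------------------------------------
# surface detection
# ---------------------------------------------------------------------------


def _grid_energy(image: np.ndarray, period_px: float) -> float:
    """Spectral energy near the electrode-grid fundamental along both axes."""
    f = np.abs(np.fft.rfft2(image - image.mean()))
    fy = np.fft.fftfreq(image.shape[0])
    fx = np.fft.rfftfreq(image.shape[1])
    f0 = 1.0 / period_px
    tol = 0.15 * f0
    my = np.abs(np.abs(fy) - f0) < tol
    mx = np.abs(fx - f0) < tol
    near_dc_y = np.abs(fy) < tol
    near_dc_x = fx < tol
    # lattice points (f0, 0), (0, f0), (f0, f0)
    sel = (
        np.outer(my, near_dc_x) | np.outer(near_dc_y, mx) | np.outer(my, mx)
    )
    return float((f[sel] ** 2).sum())


def detect_surface_plane(
    stack: ConfocalStack,
    geometry: SensorGeometry | None = None,
    min_contrast: float = 2.0,
) -> int:
    """Locate the sensor-surface slice via electrode-reflection periodicity.

    Returns the z index maximising spectral energy at the electrode-grid
    spatial frequency; if no slice stands out (max < ``min_contrast`` x the
    median slice energy) the per-slice total intensity is tried as a
    fallback, and if that is also flat a :class:`SurfaceNotFoundError` is
    raised.
    """
    geometry = geometry or SensorGeometry()
    period_px = geometry.pitch_um / stack.voxel_size_um[0]
    scores = np.array([_grid_energy(sl, period_px) for sl in stack.voxels])
    med = np.median(scores)
    if scores.max() > 0 and scores.max() >= min_contrast * max(med, 1e-30):
        return int(np.argmax(scores))
    totals = np.array([float(sl.sum()) for sl in stack.voxels])
    med_t = np.median(totals)
    if totals.max() >= min_contrast * max(med_t, 1e-30) and totals.max() > 0:
        return int(np.argmax(totals))
    raise SurfaceNotFoundError(
        "no z-slice exceeds background energy by the required contrast"
    )


# ---------------------------------------------------------------------------
# thickness extraction
# ---------------------------------------------------------------------------


def _slice_mask(sl: np.ndarray, threshold: float | None) -> np.ndarray:
    """Above-threshold mask of one z-slice; empty for unimodal slices."""
    if threshold is not None:
        return sl > threshold
    sl = np.asarray(sl, dtype=np.float64)
    if sl.max() == sl.min():
        return np.zeros(sl.shape, dtype=bool)
    thr = threshold_otsu(sl)
    hi = sl > thr
    lo = ~hi
    if not hi.any() or not lo.any():
        return np.zeros(sl.shape, dtype=bool)
    # bimodality guard: Ashman's D between the two classes
    mu_d = sl[hi].mean() - sl[lo].mean()
    s2 = 0.5 * (sl[hi].var() + sl[lo].var())
    d = np.sqrt(2.0) * abs(mu_d) / np.sqrt(max(s2, 1e-30))
    if d < 5.0:
        return np.zeros(sl.shape, dtype=bool)
    return hi


def thickness_from_stack(
    stack: ConfocalStack,
    surface_z: int | None = None,
    intensity_threshold: float | None = None,
) -> ThicknessMap:
    """Biomass thickness at confocal resolution from a segmented z-stack.

    Thickness at each lateral position is ``z_step`` times the length of the
    contiguous above-threshold voxel run starting at ``surface_z + 1`` (a
    run-length definition, robust to detached debris higher in the scan).
    The threshold defaults to per-slice Otsu with a bimodality guard, so
    biomass-free slices contribute nothing; pass ``intensity_threshold`` to
    use one fixed value instead.
    """
    if surface_z is None:
        surface_z = (
            stack.surface_plane
            if stack.surface_plane is not None
            else detect_surface_plane(stack)
        )
    nz, ny, nx = stack.voxels.shape
    if not (0 <= surface_z < nz):
        raise ValueError("surface_z outside the stack")
    run = np.zeros((ny, nx), dtype=np.int32)
    alive = np.ones((ny, nx), dtype=bool)
    for k in range(surface_z + 1, nz):
        occ = _slice_mask(stack.voxels[k], intensity_threshold)
        alive &= occ
        if not alive.any():
            break
        run += alive
    return ThicknessMap(run * stack.z_step_um, stack.z_step_um)


def align_to_sensor_grid(
    hi_map: ThicknessMap, geometry: SensorGeometry | None = None
) -> ThicknessMap:
    """Block-average a confocal-resolution map down to the sensor grid.

    The lateral dimensions must be integer multiples of the grid (default
    factor 7); block means are re-quantized to the z-step lattice by
    rounding.  The pre-quantization global mean is conserved exactly.
    """
    geometry = geometry or SensorGeometry()
    ny, nx = hi_map.thickness_um.shape
    fy, ry = divmod(ny, geometry.n_rows)
    fx, rx = divmod(nx, geometry.n_cols)
    if ry or rx or fy != fx or fy < 1:
        raise ValueError(
            f"map shape {(ny, nx)} is not an integer multiple of the sensor "
            f"grid {geometry.shape}"
        )
    means = _block_mean(hi_map.thickness_um, fy)
    quant = quantize_thickness(means, hi_map.z_step_um)
    return ThicknessMap(quant, hi_map.z_step_um)


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = arr.shape
    return arr.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def infer_reduction_factor(
    hi_shape: tuple[int, int], geometry: SensorGeometry | None = None
) -> int:
    """Integer confocal-to-sensor downsampling factor implied by a stack."""
    geometry = geometry or SensorGeometry()
    fy, ry = divmod(hi_shape[0], geometry.n_rows)
    fx, rx = divmod(hi_shape[1], geometry.n_cols)
    if ry or rx or fy != fx:
        raise ValueError("lateral shape is not an integer multiple of the grid")
    return fy


# ---------------------------------------------------------------------------
# calibration curve
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Capacitance statistics per thickness level.

    One row per distinct thickness value present in the map (level 0
    included).  ``correlation`` is the Pearson correlation between thickness
    and capacitance over all pixels; if either variable is constant it is
    reported as 0 with ``correlation_defined = False``.
    """

    levels_um: np.ndarray
    n_pixels: np.ndarray
    mean_fF: np.ndarray
    sd_fF: np.ndarray
    correlation: float
    correlation_defined: bool = True
    plateau_onset_um: float | None = None
    z_step_um: float = field(default=1.514)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_index": np.round(self.levels_um / self.z_step_um).astype(int),
                "thickness_um": self.levels_um,
                "n_pixels": self.n_pixels,
                "mean_fF": self.mean_fF,
                "sd_fF": self.sd_fF,
            }
        )


def build_calibration(
    capacitance: CapacitanceFrame, thickness: ThicknessMap
) -> CalibrationCurve:
    """Pixel-wise capacitance-vs-thickness statistics on the sensor grid."""
    cap = capacitance.values
    thick = thickness.thickness_um
    if cap.shape != thick.shape:
        raise ValueError("capacitance and thickness maps must share the grid")
    levels = np.unique(thick)
    n = np.empty(levels.size, dtype=np.int64)
    mean = np.empty(levels.size)
    sd = np.empty(levels.size)
    for i, lv in enumerate(levels):
        sel = cap[thick == lv]
        n[i] = sel.size
        mean[i] = sel.mean()
        sd[i] = sel.std(ddof=1) if sel.size > 1 else 0.0
    if np.ptp(cap) == 0 or np.ptp(thick) == 0:
        corr, defined = 0.0, False
    else:
        corr = float(stats.pearsonr(thick.ravel(), cap.ravel()).statistic)
        defined = True
    return CalibrationCurve(
        levels_um=levels,
        n_pixels=n,
        mean_fF=mean,
        sd_fF=sd,
        correlation=corr,
        correlation_defined=defined,
        z_step_um=thickness.z_step_um,
    )


def detect_plateau(
    curve: CalibrationCurve, epsilon_frac: float = 0.02
) -> float | None:
    """Thickness at which the calibration curve flattens, or ``None``.

    The plateau onset is the smallest level L such that every consecutive
    level-mean difference at levels >= L is below ``epsilon_frac`` of the
    curve's full mean range.  A constant curve plateaus at its first level.
    """
    m = curve.mean_fF
    lv = curve.levels_um
    if m.size == 0:
        return None
    rng = float(m.max() - m.min())
    if rng == 0:
        return float(lv[0])
    if m.size == 1:
        return float(lv[0])
    diffs = np.abs(np.diff(m))
    small = diffs < epsilon_frac * rng
    # smallest i with small[i:] all true
    for i in range(m.size - 1):
        if small[i:].all():
            return float(lv[i])
    return None


def fit_screening_depth(
    curve: CalibrationCurve,
) -> tuple[float, float, float]:
    """Least-squares fit of ``c0 - d*(1 - exp(-t/lam))`` to the level means.

    Returns ``(c0, d, lam)``; the fit is over the level means weighted
    equally, which matches how the curve is plotted and read.
    """
    t = curve.levels_um
    m = curve.mean_fF
    if t.size < 4:
        raise ValueError("need at least 4 levels to fit the screening depth")
    c0_0 = float(m[t == t.min()][0])
    d_0 = max(float(m.max() - m.min()), 1e-6)
    lam_0 = max(float(t.max()) / 4.0, 1e-3)

    def model(tt, c0, d, lam):
        return c0 - d * (1.0 - np.exp(-tt / lam))

    popt, _ = optimize.curve_fit(
        model,
        t,
        m,
        p0=(c0_0, d_0, lam_0),
        bounds=([-np.inf, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
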