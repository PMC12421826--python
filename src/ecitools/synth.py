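"""Forward model of the capacitance sensor and synthetic fixture generators.

The physical picture: a biofilm sits directly on the electrode array in
conductive medium.  Biomass has a lower permittivity than the surrounding
medium, so colonized pixels read a *lower* capacitance.  Ionic screening
limits how deep the measurement sees: material further than a few
screening depths above an electrode no longer changes its reading, which
produces the observed thickness plateau.

The simplest model with these three properties (biomass deficit, negative
thickness correlation, saturation) is an exponential depth-screening law::

    C(x, y) = c_medium - delta_c[species] * (1 - exp(-t(x, y) / lambda))
              + offset[channel(x, y)] + noise

with ``t`` the local biomass thickness (um) and ``lambda`` the screening
depth.  With the default ``lambda = 5 um`` the signal is within 7% of its
saturated value for thickness >= 16 um, reproducing the plateau regime.

Everything here is seeded and bitwise-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .calibrate import ConfocalStack
from .frames import CapacitanceFrame, CapacitanceSeries
from .geometry import SensorGeometry

__all__ = [
    "DielectricParams",
    "Phantom",
    "SpeciesTexture",
    "PellicleScenario",
    "draw_channel_offsets",
    "forward_capacitance",
    "make_colony_phantom",
    "make_two_species_phantom",
    "two_species_dielectric",
    "simulate_pellicle_timelapse",
    "render_confocal_stack",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class DielectricParams:
    """Dielectric / sensor-artifact parameters of the forward model.

    ``delta_c`` is the full-thickness capacitance deficit in fF; a scalar
    applies to every species, a sequence gives species ``s`` (labels are
    1-based) the deficit ``delta_c[s - 1]``.  ``channel_offsets`` models the
    per-readout-channel additive offsets from amplifier process variation;
    ``None`` means no offsets.
    """

    c_medium_fF: float = 100.0
    delta_c_fF: float | np.ndarray = 40.0
    screening_depth_um: float = 5.0
    noise_sd_fF: float = 1.0
    channel_offsets_fF: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.delta_c_fF) <= 0):
            raise ValueError("delta_c_fF must be > 0 (biomass lowers capacitance)")
        if self.screening_depth_um <= 0:
            raise ValueError("screening_depth_um must be > 0")
        if self.noise_sd_fF < 0:
            raise ValueError("noise_sd_fF must be >= 0")

    def deficit_map(self, species: np.ndarray) -> np.ndarray:
        """Per-pixel full-thickness deficit given a species label map."""
        delta = np.asarray(self.delta_c_fF, dtype=np.float64)
        if delta.ndim == 0:
            return np.where(species > 0, float(delta), 0.0)
        out = np.zeros(species.shape, dtype=np.float64)
        labelled = species > 0
        idx = species[labelled] - 1
        if idx.size and idx.max() >= delta.size:
            raise ValueError("species label exceeds len(delta_c_fF)")
        out[labelled] = delta[idx]
        return out


def draw_channel_offsets(
    rng: np.random.Generator, n_channels: int, sd_fF: float = 5.0
) -> np.ndarray:
    """Draw one set of per-channel offsets (Normal(0, sd); one draw per run)."""
    return rng.normal(0.0, sd_fF, size=n_channels)


@dataclass
class Phantom:
    """Ground-truth sample description on the sensor grid.

    ``thickness_um`` >= 0 everywhere; ``species`` is an integer label map
    with 0 = bare sensor, and ``species > 0`` exactly where thickness > 0.
    """

    thickness_um: np.ndarray
    species: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thickness_um = np.asarray(self.thickness_um, dtype=np.float64)
        self.species = np.asarray(self.species, dtype=np.int32)
        if self.thickness_um.shape != self.species.shape:
            raise ValueError("thickness and species maps must share a shape")
        if np.any(self.thickness_um < 0):
            raise ValueError("thickness must be non-negative")
        if np.any((self.species > 0) != (self.thickness_um > 0)):
            raise ValueError("species > 0 must hold exactly where thickness > 0")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def forward_capacitance(
    phantom: Phantom,
    params: DielectricParams,
    geometry: SensorGeometry | None = None,
    seed: int | np.random.Generator | None = None,
    timestamp_s: float = 0.0,
) -> CapacitanceFrame:
    """Simulate one capacitance frame of a phantom.

    With ``noise_sd_fF = 0`` and no offsets the output is a deterministic,
    strictly decreasing function of thickness.
    """
    geometry = geometry or SensorGeometry(
        n_rows=phantom.thickness_um.shape[0], n_cols=phantom.thickness_um.shape[1]
    )
    if phantom.thickness_um.shape != geometry.shape:
        raise ValueError(
            f"phantom shape {phantom.thickness_um.shape} != sensor grid "
            f"{geometry.shape}"
        )
    deficit = params.deficit_map(phantom.species)
    t = phantom.thickness_um
    lam = params.screening_depth_um
    values = params.c_medium_fF - deficit * (1.0 - np.exp(-t / lam))
    if params.channel_offsets_fF is not None:
        offsets = np.asarray(params.channel_offsets_fF, dtype=np.float64)
        if offsets.shape != (geometry.n_channels,):
            raise ValueError("channel_offsets_fF length must equal n_channels")
        values = values + offsets[geometry.channel_of_pixel]
    if params.noise_sd_fF > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, params.noise_sd_fF, size=values.shape)
    return CapacitanceFrame(values, timestamp_s, geometry)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def make_colony_phantom(
    geometry: SensorGeometry | None = None,
    n_blobs: int = 6,
    max_thickness_um: float = 33.2,
    smoothness_px: float = 18.0,
    seed: int | None = 0,
) -> Phantom:
    """Smooth blob-shaped colony thickness field with bare background.

    Random Gaussian bumps are summed, small values are clipped to zero so a
    genuine zero-thickness background exists, and the field is rescaled so
    its maximum equals ``max_thickness_um``.  The default maximum matches
    the 0-33.2 um range observed for confocal-validated biofilm samples.
    """
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    if max_thickness_um <= 0:
        raise ValueError("max_thickness_um must be > 0")
    geometry = geometry or SensorGeometry()
    rng = np.random.default_rng(seed)
    rows, cols = geometry.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    fld = np.zeros((rows, cols))
    for _ in range(n_blobs):
        cy = rng.uniform(0.15 * rows, 0.85 * rows)
        cx = rng.uniform(0.15 * cols, 0.85 * cols)
        sy = rng.uniform(0.6, 1.6) * smoothness_px
        sx = rng.uniform(0.6, 1.6) * smoothness_px
        amp = rng.uniform(0.4, 1.0)
        fld += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2) / 2.0)
    fld[fld < 0.05 * fld.max()] = 0.0
    fld *= max_thickness_um / fld.max()
    species = (fld > 0).astype(np.int32)
    return Phantom(
        fld,
        species,
        meta={
            "kind": "colony",
            "n_blobs": n_blobs,
            "max_thickness_um": max_thickness_um,
            "smoothness_px": smoothness_px,
            "seed": seed,
        },
    )


@dataclass
class SpeciesTexture:
    """Per-species thickness texture and dielectric deficit.

    ``mean_thickness_um`` and ``thickness_sd_um`` describe a smooth,
    spatially correlated thickness field (correlation length
    ``correlation_px``); ``delta_c_fF`` is the species' full-thickness
    capacitance deficit.
    """

    delta_c_fF: float = 40.0
    mean_thickness_um: float = 25.0
    thickness_sd_um: float = 2.5
    correlation_px: float = 12.0


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], corr_px: float
) -> np.ndarray:
    """Zero-mean unit-SD Gaussian random field with the given correlation."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, corr_px, mode="reflect")
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_two_species_phantom(
    geometry: SensorGeometry | None = None,
    species_a: SpeciesTexture | None = None,
    species_b: SpeciesTexture | None = None,
    boundary_seed: int = 0,
) -> Phantom:
    """Two contiguous colonies (labels 1 and 2) split by one wavy boundary.

    The boundary is a smooth random curve through the middle of the long
    axis; every pixel carries biomass, so the label map partitions the grid.
    """
    geometry = geometry or SensorGeometry()
    species_a = species_a or SpeciesTexture()
    species_b = species_b or SpeciesTexture()
    rng = np.random.default_rng(boundary_seed)
    rows, cols = geometry.shape
    wiggle = gaussian_filter1d(rng.standard_normal(rows), rows / 16.0, mode="reflect")
    wiggle *= (0.1 * cols) / max(np.abs(wiggle).max(), 1e-12)
    boundary_col = cols / 2.0 + wiggle
    col_idx = np.arange(cols)[None, :]
    labels = np.where(col_idx < boundary_col[:, None], 1, 2).astype(np.int32)

    thickness = np.zeros((rows, cols))
    for lab, sp in ((1, species_a), (2, species_b)):
        fld = sp.mean_thickness_um + sp.thickness_sd_um * _smooth_noise(
            rng, (rows, cols), sp.correlation_px
        )
        np.clip(fld, 0.1, None, out=fld)
        thickness[labels == lab] = fld[labels == lab]
    return Phantom(
        thickness,
        labels,
        meta={
            "kind": "two_species",
            "boundary_seed": boundary_seed,
            "delta_c_fF": (species_a.delta_c_fF, species_b.delta_c_fF),
        },
    )


def two_species_dielectric(
    species_a: SpeciesTexture,
    species_b: SpeciesTexture,
    base: DielectricParams | None = None,
) -> DielectricParams:
    """DielectricParams whose per-species deficits come from the textures."""
    base = base or DielectricParams()
    return DielectricParams(
        c_medium_fF=base.c_medium_fF,
        delta_c_fF=np.array([species_a.delta_c_fF, species_b.delta_c_fF]),
        screening_depth_um=base.screening_depth_um,
        noise_sd_fF=base.noise_sd_fF,
        channel_offsets_fF=base.channel_offsets_fF,
    )


# ---------------------------------------------------------------------------
# pellicle time-lapse
# ---------------------------------------------------------------------------


@dataclass
class PellicleScenario:
    """Parameters of the synthetic pellicle (liquid-air biofilm) time-lapse.

    The sensor images the pellicle in cross-section: the long (column) axis
    is depth below the liquid-air interface, depth index 0 at the interface.
    After a lag phase the colonized band expands down-depth at
    ``growth_rate`` (area fraction per hour); the colonized region's mean
    capacitance falls at exactly ``densify_rate`` (biomass densification)
    and its internal SD grows at exactly ``hetero_rate`` (banded spatial
    heterogeneity, standardized over the colonized region each frame),
    while the media region stays stationary.  ``base_deficit_fF`` is the
    contrast a colonized pixel develops over ``ramp_h`` hours after the
    front passes it (0 = instantaneous, the default).
    """

    lag_h: float = 24.0
    growth_rate_per_h: float = 0.004
    densify_rate_fF_per_h: float = 0.05
    hetero_rate_fF_per_h: float = 0.02
    duration_h: float = 168.0
    frame_interval_min: float = 10.0
    base_deficit_fF: float = 8.0
    ramp_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lag_h",
            "growth_rate_per_h",
            "densify_rate_fF_per_h",
            "hetero_rate_fF_per_h",
            "duration_h",
            "frame_interval_min",
            "base_deficit_fF",
            "ramp_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval_min == 0:
            raise ValueError("frame_interval_min must be > 0")

    @property
    def n_frames(self) -> int:
        """Frame count including t = 0 and the final time point."""
        return int(np.floor(self.duration_h * 60.0 / self.frame_interval_min)) + 1


def simulate_pellicle_timelapse(
    scenario: PellicleScenario,
    params: DielectricParams | None = None,
    geometry: SensorGeometry | None = None,
) -> tuple[CapacitanceSeries, np.ndarray]:
    """Simulate a pellicle time-lapse; returns (series, ground-truth labels).

    Ground-truth labels are uint8 per frame: 1 = pellicle, 2 = media.
    Colonization starts at ``lag_h`` and proceeds from depth 0 (column 0);
    each colonized depth slice spans the full short axis, as the sensor sees
    the cross-section of a floating film.
    """
    scenario = scenario
    params = params or DielectricParams()
    geometry = geometry or SensorGeometry()
    rows, cols = geometry.shape
    rng = np.random.default_rng(scenario.seed)

    # fixed banded heterogeneity pattern along depth (unit SD, zero mean)
    pattern_1d = gaussian_filter1d(
        rng.standard_normal(cols), 8.0, mode="wrap"
    )
    pattern_1d -= pattern_1d.mean()
    pattern_1d /= max(pattern_1d.std(), 1e-12)

    offsets = (
        np.asarray(params.channel_offsets_fF, dtype=np.float64)[
            geometry.channel_of_pixel
        ]
        if params.channel_offsets_fF is not None
        else 0.0
    )

    n = scenario.n_frames
    times_s = np.arange(n) * scenario.frame_interval_min * 60.0
    g = scenario.growth_rate_per_h
    depth_idx = np.arange(cols)
    # colonization time of each depth slice (inf if never colonized)
    if g > 0:
        t_col = scenario.lag_h + (depth_idx + 1) / (g * cols)
    else:
        t_col = np.full(cols, np.inf)

    values = np.empty((n, rows, cols), dtype=np.float32)
    labels = np.empty((n, rows, cols), dtype=np.uint8)
    for k, ts in enumerate(times_s):
        t_h = ts / 3600.0
        frac = np.clip(g * max(0.0, t_h - scenario.lag_h), 0.0, 1.0)
        front = int(np.floor(frac * cols))
        colonized = depth_idx < front
        age_h = np.where(colonized, t_h - t_col, 0.0)
        age_h = np.clip(age_h, 0.0, None)
        ramp = (
            np.minimum(1.0, age_h / scenario.ramp_h)
            if scenario.ramp_h > 0
            else colonized.astype(float)
        )
        densify = scenario.densify_rate_fF_per_h * max(0.0, t_h - scenario.lag_h)
        hetero_amp = scenario.hetero_rate_fF_per_h * max(0.0, t_h - scenario.lag_h)
        deficit_1d = colonized * (scenario.base_deficit_fF * ramp + densify)
        # heterogeneity standardized over the current region, so the
        # noiseless within-pellicle SD equals hetero_rate * (t - lag) exactly
        hetero_1d = np.zeros(cols)
        if front >= 2 and hetero_amp > 0:
            pat = pattern_1d[:front]
            sd = pat.std()
            if sd > 0:
                hetero_1d[:front] = (pat - pat.mean()) / sd * hetero_amp
        frame = params.c_medium_fF - (deficit_1d + hetero_1d)[None, :]
        frame = frame + offsets
        if params.noise_sd_fF > 0:
            frame = frame + rng.normal(0.0, params.noise_sd_fF, size=(rows, cols))
        values[k] = frame
        labels[k] = np.where(colonized[None, :], 1, 2)
    series = CapacitanceSeries(values, times_s, geometry)
    return series, labels


# ---------------------------------------------------------------------------
# confocal rendering
# ---------------------------------------------------------------------------


def render_confocal_stack(
    phantom: Phantom,
    geometry: SensorGeometry | None = None,
    z_step_um: float = 1.514,
    n_z: int = 100,
    lateral_oversample: int = 7,
    surface_plane_index: int = 2,
    seed: int | None = 0,
    background: float = 100.0,
    biomass_intensity: float = 1000.0,
    reflection_amplitude: float = 1500.0,
    noise_sd: float = 20.0,
) -> ConfocalStack:
    """Render a matched fluorescence z-stack of a phantom.

    The stack has shape ``(n_z, n_rows*o, n_cols*o)`` with lateral
    oversampling ``o`` (default 7, i.e. voxel size pitch/7 ~= 1.43 um).  A
    voxel at height ``h`` above the sensor surface (measured at the voxel
    centre) is bright iff ``h <= thickness``, so the run-length thickness of
    a noiseless stack equals ``round(t / z_step) * z_step``.  The slice at
    ``surface_plane_index`` carries the periodic electrode-reflection
    pattern used to locate the sensor surface within the scan.
    """
    geometry = geometry or SensorGeometry(
        n_rows=phantom.thickness_um.shape[0], n_cols=phantom.thickness_um.shape[1]
    )
    if phantom.thickness_um.shape != geometry.shape:
        raise ValueError("phantom does not match the sensor grid")
    if lateral_oversample < 1:
        raise ValueError("lateral_oversample must be >= 1")
    if not (0 <= surface_plane_index < n_z):
        raise ValueError("surface_plane_index outside the stack")
    span_um = (n_z - 1 - surface_plane_index) * z_step_um
    t_max = float(phantom.thickness_um.max())
    if span_um < t_max:
        raise ValueError(
            f"scan covers {span_um:.1f} um above the surface but the sample "
            f"is {t_max:.1f} um thick"
        )

    o = lateral_oversample
    t_hi = np.repeat(np.repeat(phantom.thickness_um, o, axis=0), o, axis=1)
    ny, nx = t_hi.shape
    rng = np.random.default_rng(seed)
    stack = np.full((n_z, ny, nx), background, dtype=np.float32)

    for k in range(surface_plane_index + 1, n_z):
        h = (k - surface_plane_index - 0.5) * z_step_um  # voxel-centre height
        occupied = h <= t_hi
        if not occupied.any():
            break
        stack[k][occupied] = biomass_intensity

    # electrode reflections: bright grid at the electrode pitch (o px period)
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    grid = (0.5 + 0.5 * np.cos(2 * np.pi * yy / o)) * (
        0.5 + 0.5 * np.cos(2 * np.pi * xx / o)
    )
    stack[surface_plane_index] = background + reflection_amplitude * grid

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape).astype(np.float32)

    voxel_xy = geometry.pitch_um / o
    return ConfocalStack(
        voxels=stack,
        voxel_size_um=(voxel_xy, voxel_xy, z_step_um),
        surface_plane=surface_plane_index,
    )
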