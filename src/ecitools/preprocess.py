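"""Sensor-artifact correction and conditioning of raw capacitance frames.

Raw frames carry three instrument signatures that must be removed before
analysis: additive per-readout-channel offsets from amplifier process
variation (flat-field correction), uncorrelated per-pixel noise (frame
averaging), and the periodic imprint of the electrode grid itself
(frequency-domain notch filtering).  A bilinear upsampler is provided for
presentation of the low-resolution frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .frames import CapacitanceFrame, CapacitanceSeries

__all__ = [
    "ChannelOffsetEstimate",
    "estimate_channel_offsets",
    "flat_field_correct",
    "average_frames",
    "window_average",
    "suppress_periodic_pattern",
    "upsample_presentation",
]


@dataclass
class ChannelOffsetEstimate:
    """Per-channel additive offsets in fF, mean-zero by convention.

    The global signal level is not identifiable from a single frame (an
    offset common to all channels is indistinguishable from sample signal),
    so estimates are centred: ``sum(offsets) == 0``.
    """

    offsets_fF: np.ndarray
    method: str = "masked-channel-median"
    reference: str = "in-image statistics"

    def __post_init__(self) -> None:
        self.offsets_fF = np.asarray(self.offsets_fF, dtype=np.float64)
        self.offsets_fF = self.offsets_fF - self.offsets_fF.mean()


def estimate_channel_offsets(
    frame: CapacitanceFrame, background_mask: np.ndarray | None = None
) -> ChannelOffsetEstimate:
    """Estimate readout-channel offsets from a frame's own statistics.

    Per channel, the offset is the median of that channel's (optionally
    masked) pixels, centred so the estimates sum to zero.  Medians make the
    estimate robust when biomass occupies part of the field; passing a
    background (biomass-free) mask removes even that sensitivity.
    """
    geom = frame.geometry
    chan = geom.channel_of_pixel
    if background_mask is None:
        background_mask = np.ones(geom.shape, dtype=bool)
    else:
        background_mask = np.asarray(background_mask, dtype=bool)
        if background_mask.shape != geom.shape:
            raise ValueError("background_mask shape does not match the grid")
    medians = np.empty(geom.n_channels)
    for k in range(geom.n_channels):
        sel = frame.values[(chan == k) & background_mask]
        if sel.size == 0:
            raise ValueError(f"channel {k} has no pixels in the background mask")
        medians[k] = np.median(sel)
    return ChannelOffsetEstimate(medians - medians.mean())


def flat_field_correct(
    frame: CapacitanceFrame, offsets: ChannelOffsetEstimate
) -> CapacitanceFrame:
    """Subtract per-channel offsets; the frame's global mean is preserved."""
    geom = frame.geometry
    off = offsets.offsets_fF
    if off.shape != (geom.n_channels,):
        raise ValueError("offset vector length must equal n_channels")
    applied = off[geom.channel_of_pixel]
    corrected = frame.values - applied + applied.mean()
    return CapacitanceFrame(corrected, frame.timestamp_s, geom)


def average_frames(series: CapacitanceSeries, n: int) -> CapacitanceFrame:
    """Pixel-wise mean of the first ``n`` frames (noise SD shrinks ~1/sqrt(n))."""
    if not (1 <= n <= len(series)):
        raise ValueError(f"n must be in [1, {len(series)}]")
    vals = series.values[:n].mean(axis=0)
    ts = float(series.times_s[:n].mean())
    return CapacitanceFrame(vals, ts, series.geometry)


def window_average(series: CapacitanceSeries, window_h: float) -> CapacitanceSeries:
    """Average frames within consecutive time windows of ``window_h`` hours.

    Windows are half-open ``[t0 + k*w, t0 + (k+1)*w)`` anchored at the first
    timestamp; empty windows are skipped.  Each output frame's timestamp is
    the mean of its members', so timestamps stay strictly increasing.
    """
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    w = window_h * 3600.0
    t0 = series.times_s[0]
    idx = np.floor((series.times_s - t0) / w).astype(np.int64)
    frames, times = [], []
    for k in np.unique(idx):
        sel = idx == k
        frames.append(series.values[sel].mean(axis=0))
        times.append(series.times_s[sel].mean())
    return CapacitanceSeries(np.stack(frames), np.array(times), series.geometry)


def suppress_periodic_pattern(
    image: np.ndarray, grid_period_px: float, notch_width: float = 0.01
) -> np.ndarray:
    """Notch out the electrode-grid periodicity in the frequency domain.

    Spectral components within ``notch_width`` (cycles/px) of the grid
    lattice frequencies ``(m/p, n/p)`` — the fundamental and harmonics along
    both axes and their cross terms, DC excluded — are zeroed.  The filter
    is linear, idempotent, and leaves the image mean untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if grid_period_px <= 1:
        raise ValueError("grid_period_px must be > 1 px")
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    f0 = 1.0 / grid_period_px
    # distance to the nearest harmonic of f0 (0 counts as a harmonic)
    dy = np.abs(fy - f0 * np.round(fy / f0))
    dx = np.abs(fx - f0 * np.round(fx / f0))
    on_y = dy < notch_width
    on_x = dx < notch_width
    notch = on_y & on_x
    notch[0, 0] = False  # DC preserved
    spec = np.fft.fft2(image)
    spec[notch] = 0.0
    return np.real(np.fft.ifft2(spec))


def upsample_presentation(image: np.ndarray, area_factor: int) -> np.ndarray:
    """Anti-alias a frame for display by bilinear upsampling.

    ``area_factor`` counts total pixels and must be a perfect square; each
    axis grows by ``sqrt(area_factor)`` (the conventional "16x" upsample
    maps 100x100 to 400x400).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if area_factor < 1:
        raise ValueError("area_factor must be >= 1")
    side = np.sqrt(area_factor)
    if side != int(side):
        raise ValueError("area_factor must be a perfect square")
    side = int(side)
    if side == 1:
        return image.copy()
    out_shape = (image.shape[0] * side, image.shape[1] * side)
    return resize(
        image,
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
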