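"""Sensor geometry for the CMOS capacitance-imaging microelectrode array.

The instrument is a rectangular grid of square titanium-nitride electrodes
(default 256 x 512 at 10 um pitch, ~13.1 mm^2 field of view) read out through
a small number of multiplexed amplifier channels.  All image arrays in this
package are indexed ``(row, col)`` with shape ``(n_rows, n_cols)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Excitation", "SensorGeometry", "default_channel_map"]


@dataclass(frozen=True)
class Excitation:
    """AC excitation applied to each electrode (informational metadata)."""

    frequency_hz: float = 6.25e6
    amplitude_v_pkpk: float = 0.015


def default_channel_map(n_rows: int, n_cols: int, n_channels: int) -> np.ndarray:
    """Default pixel-to-readout-channel assignment: contiguous column blocks.

    Channel ``k`` owns columns ``[k*w, (k+1)*w)`` with ``w = n_cols //
    n_channels``.  The real device's interleaving is not public; the map is
    pluggable via :class:`SensorGeometry`.
    """
    if n_cols % n_channels != 0:
        raise ValueError(
            f"n_cols={n_cols} not divisible by n_channels={n_channels}"
        )
    width = n_cols // n_channels
    cols = np.arange(n_cols) // width
    return np.broadcast_to(cols, (n_rows, n_cols)).astype(np.int16)


@dataclass(frozen=True, eq=False)
class SensorGeometry:
    """Electrode-grid geometry and acquisition metadata.

    Parameters
    ----------
    n_rows, n_cols
        Pixel grid shape; images have shape ``(n_rows, n_cols)``.
    pitch_um
        Electrode pitch in micrometres (electrodes are ``pitch x pitch``
        squares, so pitch equals the lateral resolution).
    n_channels
        Number of multiplexed readout channels, each with its own amplifier
        and hence its own additive offset.
    channel_map
        ``(n_rows, n_cols)`` integer array mapping each pixel to its channel
        in ``[0, n_channels)``; ``None`` selects the default column-block map.
    frame_period_s
        Seconds to acquire one full frame.
    """

    n_rows: int = 256
    n_cols: int = 512
    pitch_um: float = 10.0
    n_channels: int = 8
    channel_map: np.ndarray | None = None
    frame_period_s: float = 20.0
    excitation: Excitation = field(default_factory=Excitation)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        cmap = self.channel_map
        if cmap is not None:
            cmap = np.asarray(cmap)
            if cmap.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"channel_map shape {cmap.shape} != grid "
                    f"{(self.n_rows, self.n_cols)}"
                )
            present = np.unique(cmap)
            if present.min() < 0 or present.max() >= self.n_channels:
                raise ValueError("channel_map values outside [0, n_channels)")
            if len(present) != self.n_channels:
                raise ValueError("every channel must own at least one pixel")
            object.__setattr__(self, "channel_map", cmap)

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def field_of_view_mm2(self) -> float:
        """Active area in mm^2 (pixel count x pitch^2)."""
        return self.n_pixels * (self.pitch_um * 1e-3) ** 2

    @property
    def channel_of_pixel(self) -> np.ndarray:
        """Per-pixel channel index, materialising the default map if needed."""
        if self.channel_map is not None:
            return self.channel_map
        return default_channel_map(self.n_rows, self.n_cols, self.n_channels)
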