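"""In-memory containers for capacitance images and image series.

Capacitance values are femtofarads (fF) throughout the package; timestamps
are seconds from the start of acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterator, Sequence

import numpy as np

from .geometry import SensorGeometry

__all__ = ["CapacitanceFrame", "CapacitanceSeries"]


def _validate_values(values: np.ndarray, geometry: SensorGeometry) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-2:] != geometry.shape:
        raise ValueError(
            f"frame shape {values.shape[-2:]} does not match sensor grid "
            f"{geometry.shape}"
        )
    if not np.all(np.isfinite(values)):
        bad = tuple(int(i) for i in np.argwhere(~np.isfinite(values))[0])
        raise ValueError(f"non-finite capacitance at index {bad}")
    return values


@dataclass
class CapacitanceFrame:
    """A single capacitance image in fF on the sensor grid."""

    values: np.ndarray
    timestamp_s: float = 0.0
    geometry: SensorGeometry = field(default_factory=SensorGeometry)

    def __post_init__(self) -> None:
        self.values = _validate_values(self.values, self.geometry)
        if self.values.ndim != 2:
            raise ValueError("CapacitanceFrame requires a 2D array")


@dataclass
class CapacitanceSeries:
    """A time-ordered stack of capacitance frames sharing one geometry.

    ``values`` has shape ``(n_frames, n_rows, n_cols)``; ``times_s`` is
    strictly increasing.
    """

    values: np.ndarray
    times_s: np.ndarray
    geometry: SensorGeometry = field(default_factory=SensorGeometry)

    def __post_init__(self) -> None:
        self.values = _validate_values(self.values, self.geometry)
        if self.values.ndim != 3:
            raise ValueError("CapacitanceSeries requires a 3D array")
        self.times_s = np.asarray(self.times_s, dtype=np.float64).ravel()
        if self.times_s.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} frames but "
                f"{self.times_s.shape[0]} timestamps"
            )
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.values.shape[0]

    def __iter__(self) -> Iterator[CapacitanceFrame]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> CapacitanceFrame:
        return CapacitanceFrame(self.values[i], float(self.times_s[i]), self.geometry)

    @property
    def times_h(self) -> np.ndarray:
        return self.times_s / 3600.0

    @classmethod
    def from_frames(cls, frames: Sequence[CapacitanceFrame]) -> "CapacitanceSeries":
        if not frames:
            raise ValueError("empty frame list")
        geometry = frames[0].geometry
        values = np.stack([f.values for f in frames])
        times = np.array([f.timestamp_s for f in frames])
        return cls(values, times, geometry)
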