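"""File formats: TIFF images/stacks, CSV sidecar tables, JSON metadata.

Conventions: capacitance is stored as 32-bit float TIFF in fF with a CSV
sidecar ``frame_index,time_s``; label maps as integer TIFF; confocal stacks
as 3D TIFF with voxel sizes in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibrate import ConfocalStack
from .frames import CapacitanceSeries
from .geometry import SensorGeometry

__all__ = [
    "write_capacitance_series",
    "read_capacitance_series",
    "write_labels",
    "read_labels",
    "write_confocal_stack",
    "read_confocal_stack",
]


def write_capacitance_series(
    series: CapacitanceSeries, tiff_path: str | Path, times_csv_path: str | Path
) -> None:
    """Write a series as multi-page float32 TIFF plus a timestamp CSV."""
    tifffile.imwrite(
        str(tiff_path), series.values.astype(np.float32), photometric="minisblack"
    )
    pd.DataFrame(
        {"frame_index": np.arange(len(series)), "time_s": series.times_s}
    ).to_csv(times_csv_path, index=False)


def read_capacitance_series(
    tiff_path: str | Path,
    times_csv_path: str | Path | None = None,
    geometry: SensorGeometry | None = None,
) -> CapacitanceSeries:
    """Read a capacitance series from TIFF (+ optional timestamp CSV).

    The TIFF page count must equal the CSV row count and times must be
    strictly increasing; a single-page TIFF without a CSV gets timestamp 0.
    Non-finite pixels are rejected with their location.
    """
    values = np.asarray(tifffile.imread(str(tiff_path)), dtype=np.float64)
    if values.ndim == 2:
        values = values[None]
    n = values.shape[0]
    if times_csv_path is None:
        if n != 1:
            raise ValueError(
                f"{n}-page TIFF requires a timestamp CSV (only single-frame "
                "files may omit it)"
            )
        times = np.zeros(1)
    else:
        tbl = pd.read_csv(times_csv_path)
        if len(tbl) != n:
            raise ValueError(
                f"TIFF has {n} pages but the CSV has {len(tbl)} rows"
            )
        times = tbl["time_s"].to_numpy(dtype=np.float64)
    geometry = geometry or SensorGeometry(
        n_rows=values.shape[1], n_cols=values.shape[2]
    )
    return CapacitanceSeries(values, times, geometry)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        str(path), np.asarray(labels, dtype=np.int32), photometric="minisblack"
    )


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.int32)


def write_confocal_stack(
    stack: ConfocalStack, tiff_path: str | Path, json_path: str | Path
) -> None:
    """Write a z-stack as 3D float32 TIFF + JSON sidecar with voxel sizes."""
    tifffile.imwrite(
        str(tiff_path), stack.voxels.astype(np.float32), photometric="minisblack"
    )
    meta = {
        "voxel_size_um": list(stack.voxel_size_um),
        "surface_plane": stack.surface_plane,
        "axis_order": "zyx",
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def read_confocal_stack(
    tiff_path: str | Path, json_path: str | Path
) -> ConfocalStack:
    meta = json.loads(Path(json_path).read_text())
    voxels = np.asarray(tifffile.imread(str(tiff_path)))
    return ConfocalStack(
        voxels=voxels,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        surface_plane=meta.get("surface_plane"),
    )
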