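"""Plain-text exporters: CSV time series, line-scan matrices, JSON
summaries and legacy-ASCII VTK image data for volume rendering."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import LabeledGrid
from .solver import FieldState, Trajectory


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Dense per-step series: averages, probes and whole-cell fluxes."""
    cols = {"time_ms": traj.times,
            "ca_global_uM": traj.global_ca,
            "ca_subsarc_uM": traj.subsarc_ca}
    for k, v in traj.probe_ca.items():
        cols[f"ca_{k}_uM"] = v
    for k, v in traj.fluxes.items():
        cols[f"j_{k}_uM_per_ms"] = v
    cols["ca_total_uM"] = traj.total_ca
    cols["applied_influx_uM"] = traj.applied_influx
    return pd.DataFrame(cols)


def write_series(traj: Trajectory, path: str | Path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def write_linescan(traj: Trajectory, path: str | Path) -> None:
    """Kymograph as CSV: rows = positions (um), columns = times (ms)."""
    df = pd.DataFrame(traj.linescan.T,
                      index=np.round(traj.probes.linescan_positions, 4),
                      columns=np.round(traj.times, 3))
    df.index.name = "position_um"
    df.to_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_vtk_labels(grid: LabeledGrid, path: str | Path) -> None:
    """Occupancy labels as legacy-ASCII VTK STRUCTURED_POINTS cell data."""
    _write_vtk(path, grid, grid.labels.astype(np.int32), "labels")


def write_vtk_ca(grid: LabeledGrid, state: FieldState,
                 path: str | Path) -> None:
    """Free-Ca field (uM) as VTK cell data; non-cytosol voxels carry -1."""
    vol = np.full(grid.labels.shape, -1.0)
    vol[tuple(grid.cyt_ijk.T)] = state.Ca
    _write_vtk(path, grid, vol, "ca_uM")


def _write_vtk(path, grid, volume, name):
    nx, ny, nz = volume.shape
    h = grid.voxel_size
    flat = volume.transpose(2, 1, 0).ravel()  # VTK is x-fastest
    if np.issubdtype(flat.dtype, np.integer):
        dtype, fmt = "int", "%d"
    else:
        dtype, fmt = "float", "%.6g"
    lines = [
        "# vtk DataFile Version 3.0",
        "ttflux microdomain",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {nx * ny * nz}",
        f"SCALARS {name} {dtype} 1",
        "LOOKUP_TABLE default",
    ]
    body = "\n".join(" ".join(fmt % v for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")
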