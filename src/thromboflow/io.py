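"""File output: CSV time series, legacy-VTK structured-grid snapshots,
flow-snapshot CSV (round-trippable), and JSON provenance.

All numeric formatting is locale-independent (dot decimal separator via
repr/printf formatting); CSV follows RFC-4180 with a header row and SI
units embedded in the column names.  File naming follows
``{label}_{stage}_{cycle:03d}_{step:05d}.{ext}``.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from thromboflow.geometry import AAAGeometry, StructuredGrid
from thromboflow.hemodynamics import FlowField
from thromboflow.kinetics import SPECIES, BatchTrajectory

__all__ = [
    "output_name",
    "write_batch_csv",
    "write_timeseries_csv",
    "write_vtk_structured_grid",
    "write_flow_snapshot_csv",
    "read_flow_snapshot_csv",
    "write_provenance",
]


def output_name(label: str, stage: str, cycle: int = 0, step: int = 0,
                ext: str = "csv") -> str:
    return f"{label}_{stage}_{cycle:03d}_{step:05d}.{ext}"


def _col(name: str) -> str:
    return name.replace(":", "_")


def write_batch_csv(traj: BatchTrajectory, path: str) -> None:
    """Batch trajectory as CSV: time_s plus the 18 species (mol/m^3)."""
    cols = {"time_s": traj.t}
    for i, s in enumerate(SPECIES):
        cols[f"{_col(s)}_mol_per_m3"] = traj.c[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12e")


def write_timeseries_csv(path: str, columns: dict[str, np.ndarray]) -> None:
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.12e")


def write_vtk_structured_grid(path: str, grid: StructuredGrid,
                              cell_data: dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK structured grid of the meridional (z, r) plane with
    per-cell scalar fields."""
    nz, nr = grid.nz, grid.nr
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("thromboflow axisymmetric structured grid\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nz + 1} {nr + 1} 1\n")
        fh.write(f"POINTS {(nz + 1) * (nr + 1)} double\n")
        for j in range(nr + 1):
            for i in range(nz + 1):
                fh.write(f"{grid.Zn[i, j]:.9e} {grid.Rn[i, j]:.9e} 0.0\n")
        fh.write(f"CELL_DATA {nz * nr}\n")
        for name, field in cell_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for j in range(nr):
                for i in range(nz):
                    fh.write(f"{field[i, j]:.9e}\n")


def write_flow_snapshot_csv(path: str, flow: FlowField) -> None:
    """Flow snapshot with enough header metadata to rebuild the grid and
    recompute derived fields (lambda_2, Peclet) offline."""
    grid = flow.grid
    geo = grid.geometry
    meta = dict(R0=geo.R0, Rmax=geo.Rmax, entrance_length=geo.entrance_length,
                bulge_length=geo.bulge_length, exit_length=geo.exit_length,
                nz=grid.nz, nr=grid.nr, wall_clustering=grid.wall_clustering,
                t=flow.t)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v!r}\n")
        fh.write("i,j,z_m,r_m,u_z_m_per_s,u_r_m_per_s,p_Pa\n")
        for i in range(grid.nz):
            for j in range(grid.nr):
                fh.write(f"{i},{j},{grid.zc[i, j]:.9e},{grid.rc[i, j]:.9e},"
                         f"{flow.u_z[i, j]:.9e},{flow.u_r[i, j]:.9e},"
                         f"{flow.p[i, j]:.9e}\n")


def read_flow_snapshot_csv(path: str) -> FlowField:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = float(value.strip())
    geo = AAAGeometry(R0=meta["R0"], Rmax=meta["Rmax"],
                      entrance_length=meta["entrance_length"],
                      bulge_length=meta["bulge_length"],
                      exit_length=meta["exit_length"])
    grid = StructuredGrid(geo, nz=int(meta["nz"]), nr=int(meta["nr"]),
                          wall_clustering=meta["wall_clustering"])
    df = pd.read_csv(path, comment="#")
    shape = (grid.nz, grid.nr)
    u_z = df["u_z_m_per_s"].to_numpy().reshape(shape)
    u_r = df["u_r_m_per_s"].to_numpy().reshape(shape)
    p = df["p_Pa"].to_numpy().reshape(shape)
    return FlowField(grid, float(meta.get("t", 0.0)), u_z, u_r, p,
                     np.zeros((grid.nz + 1, grid.nr)),
                     np.zeros((grid.nz, grid.nr + 1)))


def write_provenance(record: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
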