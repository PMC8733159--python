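"""Exchange-file readers and writers.

The stages hand data to each other through plain CSV files (UTF-8, comma
separated, '.' decimal, LF endings, header row), mirroring a file-based
two-solver pipeline:

    wall_motion.csv        cycle_time_s, node_id, x_m, y_m
    boundary_pressure.csv  cycle_time_s, p_inlet_Pa, p_outlet_Pa, p_chamber_Pa
    wall_pressure.csv      cycle_time_s, element_id, p_Pa
    pressure_factor.csv    cycle_time_s, element_id, x
    scaling_factor.csv     cycle_time_s, y_s
    residual_volume.csv    time_s, V_res_ml
    coupling_report.json   ED summaries (mm), convergence flag, manifest

Doubles are written with 17 significant digits so a write/read round trip is
bit-faithful.  Readers normalize row order by (time, id), require complete
element/node coverage at every stored time, and raise :class:`FormatError`
naming the offending line for missing columns, duplicates, or gaps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "write_wall_motion", "read_wall_motion",
    "write_boundary_pressure", "read_boundary_pressure",
    "write_wall_pressure", "read_wall_pressure",
    "write_pressure_factor", "read_pressure_factor",
    "write_scaling_factor", "write_residual_volume",
    "write_report", "write_vtk", "VtkSeriesWriter",
]

_FLOAT_FMT = "%.17g"


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _check_rect(df: pd.DataFrame, path, tcol: str, idcol: str):
    """Duplicate and coverage checks for (time, id)-keyed tables; returns
    the table sorted by (time, id) plus the time and id axes."""
    dup = df.duplicated(subset=[tcol, idcol])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(f"{path}: duplicate ({tcol}, {idcol}) pair at data "
                          f"line {row + 2}")
    df = df.sort_values([tcol, idcol], kind="mergesort")
    times = np.unique(df[tcol].to_numpy())
    ids = np.unique(df[idcol].to_numpy())
    if len(df) != times.size * ids.size:
        raise FormatError(f"{path}: incomplete coverage — expected "
                          f"{times.size}x{ids.size} rows, found {len(df)}")
    if np.any(np.diff(times) <= 0):  # pragma: no cover - unique() sorts
        raise FormatError(f"{path}: non-monotone time axis")
    return df, times, ids


# -- wall motion ------------------------------------------------------------

def write_wall_motion(path, mech) -> None:
    T, N = mech.times.size, mech.node_xy.shape[1]
    df = pd.DataFrame({
        "cycle_time_s": np.repeat(mech.times, N),
        "node_id": np.tile(np.arange(N), T),
        "x_m": mech.node_xy[:, :, 0].ravel(),
        "y_m": mech.node_xy[:, :, 1].ravel(),
    })
    _write_csv(df, path)


def read_wall_motion(path):
    """Returns (times, node_xy) with node_xy of shape (T, N, 2)."""
    df = _read_csv(path, ["cycle_time_s", "node_id", "x_m", "y_m"])
    df, times, ids = _check_rect(df, path, "cycle_time_s", "node_id")
    T, N = times.size, ids.size
    xy = np.empty((T, N, 2))
    xy[:, :, 0] = df["x_m"].to_numpy().reshape(T, N)
    xy[:, :, 1] = df["y_m"].to_numpy().reshape(T, N)
    return times, xy


# -- boundary pressures -----------------------------------------------------

def write_boundary_pressure(path, mech) -> None:
    df = pd.DataFrame({
        "cycle_time_s": mech.times,
        "p_inlet_Pa": mech.p_inlet,
        "p_outlet_Pa": mech.p_outlet,
        "p_chamber_Pa": mech.p_chamber,
    })
    _write_csv(df, path)


def read_boundary_pressure(path):
    df = _read_csv(path, ["cycle_time_s", "p_inlet_Pa", "p_outlet_Pa",
                          "p_chamber_Pa"])
    df = df.sort_values("cycle_time_s", kind="mergesort")
    t = df["cycle_time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise FormatError(f"{path}: non-monotone time at data line {bad + 2}")
    return (t, df["p_inlet_Pa"].to_numpy(), df["p_outlet_Pa"].to_numpy(),
            df["p_chamber_Pa"].to_numpy())


# -- wall pressure / pressure factor ---------------------------------------

def write_wall_pressure(path, times, p) -> None:
    T, E = np.shape(p)
    df = pd.DataFrame({
        "cycle_time_s": np.repeat(np.asarray(times), E),
        "element_id": np.tile(np.arange(E), T),
        "p_Pa": np.asarray(p).ravel(),
    })
    _write_csv(df, path)


def read_wall_pressure(path):
    df = _read_csv(path, ["cycle_time_s", "element_id", "p_Pa"])
    df, times, ids = _check_rect(df, path, "cycle_time_s", "element_id")
    return times, df["p_Pa"].to_numpy().reshape(times.size, ids.size)


def write_pressure_factor(path, pf) -> None:
    T, E = pf.x.shape
    df = pd.DataFrame({
        "cycle_time_s": np.repeat(np.asarray(pf.times), E),
        "element_id": np.tile(np.arange(E), T),
        "x": np.asarray(pf.x).ravel(),
    })
    _write_csv(df, path)


def read_pressure_factor(path):
    from .coupling import PressureFactorField
    df = _read_csv(path, ["cycle_time_s", "element_id", "x"])
    df, times, ids = _check_rect(df, path, "cycle_time_s", "element_id")
    x = df["x"].to_numpy().reshape(times.size, ids.size)
    # the scaling trace is not part of this file; a zero trace satisfies the
    # container's clip invariant and the factor itself is what consumers use
    return PressureFactorField(times=times, x=x, y_s=np.zeros(times.size))


def write_scaling_factor(path, pf) -> None:
    _write_csv(pd.DataFrame({"cycle_time_s": pf.times, "y_s": pf.y_s}), path)


def write_residual_volume(path, times, v_ml) -> None:
    _write_csv(pd.DataFrame({"time_s": times, "V_res_ml": v_ml}), path)


def write_ed_summary(path, rows: list[dict]) -> None:
    _write_csv(pd.DataFrame(rows), path)


def write_pv_loop(path, V_ml, p_mmHg) -> None:
    _write_csv(pd.DataFrame({"V_ml": V_ml, "p_mmHg": p_mmHg}), path)


# -- report -----------------------------------------------------------------

def write_report(path, report) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


# -- legacy ASCII VTK -------------------------------------------------------

def write_vtk(path, mesh, node_xy=None, cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK (UNSTRUCTURED_GRID) snapshot of the polygonal mesh
    with optional cell-centered scalar/vector fields."""
    xy = mesh.node_xy0 if node_xy is None else node_xy
    cells = mesh.cells
    lines = ["# vtk DataFile Version 3.0", "cardioloop snapshot", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {xy.shape[0]} double"]
    for p in xy:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} 0")
    tri = cells[:, 0] == cells[:, 3]
    sizes = np.where(tri, 3, 4)
    lines.append(f"CELLS {cells.shape[0]} {int((sizes + 1).sum())}")
    for c, is_tri in zip(cells, tri):
        ids = c[:3] if is_tri else c
        lines.append(" ".join(map(str, [len(ids), *ids])))
    lines.append(f"CELL_TYPES {cells.shape[0]}")
    lines.extend("5" if t else "9" for t in tri)   # 5 = triangle, 9 = quad
    if cell_data:
        lines.append(f"CELL_DATA {cells.shape[0]}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.17g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.17g} {v[1]:.17g} 0" for v in arr)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class VtkSeriesWriter:
    """Numbered VTK snapshots (velocity, pressure, psi, mesh velocity)."""

    def __init__(self, outdir, mesh):
        self.outdir = Path(outdir)
        self.mesh = mesh

    def write(self, step: int, node_xy, state) -> None:
        write_vtk(self.outdir / f"fluid_{step:06d}.vtk", self.mesh, node_xy,
                  {"pressure": state.p, "psi": state.psi,
                   "velocity": state.u, "mesh_velocity": state.c_mesh})
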