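"""Evaluation criteria: Euclidean-distance convergence fields, pressure-factor
quantile bands, residual-volume washout, PV loops, and dimensionless numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ComparisonError, ConfigurationError
from .materials import MMHG_TO_PA

__all__ = [
    "EDField",
    "euclidean_distance",
    "ed_summary",
    "pf_band_stats",
    "residual_volume",
    "pv_loop",
    "womersley",
    "reynolds",
]


@dataclass(frozen=True)
class EDField:
    """Per-node, per-time displacement distance between two runs (mm)."""

    times: np.ndarray      # (T,)
    d: np.ndarray          # (T, N) in mm

    @property
    def summary(self) -> dict:
        return {"min": float(self.d.min()), "max": float(self.d.max()),
                "mean": float(self.d.mean())}


def euclidean_distance(run_a, run_b) -> EDField:
    """Node-wise Euclidean distance d_i(t) = |x_i^(b)(t) - x_i^(a)(t)| in mm.

    Both runs must store the same node indexing on the same per-cycle
    sampling grid (the mechanics stage guarantees this); the z component of
    the planar model is identically zero.
    """
    if run_a.node_xy.shape != run_b.node_xy.shape:
        raise ComparisonError(
            f"mismatched node grids {run_a.node_xy.shape} vs {run_b.node_xy.shape}")
    if not np.array_equal(run_a.times, run_b.times):
        raise ComparisonError("mismatched sampling times")
    diff = run_b.node_xy - run_a.node_xy          # (T, N, 2)
    d = np.sqrt(np.sum(diff ** 2, axis=-1)) * 1e3
    return EDField(times=run_a.times.copy(), d=d)


def ed_summary(ed: EDField,
               node_sets: Mapping[str, Sequence[int]] | None = None) -> list[dict]:
    """Min/max/mean rows (mm) per named node group plus an Overall row."""
    rows = []
    if node_sets:
        for name, idx in node_sets.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0:
                raise ConfigurationError(f"empty node group {name!r}")
            sub = ed.d[:, idx]
            rows.append({"group": name, "min": float(sub.min()),
                         "max": float(sub.max()), "mean": float(sub.mean())})
    rows.append({"group": "Overall", **ed.summary})
    return rows


def pf_band_stats(pf) -> dict[str, np.ndarray]:
    """Per-time extrema and central 50% / 90% quantile envelopes of the
    pressure factor (linear interpolation of order statistics)."""
    x = np.asarray(pf.x, dtype=float)
    if x.shape[1] < 4:
        raise ConfigurationError("need at least 4 elements for quantile bands")
    q = np.quantile(x, [0.05, 0.25, 0.75, 0.95], axis=1)
    return {
        "times": np.asarray(pf.times, float),
        "min": x.min(axis=1), "max": x.max(axis=1),
        "q05": q[0], "q25": q[1], "q75": q[2], "q95": q[3],
    }


def residual_volume(psi: np.ndarray, mesh, node_xy: np.ndarray | None = None) -> float:
    """Residual initial-blood volume sum_c psi_c V_c over chamber cells (ml)."""
    from .geometry import cell_volumes
    vol = cell_volumes(mesh, node_xy)
    sel = mesh.chamber_cells
    return float(np.sum(np.asarray(psi)[sel] * vol[sel]) * 1e6)


def pv_loop(mech) -> tuple[np.ndarray, np.ndarray]:
    """(V in ml, p_chamber in mmHg) arrays over the stored last cycle."""
    if mech.times.size < 2:
        raise ConfigurationError("need at least one stored cycle for a PV loop")
    return mech.V * 1e6, mech.p_chamber / MMHG_TO_PA


def womersley(d: float = 0.015, rho: float = 1055.0, mu: float = 0.004,
              omega: float = 2.0 * math.pi) -> float:
    """Womersley number d * sqrt(omega * rho / mu) for a port of diameter d."""
    return d * math.sqrt(omega * rho / mu)


def reynolds(u: float, d: float = 0.015, rho: float = 1055.0,
             mu: float = 0.004) -> float:
    """Reynolds number rho * u * d / mu."""
    return rho * u * d / mu
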