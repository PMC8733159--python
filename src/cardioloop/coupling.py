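"""Cycle-to-cycle pressure-factor coupling.

The fluid stage delivers a wall pressure sample p_{i,t} for every endocardial
wall element i of a chamber.  The mechanics stage only knows one spatial mean
pressure per chamber (from the lumped circulation).  The coupling payload is
the dimensionless, spatially resolved pressure factor

    x_{i,t} = y_{s,t} * (p_{i,t} - p_mean,t) / (p_max,t - p_min,t) + 1

built from the per-time spatial statistics (min, max, mean over the chamber's
elements) and the time-resolved scaling factor

    y_{s,t} = 2 * (p_max,t - p_mean,t) / p_max,t ,  clipped to [-3, 3].

By construction the element mean of x is exactly one at every time, so
multiplying the circulation pressure by x redistributes load spatially
without changing the mean chamber pressure — the circulation model stays in
balance.  With y_s = 1 the factor is bounded in [0, 2].

Degenerate inputs follow two conventions that both preserve the mean-one
property and the identity behavior: a spatially uniform field (p_max = p_min)
yields x = 1, and p_max = 0 yields y_s = 0.

Note: the scaling factor above does not make x * p_mean reconstruct p_i
exactly (that would require y = (p_max - p_min) / p_mean); the definition is
applied literally and no reconstruction is enforced.  See docs/methods.md.

`run_coupled` orchestrates the whole loop: a 10-cycle mechanics run, a
4-cycle fluid run, pressure-factor extraction, and the node-wise Euclidean
distance between the last cycles of successive mechanics runs as the
convergence metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ChamberStats",
    "PressureFactorField",
    "CouplingReport",
    "chamber_stats",
    "scaling_factor",
    "pressure_factor",
    "adapted_pressure",
    "phase_align",
    "build_pressure_factor_field",
    "run_coupled",
    "Y_CLIP",
]

log = logging.getLogger(__name__)

#: Hard bound on the scaling factor magnitude.
Y_CLIP = 3.0


@dataclass(frozen=True)
class ChamberStats:
    """Spatial pressure statistics per stored time (Pa): p_min <= p_mean <= p_max."""

    times: np.ndarray
    p_min: np.ndarray
    p_max: np.ndarray
    p_mean: np.ndarray


@dataclass(frozen=True)
class PressureFactorField:
    """Dimensionless factor x[t][e] on one cycle of phase samples plus the
    per-time scaling y_s.  Element indexing matches the chamber wall
    segments of the geometry it was computed for."""

    times: np.ndarray       # (T,) cycle phase (s)
    x: np.ndarray           # (T, E)
    y_s: np.ndarray         # (T,)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 2 or x.shape[0] != len(self.times):
            raise ConfigurationError("x must be (n_times, n_elements)")
        mean_err = np.max(np.abs(x.mean(axis=1) - 1.0)) if x.size else 0.0
        if mean_err > 1e-9:
            raise ConfigurationError(
                f"pressure factor violates the mean-one constraint by {mean_err:.2e}")
        if np.any(np.abs(self.y_s) > Y_CLIP + 1e-12):
            raise ConfigurationError("scaling factor exceeds the clip bound")

    @classmethod
    def identity(cls, times: np.ndarray, n_elements: int) -> "PressureFactorField":
        t = np.asarray(times, dtype=float)
        return cls(times=t, x=np.ones((t.size, n_elements)), y_s=np.zeros(t.size))


@dataclass
class CouplingReport:
    """Everything the coupling loop measured, one entry per iteration."""

    ed_summaries: list = field(default_factory=list)   # dicts with min/max/mean (mm)
    pf_extrema: list = field(default_factory=list)     # (x_min, x_max) per fluid run
    residual_volume: list = field(default_factory=list)  # (times, V_ml) per fluid run
    pv_loops: list = field(default_factory=list)       # (V_ml, p_mmHg) per mech run
    converged: bool = False
    n_iterations: int = 0
    tol_mm: float = 0.1
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "tol_mm": float(self.tol_mm),
            "ed_summaries_mm": [
                {k: float(v) for k, v in s.items()} for s in self.ed_summaries],
            "pf_extrema": [[float(a), float(b)] for a, b in self.pf_extrema],
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# element statistics and the factor itself
# ---------------------------------------------------------------------------

def chamber_stats(times: np.ndarray, p: np.ndarray,
                  element_set: Sequence[int] | None = None) -> ChamberStats:
    """Unweighted spatial min/max/mean over a chamber's wall elements.

    p is (n_times, n_elements); ``element_set`` restricts the statistics to a
    chamber's elements (default: all).  Element areas are deliberately not
    used as weights.
    """
    p = np.asarray(p, dtype=float)
    if element_set is not None:
        idx = np.asarray(element_set, dtype=np.int64)
        if idx.size == 0:
            raise ConfigurationError("empty element set")
        p = p[:, idx]
    if p.size == 0:
        raise ConfigurationError("empty pressure field")
    return ChamberStats(
        times=np.asarray(times, dtype=float),
        p_min=p.min(axis=1), p_max=p.max(axis=1), p_mean=p.mean(axis=1))


def scaling_factor(p_max, p_mean):
    """Time-resolved scaling y = 2 (p_max - p_mean)/p_max, clipped to [-3, 3].

    p_max = 0 maps to y = 0 (a degenerate field carries no usable amplitude).
    Vectorized over time.
    """
    p_max = np.asarray(p_max, dtype=float)
    p_mean = np.asarray(p_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        y = 2.0 * (p_max - p_mean) / p_max
    y = np.where(p_max == 0.0, 0.0, y)
    return np.clip(y, -Y_CLIP, Y_CLIP)


def pressure_factor(p: np.ndarray, stats: ChamberStats,
                    y_s: np.ndarray) -> np.ndarray:
    """Spatially resolved factor x (n_times, n_elements) with element mean 1.

    Uniform time slices (p_max = p_min) yield x = 1 for that slice; the
    uniform pressure carries no spatial information and the identity factor
    is the neutral payload.
    """
    p = np.asarray(p, dtype=float)
    rng = stats.p_max - stats.p_min
    degenerate = rng == 0.0
    if np.any(degenerate):
        log.info("uniform wall pressure at %d/%d times: emitting x = 1 there",
                 int(degenerate.sum()), degenerate.size)
    safe = np.where(degenerate, 1.0, rng)
    x = (np.asarray(y_s)[:, None] * (p - stats.p_mean[:, None])
         / safe[:, None] + 1.0)
    x[degenerate, :] = 1.0
    # remove the float dust so the mean-one constraint holds to 1e-12 even
    # for adversarial fields
    x -= x.mean(axis=1, keepdims=True) - 1.0
    return x


def adapted_pressure(p_mech_c, x):
    """Adapted local mechanical pressure p* = p_mech,c * x (Pa).

    With the mean-one constraint the element mean of p* equals the
    circulation pressure p_mech,c.
    """
    return np.asarray(p_mech_c, dtype=float) * np.asarray(x, dtype=float)


def phase_align(pf: PressureFactorField, t_query: float, T_cycle: float) -> np.ndarray:
    """Factor slice at an arbitrary time by periodic linear interpolation in
    cycle phase.

    Exactly reproduces stored slices at stored times, wraps between the last
    and first sample, and (because the interpolation is written as
    ``x0 + w*(x1 - x0)``) returns exactly 1 everywhere when the field is the
    identity field.
    """
    times = pf.times
    if times.size == 0:
        raise ConfigurationError("empty pressure factor field")
    if times.size == 1:
        return pf.x[0].copy()
    phase = float(np.mod(t_query, T_cycle))
    j = int(np.searchsorted(times, phase, side="right") - 1)
    j = max(j, 0)
    if j >= times.size - 1:
        t0, t1 = times[-1], times[0] + T_cycle
        x0, x1 = pf.x[-1], pf.x[0]
        if phase < t0:      # query before the first sample: wrap backwards
            t0, t1 = times[-1] - T_cycle, times[0]
    else:
        t0, t1 = times[j], times[j + 1]
        x0, x1 = pf.x[j], pf.x[j + 1]
    if t1 == t0:
        return x0.copy()
    w = (phase - t0) / (t1 - t0)
    return x0 + w * (x1 - x0)


def _periodic_moving_average(a: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with periodic wrap along axis 0; the kernel
    sums first and divides once, so a constant field passes through exactly."""
    if n <= 1:
        return a
    half = n // 2
    n = 2 * half + 1
    ext = np.concatenate([a[-half:], a, a[:half]], axis=0)
    ker = np.ones(n)
    if a.ndim == 1:
        return np.convolve(ext, ker, mode="valid") / n
    out = np.empty_like(a)
    for e in range(a.shape[1]):
        out[:, e] = np.convolve(ext[:, e], ker, mode="valid") / n
    return out


def build_pressure_factor_field(times: np.ndarray, p_wall: np.ndarray,
                                element_set: Sequence[int] | None = None,
                                smooth_window: float = 0.0
                                ) -> PressureFactorField:
    """Full pipeline: statistics -> scaling -> factor, for one chamber.

    ``smooth_window`` (s) applies a centered periodic moving average over
    cycle phase to the factor and the scaling trace.  Rapid valve events
    (above all the end-ejection pressure collapse) otherwise imprint large,
    ill-conditioned single-sample factors — p_max passes through zero there
    — that destabilize the coupling loop; a short time window for the
    factor determination suppresses them.  Smoothing is a convex
    combination per element, so the mean-one constraint, the clip bound and
    the identity field are all preserved exactly.
    """
    times = np.asarray(times, float)
    stats = chamber_stats(times, p_wall, element_set)
    y = scaling_factor(stats.p_max, stats.p_mean)
    x = pressure_factor(np.asarray(p_wall, float), stats, y)
    if smooth_window > 0.0 and times.size > 2:
        dt = float(np.median(np.diff(times)))
        n = int(round(smooth_window / dt))
        if n > 1:
            x = _periodic_moving_average(x, n)
            y = _periodic_moving_average(y, n)
            x -= x.mean(axis=1, keepdims=True) - 1.0
    return PressureFactorField(times=times, x=x, y_s=y)


# ---------------------------------------------------------------------------
# the orchestration loop
# ---------------------------------------------------------------------------

def run_coupled(config, fluid_stage: Callable | None = None,
                outdir=None) -> CouplingReport:
    """Iterate mechanics and fluid stages until the wall displacement settles.

    Iteration 0 runs the mechanics uncoupled (10 cycles), hands the last
    cycle to the fluid stage (4 cycles), and extracts the pressure factor.
    Iteration j >= 1 reruns the mechanics with the factor applied, measures
    the node-wise Euclidean distance (ED) to the previous iteration's last
    cycle, and stops when the maximum ED drops below ``config.coupling.tol_mm``
    or ``max_iter`` is reached.

    ``fluid_stage(mech_result, config)`` may be injected (e.g. a stub that
    returns a uniform wall pressure, which makes iteration 1 the exact fixed
    point); it must return ``(times, p_wall, residual_volume_trace)``.
    """
    from .mechanics import run_mechanics
    from .fluid import run_fluid
    from .diagnostics import euclidean_distance, pv_loop
    from . import io as cio

    cc = config.coupling
    report = CouplingReport(tol_mm=cc.tol_mm)

    def default_fluid(mech, cfg):
        res = run_fluid(mech, cfg)
        return res.times, res.wall_pressure, (res.residual_times, res.residual_volume_ml)

    stage = fluid_stage or default_fluid

    mech_prev = run_mechanics(config, n_cycles=cc.n_mech_cycles, pf=None)
    report.pv_loops.append(pv_loop(mech_prev))
    if outdir is not None:
        cio.write_wall_motion(outdir / "wall_motion.csv", mech_prev)
        cio.write_boundary_pressure(outdir / "boundary_pressure.csv", mech_prev)
        cio.write_pv_loop(outdir / "pv_loop_0.csv", *report.pv_loops[0])

    ed_prev_max = None
    for j in range(cc.max_iter):
        times, p_wall, resvol = stage(mech_prev, config)
        pf = build_pressure_factor_field(
            times, p_wall, smooth_window=getattr(cc, "pf_smooth_s", 0.0))
        report.pf_extrema.append((float(pf.x.min()), float(pf.x.max())))
        report.residual_volume.append(resvol)
        if outdir is not None:
            cio.write_pressure_factor(outdir / f"pressure_factor_{j}.csv", pf)
            cio.write_scaling_factor(outdir / f"scaling_factor_{j}.csv", pf)

        mech_new = run_mechanics(config, n_cycles=cc.n_mech_cycles, pf=pf)
        report.pv_loops.append(pv_loop(mech_new))
        ed = euclidean_distance(mech_prev, mech_new)
        summary = {"min": float(ed.d.min()), "max": float(ed.d.max()),
                   "mean": float(ed.d.mean())}
        report.ed_summaries.append(summary)
        if outdir is not None:
            from .diagnostics import ed_summary as ed_rows
            cio.write_ed_summary(outdir / f"ed_summary_{j}.csv", ed_rows(ed))
            cio.write_pv_loop(outdir / f"pv_loop_{j + 1}.csv",
                              *report.pv_loops[-1])
            cio.write_residual_volume(outdir / f"residual_volume_{j}.csv",
                                      *resvol)
        report.n_iterations = j + 1
        log.info("iteration %d: max ED %.4f mm, mean ED %.4f mm",
                 j, summary["max"], summary["mean"])
        if ed_prev_max is not None and summary["max"] >= ed_prev_max:
            report.warnings.append(
                f"coupling not contracting at iteration {j}: "
                f"max ED {summary['max']:.4f} mm >= {ed_prev_max:.4f} mm")
        ed_prev_max = summary["max"]
        mech_prev = mech_new
        if summary["max"] < cc.tol_mm:
            report.converged = True
            break

    if outdir is not None:
        cio.write_report(outdir / "coupling_report.json", report)
    return report
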