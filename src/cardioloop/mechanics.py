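"""Reduced spatially resolved wall mechanics with a lumped circulation.

Each wall node carries one radial degree of freedom r_i along its fixed ray
from the base center.  The force balance per unit wall area is a damped
Laplace-law oscillator:

    m_eff a_i = (p_local,i - p_ext) - [T_pass(lam_i) + T_act(t)] / r_i
                + kappa (r_{i+1} - 2 r_i + r_{i-1}) - c_damp v_i

with lam_i = r_i / r0_i, m_eff = rho0 h0 the wall surface density, passive
tension from the Guccione membrane reduction, a spatially uniform active
drive, a neighbor-coupling regularization kappa, and viscous damping.  Apex
and base-adjacent nodes use one-sided difference stencils.

The chamber is closed by a minimal circulation: a constant-pressure atrial
preload behind a mitral diode, an aortic diode into a two-element Windkessel
afterload, and a stiff artificial compliance that slaves the chamber
pressure to the volume balance,

    dp_chamber/dt = K_c (Q_mv - Q_ao - dV_wall/dt) / V ,

updated backward-Euler because K_c is deliberately stiff.

When a pressure factor is supplied, the local wall load in the coupled
window becomes p*_i = p_chamber(t) * x_i(phase) — spatial redistribution at
preserved chamber mean.  With x identically one the computation is bitwise
identical to the uncoupled run, which is the coupling's fixed-point anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError, SolverError, StabilityError
from .geometry import ChamberGeometry
from .materials import (ActivationParams, GuccioneParams, MMHG_TO_PA,
                        active_tension, membrane_tension)

__all__ = [
    "WallState",
    "CirculationState",
    "MechResult",
    "MechParams",
    "wall_rhs",
    "circulation_step",
    "run_mechanics",
    "chamber_volume",
    "segments_to_nodes",
]

_MAX_PRESSURE_STEP = 50.0 * MMHG_TO_PA
_LAMBDA_RANGE = (0.2, 3.0)


@dataclass
class WallState:
    r: np.ndarray       # (N,) current radius per boundary node (m)
    v: np.ndarray       # (N,) radial velocity (m/s)
    t: float            # time (s)


@dataclass
class CirculationState:
    p_chamber: float    # mean chamber pressure (Pa)
    p_atrium: float     # preload (Pa)
    p_art: float        # proximal arterial pressure (Pa)
    Q_mv: float = 0.0   # mitral inflow (m^3/s, >= 0)
    Q_ao: float = 0.0   # aortic outflow (m^3/s, >= 0)
    V: float = 0.0      # chamber volume (m^3)


@dataclass(frozen=True)
class MechParams:
    """Everything the wall ODE needs, precomputed from a RunConfig."""

    r0: np.ndarray
    theta: np.ndarray
    h0: float
    m_eff: float
    kappa: float
    c_damp: float
    p_ext: float
    guccione: GuccioneParams
    activation: ActivationParams
    act_weight: np.ndarray | None = None   # per-node active-stress weight

    @classmethod
    def from_config(cls, cfg: RunConfig, geom: ChamberGeometry) -> "MechParams":
        m = cfg.material
        g = GuccioneParams(C=m.C, b_f=m.b_f, b_t=m.b_t, b_ft=m.b_ft,
                           K=m.K, rho0=m.rho0)
        a = cfg.activation
        act = ActivationParams(T_peak=a.T_peak, alpha1=a.alpha1, alpha2=a.alpha2,
                               n1=a.n1, n2=a.n2, T_cycle=a.T_cycle,
                               t_onset=a.t_onset)
        # the active stress tapers toward the base corners (sin(theta)^q):
        # the valve annulus is much stiffer than the free wall and barely
        # contracts, which also keeps the near-base fluid cells from being
        # squeezed against the rigid port tubes
        w = np.sin(geom.theta) ** cfg.wall.activation_taper \
            if cfg.wall.activation_taper > 0 else np.ones_like(geom.theta)
        return cls(r0=geom.r0.copy(), theta=geom.theta.copy(), h0=geom.h0,
                   m_eff=m.rho0 * geom.h0, kappa=cfg.wall.kappa,
                   c_damp=cfg.wall.c_damp, p_ext=cfg.wall.p_ext,
                   guccione=g, activation=act, act_weight=w)


@dataclass
class MechResult:
    """Last-cycle traces on the shared per-cycle sampling grid.

    The sampling grid (n_out uniform phase points) and the node indexing are
    identical across iterations of a study — required for node-wise
    displacement comparisons.
    """

    times: np.ndarray        # (T,) phase within the cycle (s)
    node_xy: np.ndarray      # (T, N, 2) wall node coordinates (m)
    p_chamber: np.ndarray    # (T,) Pa
    p_inlet: np.ndarray      # (T,) Pa (atrial/pulmonary-vein side)
    p_outlet: np.ndarray     # (T,) Pa (aortic side)
    V: np.ndarray            # (T,) m^3
    Q_mv: np.ndarray         # (T,) m^3/s
    Q_ao: np.ndarray         # (T,) m^3/s
    cycle_index: int
    geom: ChamberGeometry
    T_cycle: float


def chamber_volume(node_xy: np.ndarray) -> float:
    """Chamber volume (m^3 at unit depth): shoelace area of the wall polygon
    closed by the straight base chord between its two end nodes."""
    x = node_xy[:, 0]
    y = node_xy[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    area = abs(float(area))
    if area <= 0:
        raise ConfigurationError("degenerate wall polygon")
    return area


def segments_to_nodes(x_seg: np.ndarray) -> np.ndarray:
    """Map a per-segment field to nodes by adjacent-segment averaging
    (end nodes take their single adjacent segment)."""
    x_seg = np.asarray(x_seg, dtype=float)
    n = x_seg.size + 1
    out = np.empty(n)
    out[0] = x_seg[0]
    out[-1] = x_seg[-1]
    out[1:-1] = 0.5 * (x_seg[:-1] + x_seg[1:])
    return out


def wall_rhs(state: WallState, p_local: np.ndarray, t: float,
             params: MechParams) -> np.ndarray:
    """Nodal radial accelerations (m/s^2) of the wall force balance."""
    r = state.r
    if not np.all(np.isfinite(p_local)):
        bad = int(np.flatnonzero(~np.isfinite(p_local))[0])
        raise SolverError(f"non-finite wall pressure at node {bad}")
    lam = r / params.r0
    T_pass = membrane_tension(lam, params.guccione, params.h0)
    T_act = active_tension(t, params.activation) * params.h0
    if params.act_weight is not None:
        T_act = T_act * params.act_weight
    lap = np.empty_like(r)
    lap[1:-1] = r[:-2] - 2.0 * r[1:-1] + r[2:]
    lap[0] = r[1] - r[0]
    lap[-1] = r[-2] - r[-1]
    force = ((p_local - params.p_ext)
             - (T_pass + T_act) / r
             + params.kappa * lap
             - params.c_damp * state.v)
    if not np.all(np.isfinite(force)):
        bad = int(np.flatnonzero(~np.isfinite(force))[0])
        raise SolverError(f"non-finite wall force at node {bad}")
    return force / params.m_eff


def _solve_chamber_pressure(p_old: float, g: float, dV: float,
                            p_at: float, p_art: float,
                            R_mv: float, R_ao: float,
                            A_w: float = 0.0) -> float:
    """Backward-Euler chamber pressure with diode valves.

    Solves p = p_old + g (Qmv(p) - Qao(p) - dV - A_w (p - p_old)) where
    g = dt K_c / V, the flows are piecewise linear diodes, and A_w is the
    wall's one-step volume-rate admittance dV_dot/dp.  The admittance term
    anticipates the wall's velocity response to the new pressure; without it
    the stiff compliance and the explicit wall update form an unstable
    feedback loop at any practical step size.  The right-hand side is
    monotonically decreasing in p so exactly one diode configuration is
    consistent.
    """
    gA = g * A_w
    rhs0 = p_old * (1.0 + gA) - g * dV
    # both closed
    p = rhs0 / (1.0 + gA)
    if p_at - 1e-12 <= p <= p_art + 1e-12:
        return p
    # mitral open, aortic closed
    p = (rhs0 + g * p_at / R_mv) / (1.0 + gA + g / R_mv)
    if p < p_at and p <= p_art + 1e-12:
        return p
    # aortic open, mitral closed
    p = (rhs0 + g * p_art / R_ao) / (1.0 + gA + g / R_ao)
    if p > p_art and p >= p_at - 1e-12:
        return p
    # both open (only when preload exceeds afterload)
    p = (rhs0 + g * (p_at / R_mv + p_art / R_ao)) / (
        1.0 + gA + g / R_mv + g / R_ao)
    return p


def circulation_step(circ: CirculationState, dV_wall_dt: float, dt: float,
                     cfg, wall_admittance: float = 0.0) -> CirculationState:
    """One backward-Euler update of the lumped circulation.

    cfg is a CirculationConfig; ``wall_admittance`` is the wall's one-step
    volume-rate response to a chamber-pressure change (m^3 s^-1 Pa^-1),
    zero for a rigid chamber.  Raises :class:`StabilityError` if the implied
    chamber-pressure step exceeds 50 mmHg (advises a smaller dt).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    g = dt * cfg.K_c / circ.V
    p_new = _solve_chamber_pressure(circ.p_chamber, g, dV_wall_dt,
                                    circ.p_atrium, circ.p_art,
                                    cfg.R_mv, cfg.R_ao, wall_admittance)
    if abs(p_new - circ.p_chamber) > _MAX_PRESSURE_STEP:
        raise StabilityError(
            f"chamber pressure step {abs(p_new - circ.p_chamber) / MMHG_TO_PA:.1f}"
            " mmHg exceeds 50 mmHg; reduce the mechanics time step")
    Q_mv = max(circ.p_atrium - p_new, 0.0) / cfg.R_mv
    Q_ao = max(p_new - circ.p_art, 0.0) / cfg.R_ao
    # two-element Windkessel, implicit in p_art
    p_art = (circ.p_art + dt * Q_ao / cfg.C_art) / (
        1.0 + dt / (cfg.C_art * cfg.R_per))
    V = circ.V + dV_wall_dt * dt
    return CirculationState(p_chamber=p_new, p_atrium=circ.p_atrium,
                            p_art=p_art, Q_mv=Q_mv, Q_ao=Q_ao, V=V)


def _node_positions(r: np.ndarray, params: MechParams) -> np.ndarray:
    return np.column_stack([r * np.cos(params.theta),
                            -r * np.sin(params.theta)])


def passive_equilibrium_stretch(p: float, params: MechParams) -> float:
    """Stretch at which the passive Laplace tension balances a transmural
    pressure p (used to start the wall on, not far off, its limit cycle)."""
    from scipy.optimize import brentq

    r0_ref = float(np.mean(params.r0))

    def f(lam):
        return (p - params.p_ext) - membrane_tension(
            lam, params.guccione, params.h0) / (lam * r0_ref)

    if f(1.0) <= 0:
        return 1.0
    return float(brentq(f, 1.0, _LAMBDA_RANGE[1] - 1e-6))


def run_mechanics(cfg: RunConfig, n_cycles: int = 10, pf=None,
                  geom: ChamberGeometry | None = None) -> MechResult:
    """Integrate wall + circulation for ``n_cycles`` heart cycles and return
    the last cycle on the shared sampling grid.

    ``pf`` is an optional :class:`~cardioloop.coupling.PressureFactorField`
    indexed by wall segment; it modulates the local wall load in the last
    cycle (or every cycle with ``coupling.pf_window = "all"``).
    """
    from .coupling import phase_align  # local import to avoid a cycle

    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    geom = geom or cfg.make_geometry()
    params = MechParams.from_config(cfg, geom)
    if pf is not None and pf.x.shape[1] != geom.n_seg:
        raise ConfigurationError(
            f"pressure factor has {pf.x.shape[1]} elements, geometry has "
            f"{geom.n_seg} wall segments")

    T = params.activation.T_cycle
    steps_per_cycle = max(2, int(round(T / cfg.wall.dt)))
    dt = T / steps_per_cycle
    n_nodes = geom.n_seg + 1

    lam0 = passive_equilibrium_stretch(cfg.circulation.p_chamber0, params)
    r = lam0 * geom.r0
    v = np.zeros(n_nodes)
    circ = CirculationState(
        p_chamber=cfg.circulation.p_chamber0,
        p_atrium=cfg.circulation.p_atrium,
        p_art=cfg.circulation.p_art0,
        V=chamber_volume(_node_positions(r, params)))

    pf_all = cfg.coupling.pf_window == "all"
    last_cycle = n_cycles - 1

    # one-step wall admittance for the implicit pressure solve: a pressure
    # increment dp gives each node dv = dp*dt/(m_eff + c_damp*dt) and the
    # chamber a volume-rate increment dv * perimeter
    # the factor 2 over-relaxes the quasi-Newton pressure solve: with the
    # bare admittance the pressure/wall loop has unit gain (marginal), with
    # twice the admittance the residual halves every step
    wall0 = _node_positions(geom.r0, params)
    perimeter = float(np.sum(np.linalg.norm(np.diff(wall0, axis=0), axis=1)))
    A_w = 2.0 * dt * perimeter / (params.m_eff + params.c_damp * dt)

    # last-cycle raw storage (every step), resampled onto the n_out grid below
    rec_t: list[float] = []
    rec_r: list[np.ndarray] = []
    rec_p: list[float] = []
    rec_pa: list[float] = []
    rec_part: list[float] = []
    rec_V: list[float] = []
    rec_Qm: list[float] = []
    rec_Qa: list[float] = []

    lam_lo, lam_hi = _LAMBDA_RANGE
    V_old = circ.V
    for cyc in range(n_cycles):
        apply_pf = pf is not None and (pf_all or cyc == last_cycle)
        for k in range(steps_per_cycle):
            t = cyc * T + k * dt
            if cyc == last_cycle:
                rec_t.append(k * dt)
                rec_r.append(r.copy())
                rec_p.append(circ.p_chamber)
                rec_pa.append(circ.p_atrium)
                rec_part.append(circ.p_art)
                rec_V.append(V_old)
                rec_Qm.append(circ.Q_mv)
                rec_Qa.append(circ.Q_ao)
            if apply_pf:
                x_node = segments_to_nodes(phase_align(pf, t, T))
                p_node = circ.p_chamber * x_node
            else:
                p_node = np.full(n_nodes, circ.p_chamber)

            # RK4 on (r, v); wall pressure held over the step
            st = WallState(r=r, v=v, t=t)
            k1v = wall_rhs(st, p_node, t, params); k1r = v
            st2 = WallState(r=r + 0.5 * dt * k1r, v=v + 0.5 * dt * k1v, t=t)
            k2v = wall_rhs(st2, p_node, t + 0.5 * dt, params); k2r = st2.v
            st3 = WallState(r=r + 0.5 * dt * k2r, v=v + 0.5 * dt * k2v, t=t)
            k3v = wall_rhs(st3, p_node, t + 0.5 * dt, params); k3r = st3.v
            st4 = WallState(r=r + dt * k3r, v=v + dt * k3v, t=t)
            k4v = wall_rhs(st4, p_node, t + dt, params); k4r = st4.v
            r = r + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
            v = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)

            lam = r / params.r0
            if np.any(lam < lam_lo) or np.any(lam > lam_hi):
                bad = int(np.argmax(np.abs(np.log(np.maximum(lam, 1e-12)))))
                raise SolverError(
                    f"wall diverged at t={t:.4f}s: node {bad} stretch "
                    f"{lam[bad]:.3f} outside [{lam_lo}, {lam_hi}] "
                    f"(p_chamber={circ.p_chamber:.0f} Pa)")

            V_new = chamber_volume(_node_positions(r, params))
            circ = circulation_step(circ, (V_new - V_old) / dt, dt,
                                    cfg.circulation, wall_admittance=A_w)
            V_old = V_new

    # resample the recorded cycle onto n_out uniform phase points
    rec_t_arr = np.asarray(rec_t)
    n_out = cfg.wall.n_out
    t_out = np.arange(n_out) * (T / n_out)
    r_arr = np.asarray(rec_r)                          # (S, N)
    node_tr = np.empty((n_out, n_nodes, 2))
    r_out = np.empty((n_out, n_nodes))
    for i in range(n_nodes):
        r_out[:, i] = np.interp(t_out, rec_t_arr, r_arr[:, i])
    node_tr[:, :, 0] = r_out * np.cos(params.theta)
    node_tr[:, :, 1] = -r_out * np.sin(params.theta)

    def _interp(a):
        return np.interp(t_out, rec_t_arr, np.asarray(a))

    return MechResult(
        times=t_out, node_xy=node_tr,
        p_chamber=_interp(rec_p), p_inlet=_interp(rec_pa),
        p_outlet=_interp(rec_part), V=_interp(rec_V),
        Q_mv=_interp(rec_Qm), Q_ao=_interp(rec_Qa),
        cycle_index=last_cycle, geom=geom, T_cycle=T)
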