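"""2D incompressible ALE finite-volume solver on the moving chamber grid.

The scheme is a non-incremental pressure projection with explicit upwind
convection, explicit viscous diffusion, and an implicit (pointwise) porous
valve force:

1.  Convective fluxes use the velocity relative to the mesh,
    phi_f = U_f - Vdot_mesh,f, with the mesh flux obtained from the exact
    volume swept by each face between time levels.  Summed over a cell the
    swept volumes reproduce the cell volume change identically, which is
    the discrete geometric conservation law: a uniform velocity field is
    preserved to machine precision under arbitrary mesh motion.
2.  Wall faces carry exactly the mesh flux (no flow relative to the wall),
    so the advected scalar is conserved to round-off on closed domains.
3.  The pressure Poisson equation enforces sum_f U_f = 0 per cell (div u
    = 0; the mesh-motion part of the ALE balance is carried by the swept
    volumes).  Dirichlet pressures act on the port end faces; closed
    domains pin one cell.  Porous cells scale their flux corrections by
    beta = 1/(1 + dt (a + b |u_rel|)), the same factor that implicitly
    damps their momentum, so a blocked valve resists the projection too.
4.  The valve force is the Darcy-Forchheimer drag
    F_p = -(phi mu)/(rho k_p L^2) u_rel - 1.75 phi / sqrt(150 k_p L^2)
          |u_rel| u_rel,
    with the dimensionless permeability k_p ramped between k_min (blocked,
    |Vdot| < 20 ml/s) and 1 (open, |Vdot| > 160 ml/s) by the instantaneous
    chamber volume-flux magnitude; L is the valve-zone depth, making
    k_p L^2 a dimensional permeability.
5.  Scalar transport (washout tracking) is first-order upwind in the same
    ALE flux form: bounded in [0, 1] under the CFL condition and exactly
    conservative up to boundary fluxes.

Time steps adapt to CFL <= 0.7 on the relative velocity, growth-limited to
1.2x per step, additionally bounded by the explicit diffusion limit and a
resolution cap dt_max; the first step is dt0 = 1 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError, StabilityError
from .geometry import (BASE, FluidMesh, INLET, OUTLET, PORT_WALL,
                       VELOCITY, WALL, cell_centroids, cell_volumes,
                       face_vectors, swept_face_volumes)

__all__ = [
    "FluidParams",
    "ValveConfig",
    "FluidState",
    "WallPressureField",
    "FluidRunResult",
    "valve_permeability",
    "valve_forcing",
    "cfl_timestep",
    "init_scalar",
    "AleSolver",
    "run_fluid",
]

_WALL_TYPES = (WALL, BASE, PORT_WALL)
_PRESSURE_TYPES = (INLET, OUTLET)


@dataclass(frozen=True)
class FluidParams:
    """Blood and discretization constants."""

    rho: float = 1055.0      # density (kg/m^3)
    mu: float = 0.004        # dynamic viscosity (kg/m/s)
    D: float = 1e-10         # scalar diffusivity (m^2/s)
    cfl_max: float = 0.7
    dt0: float = 1e-3        # initial step (s)
    dt_min: float = 1e-6
    dt_max: float = 5e-3

    def __post_init__(self):
        if min(self.rho, self.mu, self.D, self.cfl_max, self.dt0) <= 0:
            raise ConfigurationError("fluid parameters must be positive")
        if self.cfl_max > 1.0:
            raise ConfigurationError("cfl_max must be <= 1")

    @classmethod
    def from_config(cls, fc) -> "FluidParams":
        return cls(rho=fc.rho, mu=fc.mu, D=fc.D, cfl_max=fc.cfl_max,
                   dt0=fc.dt0, dt_min=fc.dt_min, dt_max=fc.dt_max)


@dataclass(frozen=True)
class ValveConfig:
    """Flux-dependent permeability ramp of the porous valve planes."""

    q_lo: float = 20.0       # blocked below this |Vdot| (ml/s)
    q_hi: float = 160.0      # fully open above this (ml/s)
    k_min: float = 1e-7      # blocked dimensionless permeability
    phi: float = 1.0         # porosity (kept at 1)

    def __post_init__(self):
        if not (0 < self.q_lo < self.q_hi):
            raise ConfigurationError("need 0 < q_lo < q_hi")
        if not (0 < self.k_min < 1):
            raise ConfigurationError("k_min must be in (0, 1)")

    @classmethod
    def from_config(cls, vc) -> "ValveConfig":
        return cls(q_lo=vc.q_lo, q_hi=vc.q_hi, k_min=vc.k_min, phi=vc.phi)


@dataclass
class FluidState:
    u: np.ndarray            # (C, 2) cell velocity (m/s)
    p: np.ndarray            # (C,) pressure (Pa)
    psi: np.ndarray          # (C,) scalar concentration in [0, 1]
    c_mesh: np.ndarray       # (C, 2) mesh velocity (m/s)
    t: float = 0.0
    dt: float = 0.0
    face_flux: np.ndarray | None = None   # (F,) corrected volume fluxes
    div_residual: float = 0.0             # scaled post-projection divergence


@dataclass
class WallPressureField:
    """Wall-adjacent cell pressure per wall segment on one cycle of phase
    samples: complete coverage of all segments at every stored time."""

    times: np.ndarray        # (T,) cycle phase (s)
    p: np.ndarray            # (T, E) Pa

    def __post_init__(self):
        if self.p.ndim != 2 or self.p.shape[0] != self.times.size:
            raise ConfigurationError("wall pressure must be (n_times, n_elements)")
        if not np.all(np.isfinite(self.p)):
            raise ConfigurationError("wall pressure has gaps (non-finite entries)")


@dataclass
class FluidRunResult:
    times: np.ndarray                 # (T,) last-cycle phase grid (s)
    wall_pressure: np.ndarray         # (T, E) Pa, last cycle
    residual_times: np.ndarray        # (S,) absolute time (s)
    residual_volume_ml: np.ndarray    # (S,)
    wall_pressure_cycles: np.ndarray | None = None   # (n_cycles, T, E)
    state: FluidState | None = None
    n_steps: int = 0

    @property
    def wall_pressure_field(self) -> WallPressureField:
        return WallPressureField(times=self.times, p=self.wall_pressure)


# ---------------------------------------------------------------------------
# valve law
# ---------------------------------------------------------------------------

def valve_permeability(q_abs: float, cfg: ValveConfig) -> float:
    """Dimensionless valve permeability for a volume-flux magnitude (ml/s).

    k_min below q_lo, 1 above q_hi, linear and continuous in between; the
    same single curve applies during opening and closing (no hysteresis).
    """
    if q_abs < 0:
        raise ConfigurationError("flux magnitude must be non-negative")
    if q_abs <= cfg.q_lo:
        return cfg.k_min
    if q_abs >= cfg.q_hi:
        return 1.0
    return cfg.k_min + (1.0 - cfg.k_min) * (q_abs - cfg.q_lo) / (cfg.q_hi - cfg.q_lo)


def valve_forcing(u_rel: np.ndarray, k_p: float, cfg: ValveConfig,
                  params: FluidParams, L_ref: float) -> np.ndarray:
    """Darcy-Forchheimer body force per unit mass (m/s^2) opposing u_rel."""
    if k_p <= 0:
        raise ConfigurationError("permeability must be positive")
    u_rel = np.asarray(u_rel, dtype=float)
    mag = np.linalg.norm(u_rel, axis=-1, keepdims=True) \
        if u_rel.ndim > 1 else np.linalg.norm(u_rel)
    a = cfg.phi * params.mu / (params.rho * k_p * L_ref ** 2)
    b = 1.75 * cfg.phi / math.sqrt(150.0 * k_p * L_ref ** 2)
    return -(a + b * mag) * u_rel


def _darcy_coeffs(k_p: float, cfg: ValveConfig, params: FluidParams,
                  L_ref: float) -> tuple[float, float]:
    a = cfg.phi * params.mu / (params.rho * k_p * L_ref ** 2)
    b = 1.75 * cfg.phi / math.sqrt(150.0 * k_p * L_ref ** 2)
    return a, b


def cfl_timestep(state: FluidState, mesh: FluidMesh, params: FluidParams,
                 node_xy: np.ndarray | None = None) -> float:
    """Next time step: CFL bound on |u - c_mesh| with sqrt(cell volume) as
    the length scale, the explicit-diffusion bound, a 1.2x growth limit, and
    the dt_max resolution cap.  Returns dt0 before the first step."""
    if state.dt <= 0.0:
        return params.dt0
    vol = cell_volumes(mesh, node_xy)
    # flux-based Courant number: the advective crossing length of a cell is
    # V_c / (half the summed |u_rel . S_f|), which stays correct for the
    # strongly anisotropic cells near the fan center
    sf, _ = face_vectors(mesh, node_xy)
    u_rel = state.u - state.c_mesh
    owner = mesh.face_owner
    neigh = mesh.face_neigh
    imask = neigh >= 0
    u_face = u_rel[owner].copy()
    u_face[imask] = 0.5 * (u_rel[owner[imask]] + u_rel[neigh[imask]])
    fmag = np.abs(np.einsum("ij,ij->i", u_face, sf))
    out = np.zeros(mesh.n_cells)
    np.add.at(out, owner, fmag)
    np.add.at(out, neigh[imask], fmag[imask])
    out *= 0.5
    with np.errstate(divide="ignore"):
        dt_cfl = float(np.min(np.where(out > 0, params.cfl_max * vol / out,
                                       np.inf)))
    # explicit-diffusion bound on the smallest face-to-face spacing
    area = np.linalg.norm(sf, axis=1)
    dmin = np.zeros(mesh.n_cells) + np.inf
    np.minimum.at(dmin, owner, vol[owner] / np.maximum(area, 1e-30))
    np.minimum.at(dmin, neigh[imask], vol[neigh[imask]] / area[imask])
    dt_visc = 0.25 * params.rho * float(np.min(dmin) ** 2) / params.mu
    dt = min(dt_cfl, dt_visc, 1.2 * state.dt, params.dt_max)
    if dt < params.dt_min:
        raise StabilityError(
            f"time step collapsed to {dt:.2e} s (< {params.dt_min:.0e}); "
            "the flow has blown up")
    return dt


def init_scalar(mesh: FluidMesh) -> np.ndarray:
    """Washout marker: 1 in chamber cells, 0 in port cells."""
    region = mesh.cell_region
    if np.any((region < 0) | (region > 2)):
        raise ConfigurationError("mesh has unlabeled cells")
    return (region == 0).astype(float)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

class AleSolver:
    """Projection stepper bound to one mesh.

    The caller owns the motion policy: each :meth:`step` receives the node
    positions at the new time level.  Boundary data (bcs dict) may contain
    ``p_inlet``, ``p_outlet`` (Pa) and ``u_bc`` (m/s, for VELOCITY faces).
    """

    def __init__(self, mesh: FluidMesh, params: FluidParams,
                 valve_cfg: ValveConfig | None = None,
                 L_ref: float | None = None):
        self.mesh = mesh
        self.params = params
        self.valve_cfg = valve_cfg or ValveConfig()
        if L_ref is None:
            L_ref = mesh.geom.valve_zone_depth if mesh.geom is not None else 1.0
        self.L_ref = L_ref
        self.xy = mesh.node_xy0.copy()
        self._poisson_cache_key = None
        self._poisson_lu = None
        # per-cell Darcy maps built once
        self._valve_cells = {}
        for name in ("mitral", "aortic"):
            self._valve_cells[name] = mesh.valve_zone_cells.get(
                name, np.array([], dtype=np.int64))
        self.k_p = {"mitral": 1.0, "aortic": 1.0}
        owner = mesh.face_owner
        self._bmask = mesh.face_neigh < 0
        self._imask = ~self._bmask
        self._wall_face = np.isin(mesh.face_type, _WALL_TYPES)
        self._press_face = np.isin(mesh.face_type, _PRESSURE_TYPES)
        self._vel_face = mesh.face_type == VELOCITY
        # wall segment -> boundary face / owner cell map for pressure sampling
        ws = mesh.wall_segment_of_boundary_face
        sel = np.flatnonzero(ws >= 0)
        order = np.argsort(ws[sel])
        self.segment_faces = sel[order]
        self.segment_owner_cells = owner[self.segment_faces]

    def initial_state(self) -> FluidState:
        C = self.mesh.n_cells
        return FluidState(u=np.zeros((C, 2)), p=np.zeros(C),
                          psi=init_scalar(self.mesh), c_mesh=np.zeros((C, 2)),
                          t=0.0, dt=0.0,
                          face_flux=np.zeros(self.mesh.faces.shape[0]))

    def set_valve_state(self, vdot_m3s: float) -> None:
        """Update both valve permeabilities from the chamber volume rate:
        the mitral zone responds to filling (Vdot > 0), the aortic zone to
        ejection (Vdot < 0)."""
        q_ml = abs(vdot_m3s) * 1e6
        k_open = valve_permeability(q_ml, self.valve_cfg)
        if vdot_m3s > 0:
            self.k_p = {"mitral": k_open, "aortic": self.valve_cfg.k_min}
        elif vdot_m3s < 0:
            self.k_p = {"mitral": self.valve_cfg.k_min, "aortic": k_open}
        else:
            self.k_p = {"mitral": self.valve_cfg.k_min,
                        "aortic": self.valve_cfg.k_min}

    # -- internals ----------------------------------------------------------

    def _cell_darcy(self, dt: float, u: np.ndarray,
                    c_mesh: np.ndarray) -> np.ndarray:
        """Implicit damping factor beta_c = 1/(1 + dt(a + b |u_rel|))."""
        beta = np.ones(self.mesh.n_cells)
        for name in ("mitral", "aortic"):
            cells = self._valve_cells[name]
            if cells.size == 0:
                continue
            a, b = _darcy_coeffs(self.k_p[name], self.valve_cfg,
                                 self.params, self.L_ref)
            mag = np.linalg.norm(u[cells] - c_mesh[cells], axis=1)
            beta[cells] = 1.0 / (1.0 + dt * (a + b * mag))
        return beta

    def step(self, state: FluidState, dt: float, xy_new: np.ndarray,
             bcs: dict | None = None) -> FluidState:
        """Advance one time step to the mesh configuration ``xy_new``."""
        mesh, prm = self.mesh, self.params
        bcs = bcs or {}
        xy_old = self.xy
        V_old = cell_volumes(mesh, xy_old)
        V_new = cell_volumes(mesh, xy_new, check=True)
        sf, fmid = face_vectors(mesh, xy_new)
        cen = cell_centroids(mesh, xy_new)
        swept = swept_face_volumes(mesh, xy_old, xy_new)
        vmesh_f = swept / dt

        owner = mesh.face_owner
        neigh = mesh.face_neigh
        imask = self._imask

        # nodal and cell mesh velocities
        w_node = (xy_new - xy_old) / dt
        c_mesh = w_node[mesh.cells].mean(axis=1)

        # --- convective fluxes from the previous corrected face fluxes ---
        U_old = state.face_flux
        phi = U_old - vmesh_f
        phi = np.where(self._wall_face, 0.0, phi)

        # upwind face velocity (owner for outflow & boundaries, neighbour
        # for inflow across interior faces)
        u_face = state.u[owner].copy()
        take_nb = imask & (phi < 0)
        u_face[take_nb] = state.u[neigh[take_nb]]

        conv = np.zeros((mesh.n_cells, 2))
        fl = phi[:, None] * u_face
        np.add.at(conv, owner, fl)
        np.add.at(conv, neigh[imask], -fl[imask])

        # --- viscous fluxes (explicit, compact two-point) ---
        area = np.linalg.norm(sf, axis=1)
        d_pn = np.empty(mesh.faces.shape[0])
        d_pn[imask] = np.linalg.norm(cen[neigh[imask]] - cen[owner[imask]],
                                     axis=1)
        d_pn[self._bmask] = np.linalg.norm(fmid[self._bmask]
                                           - cen[owner[self._bmask]], axis=1)
        d_pn = np.maximum(d_pn, 1e-14)

        grad_u = np.zeros((mesh.faces.shape[0], 2))
        grad_u[imask] = (state.u[neigh[imask]] - state.u[owner[imask]]) \
            / d_pn[imask, None]
        # no-slip walls: fluid velocity equals the face (mesh) velocity
        wmask = self._wall_face
        uw = 0.5 * (w_node[mesh.faces[:, 0]] + w_node[mesh.faces[:, 1]])
        grad_u[wmask] = (uw[wmask] - state.u[owner[wmask]]) / d_pn[wmask, None]
        vmask = self._vel_face
        if np.any(vmask):
            u_bc = np.asarray(bcs.get("u_bc", (0.0, 0.0)), dtype=float)
            grad_u[vmask] = (u_bc - state.u[owner[vmask]]) / d_pn[vmask, None]
        # pressure (open) boundaries: zero-gradient velocity
        visc = np.zeros((mesh.n_cells, 2))
        vf = (prm.mu / prm.rho) * area[:, None] * grad_u
        np.add.at(visc, owner, vf)
        np.add.at(visc, neigh[imask], -vf[imask])

        # --- predictor ---
        u_star = (V_old[:, None] * state.u + dt * (-conv + visc)) / V_new[:, None]
        beta = self._cell_darcy(dt, state.u, c_mesh)
        for name in ("mitral", "aortic"):
            cells = self._valve_cells[name]
            if cells.size:
                rel = u_star[cells] - c_mesh[cells]
                u_star[cells] = c_mesh[cells] + beta[cells, None] * rel

        # --- predictor face fluxes ---
        U_star = np.zeros(mesh.faces.shape[0])
        u_f_star = 0.5 * (u_star[owner] + u_star[np.where(imask, neigh, owner)])
        U_star[imask] = np.einsum("ij,ij->i", u_f_star[imask], sf[imask])
        U_star[wmask] = vmesh_f[wmask]
        if np.any(vmask):
            u_bc = np.asarray(bcs.get("u_bc", (0.0, 0.0)), dtype=float)
            U_star[vmask] = sf[vmask] @ u_bc
        pmask = self._press_face
        U_star[pmask] = np.einsum("ij,ij->i", u_star[owner[pmask]], sf[pmask])

        # --- pressure Poisson ---
        beta_f = np.ones(mesh.faces.shape[0])
        bo = beta[owner]
        bn = beta[np.where(imask, neigh, owner)]
        beta_f = 2.0 * bo * bn / (bo + bn)
        trans = beta_f * dt * area / (prm.rho * d_pn)

        div = np.zeros(mesh.n_cells)
        np.add.at(div, owner, U_star)
        np.add.at(div, neigh[imask], -U_star[imask])

        p_bc_face = np.zeros(mesh.faces.shape[0])
        if np.any(mesh.face_type == INLET):
            p_bc_face[mesh.face_type == INLET] = bcs.get("p_inlet", 0.0)
        if np.any(mesh.face_type == OUTLET):
            p_bc_face[mesh.face_type == OUTLET] = bcs.get("p_outlet", 0.0)

        p = self._solve_poisson(trans, div, p_bc_face, pmask, imask, owner,
                                neigh, xy_new)

        # --- flux and velocity correction ---
        U = U_star.copy()
        U[imask] -= trans[imask] * (p[neigh[imask]] - p[owner[imask]])
        U[pmask] -= trans[pmask] * (p_bc_face[pmask] - p[owner[pmask]])

        # velocity correction reconstructed from the face-flux corrections
        # (Gauss identity: sum_f dU_f (x_f - x_c) = V du for a linear
        # field).  Using the beta-weighted fluxes keeps cells next to a
        # blocked valve zone from seeing the full pressure jump across it.
        dU = U - U_star
        du = np.zeros((mesh.n_cells, 2))
        rel_o = fmid - cen[owner]
        np.add.at(du, owner, dU[:, None] * rel_o)
        rel_n = fmid[imask] - cen[neigh[imask]]
        np.add.at(du, neigh[imask], -dU[imask, None] * rel_n)
        u_new = u_star + du / V_new[:, None]

        # --- post-projection divergence check (scaled) ---
        res = np.zeros(mesh.n_cells)
        np.add.at(res, owner, U)
        np.add.at(res, neigh[imask], -U[imask])
        scale = max(float(np.max(np.abs(U))), 1e-30)
        div_residual = float(np.max(np.abs(res))) / scale

        # --- scalar transport ---
        psi_new = self._scalar_update(state.psi, U, vmesh_f, dt, V_old, V_new,
                                      area, d_pn, owner, neigh, imask)

        self.xy = xy_new.copy()
        return FluidState(u=u_new, p=p, psi=psi_new, c_mesh=c_mesh,
                          t=state.t + dt, dt=dt, face_flux=U,
                          div_residual=div_residual)

    def _solve_poisson(self, trans, div, p_bc_face, pmask, imask, owner,
                       neigh, xy_new):
        C = self.mesh.n_cells
        key = None
        if np.array_equal(xy_new, self.mesh.node_xy0):
            key = ("ref", self.k_p["mitral"], self.k_p["aortic"],
                   round(float(trans.sum()), 12))
        if key is None or key != self._poisson_cache_key:
            rows, cols, vals = [], [], []
            io = owner[imask]
            ine = neigh[imask]
            tv = trans[imask]
            rows.extend(io); cols.extend(io); vals.extend(tv)
            rows.extend(ine); cols.extend(ine); vals.extend(tv)
            rows.extend(io); cols.extend(ine); vals.extend(-tv)
            rows.extend(ine); cols.extend(io); vals.extend(-tv)
            po = owner[pmask]
            rows.extend(po); cols.extend(po); vals.extend(trans[pmask])
            A = sp.csc_matrix((vals, (rows, cols)), shape=(C, C))
            if not np.any(pmask):      # closed domain: pin cell 0
                A = A.tolil()
                A[0, :] = 0.0
                A[0, 0] = 1.0
                A = A.tocsc()
            lu = spla.splu(A)
            if key is not None:
                self._poisson_cache_key = key
                self._poisson_lu = lu
        else:
            lu = self._poisson_lu
        # U = U* - T (p_nb - p_P) and sum_f U_f = 0 give A p = -div(U*)
        # plus the Dirichlet contributions on port end faces
        rhs = -div
        np.add.at(rhs, owner[pmask], trans[pmask] * p_bc_face[pmask])
        if not np.any(pmask):
            rhs[0] = 0.0
        try:
            p = lu.solve(rhs)
        except Exception as e:  # pragma: no cover
            raise SolverError(f"pressure solve failed: {e}") from e
        if not np.all(np.isfinite(p)):
            raise SolverError("pressure solve produced non-finite values")
        return p

    def _scalar_update(self, psi, U, vmesh_f, dt, V_old, V_new, area, d_pn,
                       owner, neigh, imask):
        mesh, prm = self.mesh, self.params
        phi = U - vmesh_f
        phi = np.where(self._wall_face, 0.0, phi)
        psi_face = psi[owner].copy()
        take_nb = imask & (phi < 0)
        psi_face[take_nb] = psi[neigh[take_nb]]
        # boundary inflow carries fresh (psi = 0) fluid
        binflow = self._bmask & ~self._wall_face & (phi < 0)
        psi_face[binflow] = 0.0

        adv = np.zeros(mesh.n_cells)
        fl = phi * psi_face
        np.add.at(adv, owner, fl)
        np.add.at(adv, neigh[imask], -fl[imask])

        diff = np.zeros(mesh.n_cells)
        dfl = np.zeros_like(phi)
        dfl[imask] = prm.D * area[imask] * (psi[neigh[imask]]
                                            - psi[owner[imask]]) / d_pn[imask]
        np.add.at(diff, owner, dfl)
        np.add.at(diff, neigh[imask], -dfl[imask])

        return (psi * V_old - dt * adv + dt * diff) / V_new


# ---------------------------------------------------------------------------
# the fluid stage driver
# ---------------------------------------------------------------------------

def _periodic_interp(t: float, times: np.ndarray, values: np.ndarray,
                     T_cycle: float):
    """Linear interpolation in cycle phase with wrap-around; values may be
    (T,), (T, N) or (T, N, 2)."""
    phase = float(np.mod(t, T_cycle))
    j = int(np.searchsorted(times, phase, side="right") - 1)
    j = max(j, 0)
    if j >= times.size - 1:
        t0, t1 = times[-1], times[0] + T_cycle
        v0, v1 = values[-1], values[0]
        if phase < t0:
            t0, t1 = times[-1] - T_cycle, times[0]
    else:
        t0, t1 = times[j], times[j + 1]
        v0, v1 = values[j], values[j + 1]
    if t1 == t0:
        return v0
    w = (phase - t0) / (t1 - t0)
    return v0 + w * (v1 - v0)


def _boundary_displacement(mesh: FluidMesh, wall_xy_t: np.ndarray) -> np.ndarray:
    """Dirichlet displacement data for the motion solve at one time level.

    Wall ring nodes follow the mechanics trace; base nodes outside the port
    spans slide along y = base_y proportionally between the (fixed) port
    edge and the moving base corner; port nodes and the origin stay fixed.
    """
    disp = np.zeros_like(mesh.node_xy0)
    ring = mesh.wall_ring_nodes
    disp[ring] = wall_xy_t - mesh.node_xy0[ring]
    for nodes, corner_idx in ((mesh.base_right_nodes, 0),
                              (mesh.base_left_nodes, -1)):
        if nodes is None or nodes.size < 3:
            continue
        x0 = mesh.node_xy0[nodes, 0]
        corner_x0 = x0[-1]
        corner_x1 = wall_xy_t[corner_idx, 0]
        # innermost fixed abscissa: outer edge of a port column if present,
        # else the origin
        x_fix = 0.0
        sgn = math.copysign(1.0, corner_x0)
        port_xs = [abs(x) for n, x in zip(nodes[:-1], x0[:-1])
                   if _node_in_port(mesh, n)]
        if port_xs:
            x_fix = max(port_xs)
        denom = abs(corner_x0) - x_fix
        if denom <= 0:
            continue
        for n, x in zip(nodes[:-1], x0[:-1]):
            ax = abs(x)
            if ax <= x_fix + 1e-15:
                continue
            new_ax = x_fix + (ax - x_fix) * (abs(corner_x1) - x_fix) / denom
            disp[n, 0] = sgn * new_ax - x
    return disp


def _node_in_port(mesh: FluidMesh, node: int) -> bool:
    if not hasattr(mesh, "_port_node_set"):
        port_cells = np.flatnonzero(mesh.cell_region > 0)
        mesh._port_node_set = set(mesh.cells[port_cells].ravel().tolist())
    return int(node) in mesh._port_node_set


def run_fluid(mech, cfg, n_cycles: int | None = None,
              outdir=None, vtk_every: int = 0) -> FluidRunResult:
    """Replay one mechanics cycle periodically and integrate the flow.

    ``mech`` is a :class:`~cardioloop.mechanics.MechResult` covering exactly
    one cycle; its wall motion drives the mesh, its inlet/outlet pressure
    traces provide the Dirichlet port pressures, and the wall starts at the
    phase-zero configuration with the fluid at rest.  After ``n_cycles``
    (default ``cfg.coupling.n_fluid_cycles``) the wall-adjacent cell
    pressures of the last cycle are returned per wall segment on the
    mechanics sampling grid, together with the residual-volume washout
    trace.
    """
    from .mechanics import chamber_volume

    if n_cycles is None:
        n_cycles = cfg.coupling.n_fluid_cycles
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    from .geometry import build_grid

    geom = mech.geom
    mesh = build_grid(geom, cfg.geometry.n_r)
    params = FluidParams.from_config(cfg.fluid)
    vcfg = ValveConfig.from_config(cfg.valve)
    solver = AleSolver(mesh, params, vcfg)

    T = mech.T_cycle
    times = mech.times
    wall_tr = mech.node_xy           # (T, Nw, 2)

    # start from the phase-0 wall configuration
    disp0 = _boundary_displacement(mesh, _periodic_interp(0.0, times, wall_tr, T))
    from .geometry import solve_mesh_motion
    d_prev = solve_mesh_motion(mesh, disp0)
    solver.xy = mesh.node_xy0 + d_prev

    state = solver.initial_state()
    t_end = n_cycles * T
    last_start = (n_cycles - 1) * T

    res_t: list[float] = []
    res_v: list[float] = []
    samp_t: list[float] = []          # absolute time of each sample
    samp_p: list[np.ndarray] = []

    from .diagnostics import residual_volume
    res_t.append(0.0)
    res_v.append(residual_volume(state.psi, mesh, solver.xy))

    writer = None
    if outdir is not None and vtk_every:
        from . import io as cio
        writer = cio.VtkSeriesWriter(outdir, mesh)

    n_steps = 0
    t = 0.0
    while t < t_end - 1e-12:
        dt = cfl_timestep(state, mesh, params, solver.xy)
        dt = min(dt, t_end - t)
        t_new = t + dt

        wall_next = _periodic_interp(t_new, times, wall_tr, T)
        disp = _boundary_displacement(mesh, wall_next)
        d_new = solve_mesh_motion(mesh, disp, check=False)
        xy_new = mesh.node_xy0 + d_new

        # valve drive: prescribed chamber volume rate
        v_now = chamber_volume(_periodic_interp(t, times, wall_tr, T))
        v_next = chamber_volume(wall_next)
        solver.set_valve_state((v_next - v_now) / dt)

        bcs = {
            "p_inlet": float(_periodic_interp(t_new, times, mech.p_inlet, T)),
            "p_outlet": float(_periodic_interp(t_new, times, mech.p_outlet, T)),
        }
        state = solver.step(state, dt, xy_new, bcs)
        t = t_new
        n_steps += 1

        res_t.append(t)
        res_v.append(residual_volume(state.psi, mesh, solver.xy))
        samp_t.append(t)
        samp_p.append(state.p[solver.segment_owner_cells].copy())
        if writer is not None and n_steps % vtk_every == 0:
            writer.write(n_steps, solver.xy, state)

    # resample wall pressures of every cycle onto the shared phase grid
    samp_t_arr = np.asarray(samp_t)
    samp_p_arr = np.asarray(samp_p)            # (S, E)
    E = samp_p_arr.shape[1]
    wp_cycles = np.empty((n_cycles, times.size, E))
    for c in range(n_cycles):
        tq = times + c * T
        for e in range(E):
            wp_cycles[c, :, e] = np.interp(tq, samp_t_arr, samp_p_arr[:, e])
    return FluidRunResult(
        times=times.copy(), wall_pressure=wp_cycles[-1],
        residual_times=np.asarray(res_t),
        residual_volume_ml=np.asarray(res_v),
        wall_pressure_cycles=wp_cycles,
        state=state, n_steps=n_steps)
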