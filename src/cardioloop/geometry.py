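"""Idealized chamber geometry and the boundary-fitted moving fluid grid.

The chamber is a 2D half-ellipse (unit depth): base plane at y = 0, apex at
y = -L, wall parameterized by theta in [0, pi] running from the base-right
corner through the apex to the base-left corner.  Wall node i sits at
``r0[i] * (cos(theta[i]), -sin(theta[i]))``.  Two straight port tubes (mitral
inlet on the left half of the base, aortic outlet on the right half) attach
at the base and extend upward; their outer ends carry pressure boundary
conditions and their first few cell rows form the porous valve zones.

The fluid grid is a fan of n_r x n_theta cells inside the chamber (triangles
in the innermost ring, quadrilaterals elsewhere) stitched node-exactly to
Cartesian blocks inside the ports.  All solver-facing data are flat arrays:
cells as node quadruples (triangles repeat a node), faces as directed node
pairs with owner/neighbour cells, per-face boundary types, and the map from
wall boundary faces to chamber wall segments.  Node and cell indices are
fixed at build time and never change during a study, which is what makes
node-wise displacement comparisons between coupling iterations meaningful.

Mesh motion is a Laplace problem per displacement component with a
"quadratic" (inverse squared wall distance) diffusivity: boundary nodes are
Dirichlet data, interior chamber nodes are solved for.  The operator is
assembled once on the reference configuration and factorized, so a motion
solve during time stepping is two triangular solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, MeshError

__all__ = [
    "ChamberGeometry",
    "FluidMesh",
    "make_chamber",
    "build_grid",
    "build_box_grid",
    "solve_mesh_motion",
    "cell_volumes",
    "face_vectors",
    "swept_face_volumes",
    "INTERIOR",
    "WALL",
    "BASE",
    "PORT_WALL",
    "INLET",
    "OUTLET",
    "VELOCITY",
]

# face type codes
INTERIOR = 0   # internal face between two cells
WALL = 1       # moving chamber wall (no-slip, flux = mesh flux)
BASE = 2       # base plane outside the ports (static/sliding wall)
PORT_WALL = 3  # static port side wall
INLET = 4      # mitral port outer end, Dirichlet pressure
OUTLET = 5     # aortic port outer end, Dirichlet pressure
VELOCITY = 6   # prescribed-velocity boundary (verification cases)

_WALL_LIKE = (WALL, BASE, PORT_WALL)


@dataclass(frozen=True)
class ChamberGeometry:
    """Parametric 2D chamber boundary with optional port spans.

    theta, r0 are per-boundary-node arrays (n_seg + 1 nodes); h0 is the
    reference wall thickness (m).  Port spans are signed fractions of the
    base half-width: the outlet (aortic) span lies on the positive-x half,
    the inlet (mitral) span on the negative-x half, so the two are disjoint
    by construction and validated anyway.
    """

    n_seg: int
    theta: np.ndarray
    r0: np.ndarray
    h0: float
    base_y: float = 0.0
    inlet_span: tuple[float, float] | None = None
    outlet_span: tuple[float, float] | None = None
    valve_zone_depth: float = 0.006
    port_length_factor: float = 4.0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        r0 = np.asarray(self.r0, dtype=float)
        if theta.shape != (self.n_seg + 1,) or r0.shape != (self.n_seg + 1,):
            raise ConfigurationError("theta and r0 must have n_seg + 1 entries")
        if np.any(np.diff(theta) <= 0):
            raise ConfigurationError("theta must be strictly increasing")
        if np.any(r0 <= 0):
            raise ConfigurationError("all reference radii must be positive")
        if self.h0 <= 0:
            raise ConfigurationError("wall thickness h0 must be positive")
        for name, span in (("inlet_span", self.inlet_span),
                           ("outlet_span", self.outlet_span)):
            if span is None:
                continue
            lo, hi = span
            if not (lo < hi):
                raise ConfigurationError(f"{name} must satisfy lo < hi")
            if max(abs(lo), abs(hi)) >= 1.0 or min(abs(lo), abs(hi)) <= 0.0:
                raise ConfigurationError(
                    f"{name} must lie strictly inside the base half-width")
            if lo * hi <= 0:
                raise ConfigurationError(f"{name} must not straddle the apex axis")
        if self.inlet_span is not None and self.outlet_span is not None:
            a, b = sorted([self.inlet_span, self.outlet_span])
            if a[1] >= b[0]:
                raise ConfigurationError("inlet and outlet spans overlap")
            if self.inlet_span[0] >= 0 or self.outlet_span[0] <= 0:
                raise ConfigurationError(
                    "inlet span must lie on x<0, outlet span on x>0")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "r0", r0)

    # -- derived quantities -------------------------------------------------

    def wall_nodes(self) -> np.ndarray:
        """Reference wall node coordinates, shape (n_seg + 1, 2)."""
        return np.column_stack(
            [self.r0 * np.cos(self.theta),
             self.base_y - self.r0 * np.sin(self.theta)])

    def enclosed_volume(self) -> float:
        """Chamber volume (m^3 at unit depth): shoelace area of the wall
        polygon closed by the straight base chord."""
        xy = self.wall_nodes()
        x, y = xy[:, 0], xy[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return float(abs(area))


def make_chamber(R: float = 0.025, L: float = 0.07, h0: float = 0.01,
                 n_seg: int = 64,
                 inlet_span: tuple[float, float] | None = (-0.625, -0.25),
                 outlet_span: tuple[float, float] | None = (0.25, 0.5),
                 valve_zone_depth: float = 0.006,
                 port_length_factor: float = 4.0) -> ChamberGeometry:
    """Half-ellipse chamber with semi-axes R (base half-width) and L (apex
    depth) and two straight port tubes at the base.

    The wall is sampled at n_seg + 1 equispaced parameter values; the polar
    radius of the ellipse is r0(theta) = R L / sqrt((L cos)^2 + (R sin)^2).
    Pass ``inlet_span=None, outlet_span=None`` for a closed chamber.
    """
    if n_seg < 16:
        raise ConfigurationError("need at least 16 wall segments")
    if R <= 0 or L <= 0 or h0 <= 0:
        raise ConfigurationError("R, L, h0 must all be positive")
    theta = np.linspace(0.0, math.pi, n_seg + 1)
    r0 = R * L / np.sqrt((L * np.cos(theta)) ** 2 + (R * np.sin(theta)) ** 2)
    return ChamberGeometry(
        n_seg=n_seg, theta=theta, r0=r0, h0=h0,
        inlet_span=inlet_span, outlet_span=outlet_span,
        valve_zone_depth=valve_zone_depth,
        port_length_factor=port_length_factor)


# ---------------------------------------------------------------------------
# mesh container and elementary geometry kernels
# ---------------------------------------------------------------------------

@dataclass
class FluidMesh:
    """Polygonal finite-volume mesh with fixed connectivity.

    cells hold 4 node ids each (triangles repeat the first id).  faces are
    directed node pairs ordered so the outward normal of the owner cell is
    ``(dy, -dx)`` of the edge vector.  ``face_neigh`` is -1 on the boundary.
    """

    node_xy0: np.ndarray                 # (N, 2) reference node positions
    cells: np.ndarray                    # (C, 4) int
    faces: np.ndarray                    # (F, 2) int, owner-CCW order
    face_owner: np.ndarray               # (F,) int
    face_neigh: np.ndarray               # (F,) int, -1 on boundary
    face_type: np.ndarray                # (F,) int, codes above
    cell_region: np.ndarray              # (C,) 0 chamber, 1 mitral, 2 aortic
    wall_segment_of_boundary_face: np.ndarray   # (F,) int, -1 if not wall
    valve_zone_cells: dict[str, np.ndarray]
    geom: ChamberGeometry | None = None
    n_r: int = 0
    n_theta: int = 0
    wall_ring_nodes: np.ndarray | None = None    # (n_seg + 1,) node ids
    base_right_nodes: np.ndarray | None = None   # node ids k = 0..n_r (origin first)
    base_left_nodes: np.ndarray | None = None
    dirichlet_nodes: np.ndarray | None = None    # bool mask (N,)
    wall_distance: np.ndarray | None = None      # (N,) distance to moving wall
    _motion: "_MeshMotionSolver | None" = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_xy0.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def n_chamber_cells(self) -> int:
        return int(np.sum(self.cell_region == 0))

    @property
    def chamber_cells(self) -> np.ndarray:
        return np.flatnonzero(self.cell_region == 0)

    def motion_solver(self, delta_floor: float = 1e-3) -> "_MeshMotionSolver":
        if self._motion is None:
            self._motion = _MeshMotionSolver(self, delta_floor=delta_floor)
        return self._motion


def cell_volumes(mesh: FluidMesh, node_xy: np.ndarray | None = None,
                 check: bool = False) -> np.ndarray:
    """Cell areas x unit depth (m^3) by the shoelace formula.

    With ``check=True`` raises :class:`MeshError` naming the first
    non-positive cell (tangled mesh).
    """
    xy = mesh.node_xy0 if node_xy is None else node_xy
    px = xy[mesh.cells, 0]          # (C, 4)
    py = xy[mesh.cells, 1]
    qx = np.roll(px, -1, axis=1)
    qy = np.roll(py, -1, axis=1)
    vol = 0.5 * np.sum(px * qy - qx * py, axis=1)
    if check and np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise MeshError(f"non-positive volume in cell {bad}: {vol[bad]:.3e}")
    return vol


def cell_centroids(mesh: FluidMesh, node_xy: np.ndarray | None = None) -> np.ndarray:
    """Vertex-mean cell centers (adequate for the compact FV stencils used)."""
    xy = mesh.node_xy0 if node_xy is None else node_xy
    pts = xy[mesh.cells]                         # (C, 4, 2)
    # triangles repeat the first node; a plain vertex mean would double-count
    # it, so weight unique vertices only.
    first = mesh.cells[:, :1]
    dup = (mesh.cells == first) & (np.arange(4) > 0)
    w = np.where(dup, 0.0, 1.0)[:, :, None]
    return (pts * w).sum(axis=1) / w.sum(axis=1)


def face_vectors(mesh: FluidMesh, node_xy: np.ndarray | None = None):
    """Outward (owner-side) face normal vectors S_f with |S_f| = face length,
    plus face midpoints."""
    xy = mesh.node_xy0 if node_xy is None else node_xy
    a = xy[mesh.faces[:, 0]]
    b = xy[mesh.faces[:, 1]]
    d = b - a
    sf = np.column_stack([d[:, 1], -d[:, 0]])
    mid = 0.5 * (a + b)
    return sf, mid


def swept_face_volumes(mesh: FluidMesh, xy_old: np.ndarray,
                       xy_new: np.ndarray) -> np.ndarray:
    """Signed volume swept by each face between two time levels, positive
    when the face moves along the owner's outward normal.

    Discrete geometric conservation: for every cell,
    sum_f sign * swept_f == V_new - V_old to machine precision.
    """
    a0 = xy_old[mesh.faces[:, 0]]
    b0 = xy_old[mesh.faces[:, 1]]
    a1 = xy_new[mesh.faces[:, 0]]
    b1 = xy_new[mesh.faces[:, 1]]
    # polygon a0 -> b0 -> b1 -> a1; outward sweep = minus its shoelace area
    x = np.stack([a0[:, 0], b0[:, 0], b1[:, 0], a1[:, 0]], axis=1)
    y = np.stack([a0[:, 1], b0[:, 1], b1[:, 1], a1[:, 1]], axis=1)
    qx = np.roll(x, -1, axis=1)
    qy = np.roll(y, -1, axis=1)
    return -0.5 * np.sum(x * qy - qx * y, axis=1)


# ---------------------------------------------------------------------------
# grid builders
# ---------------------------------------------------------------------------

def _orient_cells_ccw(cells: np.ndarray, node_xy: np.ndarray) -> np.ndarray:
    px = node_xy[cells, 0]
    py = node_xy[cells, 1]
    area = 0.5 * np.sum(px * np.roll(py, -1, axis=1)
                        - np.roll(px, -1, axis=1) * py, axis=1)
    flipped = cells.copy()
    flip = area < 0
    flipped[flip] = cells[flip][:, ::-1]
    return flipped


def _build_faces(cells: np.ndarray, node_xy: np.ndarray):
    """Derive the face list from CCW cells; orient each stored face so that
    (dy, -dx) of its edge vector is the owner's outward normal."""
    edge_map: dict[tuple[int, int], list] = {}
    for c in range(cells.shape[0]):
        nodes = cells[c]
        m = 4
        for i in range(m):
            a, b = int(nodes[i]), int(nodes[(i + 1) % m])
            if a == b:
                continue  # degenerate edge of a stored triangle
            key = (a, b) if a < b else (b, a)
            edge_map.setdefault(key, []).append((c, a, b))
    faces, owner, neigh = [], [], []
    for key, users in edge_map.items():
        if len(users) > 2:
            raise MeshError(f"face {key} shared by {len(users)} cells")
        c0, a, b = users[0]
        # CCW cell boundary: interior on the left of a->b, so (dy,-dx)
        # points outward of the owner already.
        faces.append((a, b))
        owner.append(c0)
        neigh.append(users[1][0] if len(users) == 2 else -1)
    return (np.asarray(faces, dtype=np.int64),
            np.asarray(owner, dtype=np.int64),
            np.asarray(neigh, dtype=np.int64))


def _span_to_columns(span: tuple[float, float], n_r: int, side: str) -> tuple[int, int]:
    lo, hi = sorted((abs(span[0]), abs(span[1])))
    ka = int(round(lo * n_r))
    kb = int(round(hi * n_r))
    ka = max(ka, 1)
    kb = min(kb, n_r - 1)
    if kb <= ka:
        raise ConfigurationError(
            f"{side} span {span} collapses on an n_r={n_r} grid; widen the "
            "span or refine the grid")
    return ka, kb


def build_grid(geom: ChamberGeometry, n_r: int = 8) -> FluidMesh:
    """Boundary-fitted fan grid in the chamber plus Cartesian port blocks.

    The chamber fan has n_r rings by n_seg sectors (innermost ring collapses
    to triangles at the base-center origin).  Port columns are snapped to the
    base node positions of the fan so the blocks stitch node-exactly.
    """
    if n_r < 4:
        raise ConfigurationError("n_r must be at least 4")
    n_seg = geom.n_seg
    wall = geom.wall_nodes()

    # --- chamber nodes: origin + rings k = 1..n_r ---
    node_list = [np.array([0.0, geom.base_y])]
    ring_id = np.zeros((n_r + 1, n_seg + 1), dtype=np.int64)  # ring_id[0] = origin
    nid = 1
    for k in range(1, n_r + 1):
        frac = k / n_r
        for l in range(n_seg + 1):
            node_list.append(frac * wall[l])
            ring_id[k, l] = nid
            nid += 1
    ring_id[0, :] = 0

    cells = []
    region = []
    for k in range(n_r):
        for l in range(n_seg):
            if k == 0:
                cells.append([0, ring_id[1, l], ring_id[1, l + 1], 0])
            else:
                cells.append([ring_id[k, l], ring_id[k + 1, l],
                              ring_id[k + 1, l + 1], ring_id[k, l + 1]])
            region.append(0)

    # --- port blocks ---
    dr_right = geom.r0[0] / n_r
    dr_left = geom.r0[-1] / n_r
    port_meta = []  # (region_code, columns, n_y, node_id_grid)
    for side, span, code in (("right", geom.outlet_span, 2),
                             ("left", geom.inlet_span, 1)):
        if span is None:
            continue
        n_rad = n_r
        ka, kb = _span_to_columns(span, n_rad, side)
        if side == "right":
            xs = np.array([(k / n_r) * geom.r0[0] for k in range(ka, kb + 1)])
            base_ids = np.array([ring_id[k, 0] for k in range(ka, kb + 1)])
            dr = dr_right
        else:
            xs = np.array([-(k / n_r) * geom.r0[-1] for k in range(ka, kb + 1)])
            base_ids = np.array([ring_id[k, n_seg] for k in range(ka, kb + 1)])
            dr = dr_left
        width = abs(xs[-1] - xs[0])
        length = geom.port_length_factor * width
        n_y = max(2, int(math.ceil(length / dr)))
        dy = length / n_y
        ids = np.zeros((n_y + 1, xs.size), dtype=np.int64)
        ids[0] = base_ids
        for j in range(1, n_y + 1):
            for m in range(xs.size):
                node_list.append(np.array([xs[m], geom.base_y + j * dy]))
                ids[j, m] = nid
                nid += 1
        for j in range(n_y):
            for m in range(xs.size - 1):
                cells.append([ids[j, m], ids[j, m + 1],
                              ids[j + 1, m + 1], ids[j + 1, m]])
                region.append(code)
        port_meta.append((code, ids, dy))

    node_xy = np.asarray(node_list, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    region = np.asarray(region, dtype=np.int64)
    cells = _orient_cells_ccw(cells, node_xy)
    faces, owner, neigh = _build_faces(cells, node_xy)

    # --- classify boundary faces ---
    face_type = np.zeros(faces.shape[0], dtype=np.int64)
    wall_seg = np.full(faces.shape[0], -1, dtype=np.int64)
    wall_ring = ring_id[n_r]                          # outer ring node ids
    wall_rank = {int(wall_ring[l]): l for l in range(n_seg + 1)}
    port_end_ids = {}
    for code, ids, _dy in port_meta:
        port_end_ids[code] = set(int(i) for i in ids[-1])
    port_node_sets = {code: set(int(i) for i in ids.ravel())
                      for code, ids, _dy in port_meta}

    on_base = np.isclose(node_xy[:, 1], geom.base_y)
    for f in range(faces.shape[0]):
        if neigh[f] >= 0:
            continue
        a, b = int(faces[f, 0]), int(faces[f, 1])
        if a in wall_rank and b in wall_rank:
            face_type[f] = WALL
            wall_seg[f] = min(wall_rank[a], wall_rank[b])
            continue
        placed = False
        for code, ids, _dy in port_meta:
            if a in port_end_ids[code] and b in port_end_ids[code]:
                face_type[f] = INLET if code == 1 else OUTLET
                placed = True
                break
            if a in port_node_sets[code] and b in port_node_sets[code] \
                    and not (on_base[a] and on_base[b]):
                face_type[f] = PORT_WALL
                placed = True
                break
        if placed:
            continue
        if on_base[a] and on_base[b]:
            face_type[f] = BASE
        else:  # pragma: no cover - construction guarantees full coverage
            raise MeshError(f"unclassified boundary face {f} ({a}, {b})")

    # --- valve zones: port cells within valve_zone_depth of the base ---
    cen = np.zeros((cells.shape[0], 2))
    cen_tmp = node_xy[cells]
    cen = cen_tmp.mean(axis=1)
    valve = {}
    for name, code in (("mitral", 1), ("aortic", 2)):
        sel = np.flatnonzero(
            (region == code)
            & (cen[:, 1] - geom.base_y <= geom.valve_zone_depth))
        valve[name] = sel

    # --- node classification for the motion solve ---
    dirichlet = np.zeros(node_xy.shape[0], dtype=bool)
    dirichlet[0] = True
    dirichlet[wall_ring] = True
    dirichlet[ring_id[1:, 0]] = True          # base-right radial line
    dirichlet[ring_id[1:, n_seg]] = True      # base-left radial line
    for code, ids, _dy in port_meta:
        dirichlet[ids.ravel()] = True

    # distance to the moving wall along the fan ray (exact enough for the
    # diffusivity weighting); port/base nodes get their ring value.
    dist = np.zeros(node_xy.shape[0])
    dist[0] = float(np.mean(geom.r0))
    for k in range(1, n_r + 1):
        dist[ring_id[k]] = geom.r0 * (1.0 - k / n_r)
    for code, ids, _dy in port_meta:
        dist[ids.ravel()[ids.shape[1]:]] = geom.r0[0]  # far from the wall

    mesh = FluidMesh(
        node_xy0=node_xy, cells=cells, faces=faces, face_owner=owner,
        face_neigh=neigh, face_type=face_type, cell_region=region,
        wall_segment_of_boundary_face=wall_seg, valve_zone_cells=valve,
        geom=geom, n_r=n_r, n_theta=n_seg,
        wall_ring_nodes=wall_ring.copy(),
        base_right_nodes=ring_id[:, 0].copy(),
        base_left_nodes=ring_id[:, n_seg].copy(),
        dirichlet_nodes=dirichlet, wall_distance=dist)
    cell_volumes(mesh, check=True)
    return mesh


def build_box_grid(Lx: float, Ly: float, nx: int, ny: int,
                   bc: str = "closed") -> FluidMesh:
    """Rectangular verification mesh on [0,Lx] x [0,Ly].

    bc = "closed"   : all boundaries WALL (static)
    bc = "channel"  : x = 0 face INLET, x = Lx face OUTLET, rest WALL
    bc = "velocity" : all boundaries VELOCITY (free-stream / GCL tests)
    """
    xs = np.linspace(0.0, Lx, nx + 1)
    ys = np.linspace(0.0, Ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    node_xy = np.column_stack([X.ravel(), Y.ravel()])
    nid = np.arange(node_xy.shape[0]).reshape(nx + 1, ny + 1)
    cells = []
    for i in range(nx):
        for j in range(ny):
            cells.append([nid[i, j], nid[i + 1, j],
                          nid[i + 1, j + 1], nid[i, j + 1]])
    cells = _orient_cells_ccw(np.asarray(cells, dtype=np.int64), node_xy)
    faces, owner, neigh = _build_faces(cells, node_xy)
    face_type = np.zeros(faces.shape[0], dtype=np.int64)
    wall_seg = np.full(faces.shape[0], -1, dtype=np.int64)
    a = node_xy[faces[:, 0]]
    b = node_xy[faces[:, 1]]
    mid = 0.5 * (a + b)
    for f in range(faces.shape[0]):
        if neigh[f] >= 0:
            continue
        if bc == "velocity":
            face_type[f] = VELOCITY
        elif bc == "channel" and np.isclose(mid[f, 0], 0.0):
            face_type[f] = INLET
        elif bc == "channel" and np.isclose(mid[f, 0], Lx):
            face_type[f] = OUTLET
        else:
            face_type[f] = WALL
    boundary_nodes = np.zeros(node_xy.shape[0], dtype=bool)
    bmask = neigh < 0
    boundary_nodes[faces[bmask].ravel()] = True
    # wall distance: distance to the nearest boundary edge of the box
    d = np.minimum.reduce([node_xy[:, 0], Lx - node_xy[:, 0],
                           node_xy[:, 1], Ly - node_xy[:, 1]])
    return FluidMesh(
        node_xy0=node_xy, cells=cells, faces=faces, face_owner=owner,
        face_neigh=neigh, face_type=face_type,
        cell_region=np.zeros(cells.shape[0], dtype=np.int64),
        wall_segment_of_boundary_face=wall_seg,
        valve_zone_cells={"mitral": np.array([], dtype=np.int64),
                          "aortic": np.array([], dtype=np.int64)},
        geom=None, n_r=nx, n_theta=ny,
        dirichlet_nodes=boundary_nodes, wall_distance=d)


# ---------------------------------------------------------------------------
# mesh motion
# ---------------------------------------------------------------------------

class _MeshMotionSolver:
    """Prefactorized graph Laplacian with inverse-squared-distance diffusivity.

    Edge weights are the mean of the nodal diffusivities
    gamma = 1 / max(delta, delta_floor)^2 where delta is the distance to the
    moving wall; stiff cells near the wall then follow it almost rigidly
    while the far field absorbs the deformation.
    """

    def __init__(self, mesh: FluidMesh, delta_floor: float = 1e-3):
        if mesh.dirichlet_nodes is None or mesh.wall_distance is None:
            raise MeshError("mesh lacks motion metadata")
        n = mesh.n_nodes
        gamma = 1.0 / np.maximum(mesh.wall_distance, delta_floor) ** 2
        e = mesh.faces  # every face is a node-graph edge
        w = 0.5 * (gamma[e[:, 0]] + gamma[e[:, 1]])
        free = ~mesh.dirichlet_nodes
        self.free_idx = np.flatnonzero(free)
        self.n_free = self.free_idx.size
        pos = -np.ones(n, dtype=np.int64)
        pos[self.free_idx] = np.arange(self.n_free)

        rows, cols, vals = [], [], []
        rows_b, cols_b, vals_b = [], [], []
        for (i, j), wij in zip(e, w):
            for a, bnode in ((i, j), (j, i)):
                if not free[a]:
                    continue
                ra = pos[a]
                rows.append(ra); cols.append(ra); vals.append(wij)
                if free[bnode]:
                    rows.append(ra); cols.append(pos[bnode]); vals.append(-wij)
                else:
                    rows_b.append(ra); cols_b.append(bnode); vals_b.append(-wij)
        A = sp.csc_matrix((vals, (rows, cols)), shape=(self.n_free, self.n_free))
        self.B = sp.csr_matrix((vals_b, (rows_b, cols_b)), shape=(self.n_free, n))
        self.lu = spla.splu(A) if self.n_free else None
        self.dirichlet = mesh.dirichlet_nodes

    def solve(self, boundary_disp: np.ndarray) -> np.ndarray:
        """Full nodal displacement field from Dirichlet data.

        boundary_disp: (n_nodes, 2); only rows of Dirichlet nodes are read.
        """
        n = self.dirichlet.size
        out = np.zeros((n, 2))
        out[self.dirichlet] = boundary_disp[self.dirichlet]
        if self.lu is not None:
            rhs = -self.B @ out
            out[self.free_idx] = np.column_stack(
                [self.lu.solve(rhs[:, 0]), self.lu.solve(rhs[:, 1])])
        return out


def solve_mesh_motion(mesh: FluidMesh, wall_displacement: np.ndarray,
                      dt: float | None = None,
                      prev_displacement: np.ndarray | None = None,
                      delta_floor: float = 1e-3,
                      check: bool = True):
    """Interior mesh displacement (and optionally velocity) from boundary data.

    wall_displacement: (n_nodes, 2) array carrying the prescribed displacement
    of every Dirichlet (boundary/port) node; interior rows are ignored.
    Returns ``disp`` or ``(disp, vel)`` when ``dt`` is given, with
    ``vel = (disp - prev_displacement) / dt``.

    Raises :class:`MeshError` (with the offending cell) if the displaced mesh
    tangles.
    """
    if not np.all(np.isfinite(wall_displacement)):
        raise MeshError("non-finite wall displacement")
    disp = mesh.motion_solver(delta_floor).solve(np.asarray(wall_displacement, float))
    if check:
        cell_volumes(mesh, mesh.node_xy0 + disp, check=True)
    if dt is None:
        return disp
    prev = np.zeros_like(disp) if prev_displacement is None else prev_displacement
    return disp, (disp - prev) / dt
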