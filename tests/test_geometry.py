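"""Geometry, grid and mesh-motion tests: closed-form areas, quadrature
oracles, the swept-volume conservation identity, and Laplace properties."""

import math

import numpy as np
import pytest

from cardioloop.errors import ConfigurationError, MeshError
from cardioloop.geometry import (build_box_grid, build_grid, cell_volumes,
                                 make_chamber, solve_mesh_motion,
                                 swept_face_volumes)


class TestMakeChamber:
    def test_unit_half_disc_volume(self):
        g = make_chamber(R=1.0, L=1.0, n_seg=512, inlet_span=None,
                         outlet_span=None)
        assert g.enclosed_volume() == pytest.approx(math.pi / 2, rel=2e-4)

    def test_node_and_segment_counts(self):
        g = make_chamber(n_seg=64)
        assert g.theta.size == 65
        assert g.wall_nodes().shape == (65, 2)
        assert g.n_seg == 64

    def test_default_preset_volume_vs_quadrature(self):
        g = make_chamber()   # R = 25 mm, L = 70 mm
        # oracle: polar quadrature of the ellipse area, (1/2) int r^2 dtheta
        theta = np.linspace(0, math.pi, 20001)
        r = 0.025 * 0.07 / np.sqrt((0.07 * np.cos(theta)) ** 2
                                   + (0.025 * np.sin(theta)) ** 2)
        area = np.trapezoid(0.5 * r ** 2, theta)
        # the 64-segment polygon sits inside the smooth ellipse; its area
        # deficit is O(dtheta^2) ~ 0.13%
        assert g.enclosed_volume() == pytest.approx(area, rel=3e-3)

    def test_overlapping_spans_rejected(self):
        make_chamber(inlet_span=(-0.5, -0.2), outlet_span=(0.25, 0.5),
                     n_seg=32)   # disjoint spans are fine
        with pytest.raises(ConfigurationError):
            make_chamber(inlet_span=(0.2, 0.4), outlet_span=(0.3, 0.6))

    def test_span_on_wrong_side_rejected(self):
        with pytest.raises(ConfigurationError):
            make_chamber(inlet_span=(0.1, 0.2), outlet_span=(-0.5, -0.3))


class TestBuildGrid:
    def test_chamber_cell_count(self, default_geom):
        m = build_grid(default_geom, n_r=8)
        assert m.n_chamber_cells == 8 * 64

    def test_volume_sum_matches_quadrature(self):
        g = make_chamber()
        m = build_grid(g, n_r=32)
        vol = cell_volumes(m)
        chamber_vol = vol[m.chamber_cells].sum()
        assert chamber_vol == pytest.approx(g.enclosed_volume(), rel=1e-12)
        # and against the smooth ellipse area within 1%
        assert chamber_vol == pytest.approx(math.pi * 0.025 * 0.07 / 2,
                                            rel=0.01)

    def test_wall_faces_bijective_to_segments(self, default_mesh):
        ws = default_mesh.wall_segment_of_boundary_face
        segs = ws[ws >= 0]
        assert segs.size == default_mesh.geom.n_seg
        assert sorted(segs.tolist()) == list(range(default_mesh.geom.n_seg))

    def test_boundary_faces_tile_once(self, default_mesh):
        # every boundary face has exactly one owner and no neighbour
        b = default_mesh.face_neigh < 0
        assert np.all(default_mesh.face_type[b] > 0)
        assert np.all(default_mesh.face_type[~b] == 0)

    def test_valve_zones_inside_ports(self, default_mesh):
        for name, code in (("mitral", 1), ("aortic", 2)):
            cells = default_mesh.valve_zone_cells[name]
            assert cells.size > 0
            assert np.all(default_mesh.cell_region[cells] == code)

    def test_swept_volume_identity_random_motion(self, default_mesh):
        """Discrete geometric conservation: summed face sweeps equal the
        cell volume change for arbitrary node motion."""
        m = default_mesh
        rng = np.random.default_rng(7)
        xy1 = m.node_xy0 + 2e-4 * rng.standard_normal(m.node_xy0.shape)
        sw = swept_face_volumes(m, m.node_xy0, xy1)
        dv = np.zeros(m.n_cells)
        np.add.at(dv, m.face_owner, sw)
        interior = m.face_neigh >= 0
        np.add.at(dv, m.face_neigh[interior], -sw[interior])
        dv_direct = cell_volumes(m, xy1) - cell_volumes(m)
        assert np.max(np.abs(dv - dv_direct)) < 1e-18


class TestMeshMotion:
    def test_zero_boundary_data(self, default_mesh):
        d = solve_mesh_motion(default_mesh, np.zeros((default_mesh.n_nodes, 2)))
        assert np.all(d == 0.0)

    def test_uniform_translation_is_harmonic(self):
        # constants are in the kernel of the weighted graph Laplacian
        m = build_box_grid(1.0, 1.0, 10, 10)
        t = np.tile([0.003, -0.001], (m.n_nodes, 1))
        d = solve_mesh_motion(m, t, check=False)
        assert np.max(np.abs(d - t)) < 1e-12

    def test_linearity_in_boundary_data(self, default_mesh):
        m = default_mesh
        rng = np.random.default_rng(3)
        bd = np.zeros((m.n_nodes, 2))
        bd[m.dirichlet_nodes] = 1e-4 * rng.standard_normal(
            (int(m.dirichlet_nodes.sum()), 2))
        d1 = solve_mesh_motion(m, bd, check=False)
        d3 = solve_mesh_motion(m, 3.0 * bd, check=False)
        assert np.max(np.abs(d3 - 3.0 * d1)) < 1e-10

    def test_radial_contraction_vs_dense_solve(self):
        """5% contraction of a closed half-disc against a dense direct solve
        of the same discrete Laplacian."""
        g = make_chamber(R=1.0, L=1.0, n_seg=24, inlet_span=None,
                         outlet_span=None)
        m = build_grid(g, n_r=6)
        bd = np.zeros((m.n_nodes, 2))
        wn = m.wall_ring_nodes
        bd[wn] = -0.05 * m.node_xy0[wn]
        bd[m.base_right_nodes[:-1]] = -0.05 * m.node_xy0[
            m.base_right_nodes[:-1]]
        bd[m.base_left_nodes[:-1]] = -0.05 * m.node_xy0[m.base_left_nodes[:-1]]
        d = solve_mesh_motion(m, bd)

        # dense oracle: rebuild the weighted Laplacian explicitly
        gamma = 1.0 / np.maximum(m.wall_distance, 1e-3) ** 2
        n = m.n_nodes
        L = np.zeros((n, n))
        for (i, j) in m.faces:
            w = 0.5 * (gamma[i] + gamma[j])
            L[i, i] += w
            L[j, j] += w
            L[i, j] -= w
            L[j, i] -= w
        free = ~m.dirichlet_nodes
        expected = bd.copy()
        A = L[np.ix_(free, free)]
        B = L[np.ix_(free, ~free)]
        for c in range(2):
            expected[free, c] = np.linalg.solve(A, -B @ bd[~free, c])
        assert np.max(np.abs(d - expected)) < 1e-10

    def test_volumes_stay_positive_under_20pct_contraction(self, default_mesh):
        m = default_mesh
        bd = np.zeros((m.n_nodes, 2))
        wn = m.wall_ring_nodes
        bd[wn] = -0.20 * m.node_xy0[wn]
        d = solve_mesh_motion(m, bd)   # raises MeshError on tangling
        assert np.all(cell_volumes(m, m.node_xy0 + d) > 0)

    def test_tangling_raises_with_cell_index(self):
        m = build_box_grid(1.0, 1.0, 4, 4)
        bd = np.zeros((m.n_nodes, 2))
        # collapse one boundary edge far past its neighbour
        bd[m.dirichlet_nodes] = 0.0
        left = np.isclose(m.node_xy0[:, 0], 0.0)
        bd[left, 0] = 2.0
        with pytest.raises(MeshError):
            solve_mesh_motion(m, bd)

    def test_non_finite_displacement_rejected(self, default_mesh):
        bd = np.zeros((default_mesh.n_nodes, 2))
        bd[0, 0] = np.nan
        with pytest.raises(MeshError):
            solve_mesh_motion(default_mesh, bd)
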