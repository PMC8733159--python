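"""Wall-mechanics and circulation tests: equilibrium and symmetry of the
force balance, an independent RK4 oracle, diode/Windkessel behavior,
limit-cycle convergence, and the pressure-factor identity."""

import numpy as np
import pytest

from cardioloop.config import RunConfig
from cardioloop.coupling import PressureFactorField, build_pressure_factor_field
from cardioloop.errors import StabilityError
from cardioloop.geometry import make_chamber
from cardioloop.mechanics import (CirculationState, MechParams, WallState,
                                  chamber_volume, circulation_step,
                                  run_mechanics, segments_to_nodes, wall_rhs)


@pytest.fixture()
def ring_params():
    """Uniform ring: half-circle chamber, no activation (T_peak ~ 0)."""
    cfg = RunConfig()
    cfg.activation.T_peak = 1e-30
    cfg.wall.activation_taper = 0.0
    geom = make_chamber(R=0.025, L=0.025, n_seg=32, inlet_span=None,
                        outlet_span=None)
    return MechParams.from_config(cfg, geom), geom


class TestWallRhs:
    def test_equilibrium(self, ring_params):
        params, geom = ring_params
        n = geom.n_seg + 1
        st = WallState(r=geom.r0.copy(), v=np.zeros(n), t=0.0)
        a = wall_rhs(st, np.full(n, params.p_ext), 0.0, params)
        # only round-off from the polar-radius formula survives
        assert np.max(np.abs(a)) < 1e-9

    def test_uniform_overpressure_symmetric(self, ring_params):
        params, geom = ring_params
        n = geom.n_seg + 1
        st = WallState(r=geom.r0.copy(), v=np.zeros(n), t=0.0)
        a = wall_rhs(st, np.full(n, params.p_ext + 500.0), 0.0, params)
        assert np.all(a > 0)
        assert np.max(np.abs(a - a[0])) < 1e-9 * abs(a[0])

    def test_single_node_against_independent_rk4(self, ring_params):
        """A one-node chamber integrated by the solver's RHS must match a
        hand-rolled scalar RK4 using only the analytic force balance."""
        from cardioloop.materials import membrane_tension

        params, geom = ring_params
        n = geom.n_seg + 1
        dp = 300.0
        p = np.full(n, params.p_ext + dp)
        dt, steps = 1e-3, 400
        # vector solve (uniform -> every node behaves like the scalar ODE)
        r = geom.r0.copy()
        v = np.zeros(n)
        for k in range(steps):
            def acc(rr, vv):
                return wall_rhs(WallState(r=rr, v=vv, t=0.0), p, 0.0, params)
            k1v = acc(r, v); k1r = v
            k2v = acc(r + 0.5 * dt * k1r, v + 0.5 * dt * k1v); k2r = v + 0.5 * dt * k1v
            k3v = acc(r + 0.5 * dt * k2r, v + 0.5 * dt * k2v); k3r = v + 0.5 * dt * k2v
            k4v = acc(r + dt * k3r, v + dt * k3v); k4r = v + dt * k3v
            r = r + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
            v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)

        # scalar oracle (no neighbour/end effects for a uniform ring)
        r0s = float(geom.r0[0])
        rs, vs = r0s, 0.0
        for k in range(steps):
            def acc_s(rr, vv):
                lam = rr / r0s
                T = membrane_tension(lam, params.guccione, params.h0)
                return (dp - T / rr - params.c_damp * vv) / params.m_eff
            k1v = acc_s(rs, vs); k1r = vs
            k2v = acc_s(rs + 0.5 * dt * k1r, vs + 0.5 * dt * k1v); k2r = vs + 0.5 * dt * k1v
            k3v = acc_s(rs + 0.5 * dt * k2r, vs + 0.5 * dt * k2v); k3r = vs + 0.5 * dt * k2v
            k4v = acc_s(rs + dt * k3r, vs + dt * k3v); k4r = vs + dt * k3v
            rs = rs + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
            vs = vs + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        assert r[5] == pytest.approx(rs, rel=1e-12)

    def test_settles_to_static_equilibrium(self, ring_params):
        """With damping, zero activation and constant pressure the wall must
        come to rest."""
        params, geom = ring_params
        n = geom.n_seg + 1
        p = np.full(n, params.p_ext + 400.0)
        r, v = geom.r0.copy(), np.zeros(n)
        dt = 1e-3
        for k in range(3000):
            def acc(rr, vv):
                return wall_rhs(WallState(r=rr, v=vv, t=0.0), p, 0.0, params)
            k1v = acc(r, v); k1r = v
            k2v = acc(r + 0.5 * dt * k1r, v + 0.5 * dt * k1v); k2r = v + 0.5 * dt * k1v
            k3v = acc(r + 0.5 * dt * k2r, v + 0.5 * dt * k2v); k3r = v + 0.5 * dt * k2v
            k4v = acc(r + dt * k3r, v + dt * k3v); k4r = v + dt * k3v
            r = r + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
            v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        assert np.max(np.abs(v)) < 1e-8


class TestSegmentsToNodes:
    def test_adjacent_averaging(self):
        x = segments_to_nodes(np.array([1.0, 3.0, 5.0]))
        assert np.array_equal(x, [1.0, 2.0, 4.0, 5.0])

    def test_identity_field_exact(self):
        x = segments_to_nodes(np.ones(64))
        assert np.all(x == 1.0)


class TestCirculation:
    CFG = RunConfig().circulation

    def test_all_equal_pressures_unchanged(self):
        c = CirculationState(p_chamber=5e3, p_atrium=5e3, p_art=5e3, V=3e-3)
        c2 = circulation_step(c, 0.0, 1e-3, self.CFG)
        assert c2.p_chamber == pytest.approx(5e3)
        assert c2.Q_mv == 0.0 and c2.Q_ao == 0.0

    def test_isovolumetric_pressure_rise(self):
        """Closed valves, wall contracting at rate q: dp/dt -> K_c q / V in
        the rigid-chamber limit."""
        q = 1e-5
        V = 3e-3
        c = CirculationState(p_chamber=5e3, p_atrium=2e3, p_art=50e3, V=V)
        dt = 1e-6    # small step so the implicit update approaches the ODE
        c2 = circulation_step(c, -q, dt, self.CFG)
        dpdt = (c2.p_chamber - c.p_chamber) / dt
        assert dpdt == pytest.approx(self.CFG.K_c * q / V, rel=1e-6)

    def test_pressure_step_guard(self):
        c = CirculationState(p_chamber=5e3, p_atrium=2e3, p_art=50e3, V=3e-3)
        with pytest.raises(StabilityError):
            circulation_step(c, -1e-2, 0.1, self.CFG)

    def test_cycle_volume_balance(self, settled_mech):
        """Over a converged cycle the net valve throughput matches the wall
        volume change within 1% of the stroke volume."""
        m = settled_mech
        dt = np.gradient(m.times)
        net = float(np.sum((m.Q_mv - m.Q_ao) * dt))
        dV = float(m.V[-1] - m.V[0])
        stroke = float(m.V.max() - m.V.min())
        assert abs(net - dV) < 0.01 * stroke


class TestRunMechanics:
    def test_pf_identity_bitwise(self):
        """Applying the neutral factor x = 1 must reproduce the uncoupled
        run bit for bit."""
        cfg = RunConfig()
        base = run_mechanics(cfg, n_cycles=3)
        pf = PressureFactorField.identity(base.times, cfg.geometry.n_seg)
        mod = run_mechanics(cfg, n_cycles=3, pf=pf)
        assert np.array_equal(base.node_xy, mod.node_xy)
        assert np.array_equal(base.p_chamber, mod.p_chamber)
        assert np.array_equal(base.V, mod.V)

    def test_limit_cycle_reached(self, settled_mech):
        """Cycle 10 differs from cycle 9 by < 0.1 mm max displacement."""
        nine = run_mechanics(RunConfig(), n_cycles=9)
        d = np.linalg.norm(settled_mech.node_xy - nine.node_xy, axis=2)
        assert d.max() * 1e3 < 0.1

    def test_ed_vs_ventricular_volumes(self, settled_mech):
        assert settled_mech.V.max() > settled_mech.V.min()
        # a real stroke, not numerical noise
        assert (settled_mech.V.max() - settled_mech.V.min()) > 20e-6

    def test_mean_free_pf_keeps_mean_pressure(self, settled_mech):
        """A genuinely non-uniform, mean-free factor changes the cycle-mean
        chamber pressure by well under 1%."""
        cfg = RunConfig()
        rng = np.random.default_rng(4)
        p = np.tile(settled_mech.p_chamber[:, None], (1, cfg.geometry.n_seg))
        bump = 0.03 * p.max() * np.exp(
            -0.5 * ((np.arange(cfg.geometry.n_seg) - 5) / 3.0) ** 2)
        p = p + bump[None, :] + 20.0 * rng.standard_normal(p.shape)
        pf = build_pressure_factor_field(settled_mech.times, p)
        mod = run_mechanics(cfg, n_cycles=10, pf=pf)
        rel = abs(mod.p_chamber.mean() - settled_mech.p_chamber.mean()) \
            / settled_mech.p_chamber.mean()
        assert rel < 0.01


class TestChamberVolume:
    def test_half_disc(self):
        g = make_chamber(R=1.0, L=1.0, n_seg=128, inlet_span=None,
                         outlet_span=None)
        v = chamber_volume(g.wall_nodes())
        assert v == pytest.approx(np.pi / 2, rel=5e-3)

    def test_translation_invariance(self):
        g = make_chamber(n_seg=32)
        xy = g.wall_nodes()
        assert chamber_volume(xy + np.array([0.3, -0.2])) == \
            pytest.approx(chamber_volume(xy), rel=1e-12)

    def test_agrees_with_grid_cells(self, default_geom, default_mesh):
        from cardioloop.geometry import cell_volumes
        poly = chamber_volume(default_geom.wall_nodes())
        grid = cell_volumes(default_mesh)[default_mesh.chamber_cells].sum()
        assert grid == pytest.approx(poly, rel=1e-12)
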