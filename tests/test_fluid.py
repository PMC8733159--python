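"""Flow-solver verification: the valve law, Darcy-Forchheimer forcing,
adaptive stepping, free-stream preservation under mesh motion, a
closed-form channel flow, scalar boundedness/conservation, and the
blocked-valve contrast."""

import numpy as np
import pytest

from cardioloop.config import RunConfig
from cardioloop.errors import ConfigurationError, StabilityError
from cardioloop.fluid import (AleSolver, FluidParams, ValveConfig,
                              cfl_timestep, init_scalar, run_fluid,
                              valve_forcing, valve_permeability)
from cardioloop.geometry import (build_box_grid, cell_centroids,
                                 cell_volumes, face_vectors)

VCFG = ValveConfig()
PRM = FluidParams()


class TestValveLaw:
    def test_blocked_below_threshold(self):
        assert valve_permeability(10.0, VCFG) == VCFG.k_min
        assert valve_permeability(0.0, VCFG) == VCFG.k_min

    def test_open_above_threshold(self):
        assert valve_permeability(200.0, VCFG) == 1.0
        assert valve_permeability(160.0, VCFG) == 1.0

    def test_linear_ramp_midpoint(self):
        # interpolation oracle between (20, k_min) and (160, 1)
        k90 = valve_permeability(90.0, VCFG)
        expect = np.interp(90.0, [20.0, 160.0], [VCFG.k_min, 1.0])
        assert k90 == pytest.approx(expect, rel=1e-12)
        assert k90 == pytest.approx(0.5, abs=1e-6)

    def test_continuity_at_thresholds(self):
        eps = 1e-9
        assert valve_permeability(20.0 + eps, VCFG) == \
            pytest.approx(VCFG.k_min, abs=1e-10)
        assert valve_permeability(160.0 - eps, VCFG) == \
            pytest.approx(1.0, abs=1e-10)

    def test_negative_flux_rejected(self):
        with pytest.raises(ConfigurationError):
            valve_permeability(-1.0, VCFG)


class TestValveForcing:
    def test_zero_relative_velocity(self):
        F = valve_forcing(np.zeros(2), 0.5, VCFG, PRM, L_ref=0.006)
        assert np.all(F == 0.0)

    def test_dissipative_sign(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u = rng.standard_normal(2)
            k = rng.uniform(VCFG.k_min, 1.0)
            F = valve_forcing(u, k, VCFG, PRM, L_ref=0.006)
            assert float(F @ u) <= 0.0

    def test_hand_value_unit_permeability(self):
        # k = 1, phi = 1, L = 1 m, |u| = 1: |F| = mu/rho + 1.75/sqrt(150)
        F = valve_forcing(np.array([1.0, 0.0]), 1.0, VCFG, PRM, L_ref=1.0)
        expect = 0.004 / 1055.0 + 1.75 / np.sqrt(150.0)
        assert abs(F[0]) == pytest.approx(expect, rel=1e-12)
        assert abs(F[0]) == pytest.approx(0.14289, abs=1e-5)

    def test_monotone_in_permeability(self):
        u = np.array([0.3, 0.0])
        mags = [np.linalg.norm(valve_forcing(u, k, VCFG, PRM, 0.006))
                for k in (1e-6, 1e-4, 1e-2, 1.0)]
        assert all(a > b for a, b in zip(mags, mags[1:]))


class TestCflTimestep:
    def test_first_step_dt0(self):
        m = build_box_grid(0.01, 0.01, 4, 4)
        s = AleSolver(m, PRM).initial_state()
        assert cfl_timestep(s, m, PRM) == PRM.dt0

    def test_uniform_flow_bound(self):
        # |u - c| = 1 m/s on 1 mm cells -> dt <= 0.7 ms
        m = build_box_grid(0.032, 0.032, 32, 32)
        s = AleSolver(m, PRM).initial_state()
        s.u[:, 0] = 1.0
        s.dt = 1.0
        prm = FluidParams(dt_max=1.0)
        assert cfl_timestep(s, m, prm) <= 0.7e-3 + 1e-12

    def test_growth_limited_when_unconstrained(self):
        m = build_box_grid(0.01, 0.01, 4, 4)
        prm = FluidParams(dt_max=10.0, mu=1e-6)
        s = AleSolver(m, prm).initial_state()
        s.u[:] = 0.0   # u = c everywhere (both zero)
        s.dt = 1e-3
        assert cfl_timestep(s, m, prm) == pytest.approx(1.2e-3)

    def test_blow_up_detected(self):
        m = build_box_grid(0.01, 0.01, 4, 4)
        s = AleSolver(m, PRM).initial_state()
        s.u[:, 0] = 1e6
        s.dt = 1e-3
        with pytest.raises(StabilityError):
            cfl_timestep(s, m, PRM)


class TestInitScalar:
    def test_chamber_one_ports_zero(self, default_mesh):
        psi = init_scalar(default_mesh)
        assert np.all(psi[default_mesh.cell_region == 0] == 1.0)
        assert np.all(psi[default_mesh.cell_region > 0] == 0.0)

    def test_all_chamber_mesh(self):
        m = build_box_grid(0.01, 0.01, 4, 4)
        assert np.all(init_scalar(m) == 1.0)

    def test_residual_volume_equals_chamber(self, default_mesh):
        from cardioloop.diagnostics import residual_volume
        psi = init_scalar(default_mesh)
        vol = cell_volumes(default_mesh)
        assert residual_volume(psi, default_mesh) == pytest.approx(
            vol[default_mesh.chamber_cells].sum() * 1e6)


class TestFreeStream:
    def test_uniform_flow_preserved_under_mesh_motion(self):
        """Geometric conservation: a uniform field on a box with arbitrary
        interior mesh motion stays uniform to round-off."""
        m = build_box_grid(1.0, 1.0, 10, 10, bc="velocity")
        prm = FluidParams(rho=1.0, mu=0.01, dt_max=0.01)
        s = AleSolver(m, prm)
        st = s.initial_state()
        u0 = np.array([0.4, -0.25])
        st.u[:] = u0
        sf, _ = face_vectors(m)
        st.face_flux = sf @ u0
        interior = ~m.dirichlet_nodes
        for k in range(25):
            xy_new = m.node_xy0.copy()
            xy_new[interior] += 0.03 * np.sin(0.25 * (k + 1)) * np.sin(
                2.5 * m.node_xy0[interior] + 0.3 * k)
            st = s.step(st, 0.004, xy_new, {"u_bc": u0})
        assert np.max(np.abs(st.u - u0)) < 1e-10
        assert st.div_residual < 1e-10


class TestPoiseuille:
    def test_parabolic_profile_within_2pct(self):
        """Steady pressure-driven channel flow against the closed form
        u_max = dp h^2 / (8 mu L) at 32 cells across."""
        h, L, mu, rho, dp = 0.01, 0.04, 0.1, 100.0, 10.0
        m = build_box_grid(L, h, 16, 32, bc="channel")
        prm = FluidParams(rho=rho, mu=mu, dt_max=1.0, dt0=2e-5)
        s = AleSolver(m, prm, L_ref=1.0)
        st = s.initial_state()
        bcs = {"p_inlet": dp, "p_outlet": 0.0}
        dt = 2e-5
        for _ in range(5000):
            st = s.step(st, dt, m.node_xy0, bcs)
        umax = st.u[:, 0].max()
        exact = dp * h * h / (8 * mu * L)
        assert umax == pytest.approx(exact, rel=0.02)
        assert st.div_residual < 1e-10

    def test_profile_shape(self):
        h, L, mu, rho, dp = 0.01, 0.04, 0.1, 100.0, 10.0
        m = build_box_grid(L, h, 16, 32, bc="channel")
        prm = FluidParams(rho=rho, mu=mu, dt_max=1.0, dt0=2e-5)
        s = AleSolver(m, prm, L_ref=1.0)
        st = s.initial_state()
        for _ in range(5000):
            st = s.step(st, 2e-5, m.node_xy0, {"p_inlet": dp, "p_outlet": 0.0})
        cen = cell_centroids(m)
        col = np.flatnonzero(np.isclose(cen[:, 0], cen[:, 0][np.argmin(
            np.abs(cen[:, 0] - L / 2))]))
        y = cen[col, 1]
        expect = dp / (2 * mu * L) * y * (h - y)
        assert np.allclose(st.u[col, 0], expect, rtol=0.02, atol=1e-5)


class TestScalarTransport:
    def test_no_relative_motion_leaves_psi(self):
        m = build_box_grid(1.0, 1.0, 8, 8, bc="closed")
        prm = FluidParams(rho=1.0, mu=0.01, D=1e-30, dt_max=0.01)
        s = AleSolver(m, prm)
        st = s.initial_state()
        st.psi = np.linspace(0, 1, m.n_cells)
        psi0 = st.psi.copy()
        st = s.step(st, 0.004, m.node_xy0)  # fluid at rest, mesh static
        assert np.allclose(st.psi, psi0, atol=1e-14)

    def test_conservation_on_closed_moving_domain(self):
        m = build_box_grid(1.0, 1.0, 10, 10, bc="closed")
        prm = FluidParams(rho=1.0, mu=0.01, dt_max=0.01)
        s = AleSolver(m, prm)
        st = s.initial_state()
        st.psi = (cell_centroids(m)[:, 0] < 0.5).astype(float)
        tot0 = float((st.psi * cell_volumes(m)).sum())
        interior = ~m.dirichlet_nodes
        for k in range(40):
            xy_new = m.node_xy0.copy()
            xy_new[interior] += 0.025 * np.sin(0.2 * (k + 1)) * np.cos(
                3.0 * m.node_xy0[interior, ::-1])
            st = s.step(st, 0.004, xy_new)
        tot1 = float((st.psi * cell_volumes(m, s.xy)).sum())
        assert abs(tot1 - tot0) <= 1e-10 * tot0
        assert st.psi.min() > -1e-12
        assert st.psi.max() < 1.0 + 1e-12

    def test_step_advection_vs_characteristics(self):
        """Uniform advection of a step: total mass moves at exactly the
        advection speed (upwind smears the front but conserves mass)."""
        nx, ny = 64, 4
        Lx = 1.0
        m = build_box_grid(Lx, 0.1, nx, ny, bc="channel")
        prm = FluidParams(rho=1.0, mu=1e-6, D=1e-30, dt_max=1.0)
        s = AleSolver(m, prm)
        st = s.initial_state()
        u0 = 0.5
        st.u[:, 0] = u0
        sf, _ = face_vectors(m)
        st.face_flux = sf @ np.array([u0, 0.0])
        cen = cell_centroids(m)
        st.psi = (cen[:, 0] < 0.25).astype(float)
        vol = cell_volumes(m)
        mass0 = float((st.psi * vol).sum())
        dt = 0.5 * (Lx / nx) / u0
        steps = 50    # front travels to ~0.64, safely inside the channel
        # drive with a pressure difference that sustains exactly u0:
        # for inviscid steady flow no gradient is needed; keep p equal
        for _ in range(steps):
            st = s.step(st, dt, m.node_xy0, {"p_inlet": 0.0, "p_outlet": 0.0})
        # inflow brings psi = 0, outflow removes psi = 1 once the front
        # reaches the outlet; for this run the front stays inside
        mass1 = float((st.psi * vol).sum())
        shift = u0 * dt * steps
        # mass lost only over the inlet (psi=0 in) => mass constant until
        # the smeared front reaches the outlet; centroid advances by shift
        x_c0 = float((st.psi * vol * cen[:, 0]).sum()) / mass1
        assert mass1 == pytest.approx(mass0, rel=1e-10)
        assert x_c0 == pytest.approx(0.125 + shift, rel=0.05)
        assert st.psi.min() > -1e-12 and st.psi.max() < 1 + 1e-12


class TestBlockedValve:
    def test_blocked_vs_open_throughflow(self):
        """A fully blocked valve zone passes < 1e-3 of the open-valve flux
        under the same pressure drop."""
        h, L = 0.01, 0.04
        m = build_box_grid(L, h, 20, 10, bc="channel")
        cen = cell_centroids(m)
        zone = np.flatnonzero(np.abs(cen[:, 0] - L / 2) < L / 10)
        m.valve_zone_cells = {"mitral": zone,
                              "aortic": np.array([], dtype=np.int64)}
        prm = FluidParams(rho=1055.0, mu=0.004, dt_max=1.0, dt0=1e-4)
        means = {}
        for label, k in (("open", 1.0), ("blocked", VCFG.k_min)):
            s = AleSolver(m, prm, ValveConfig(), L_ref=0.004)
            s.k_p = {"mitral": k, "aortic": 1.0}
            st = s.initial_state()
            for _ in range(1500):
                st = s.step(st, 1e-4, m.node_xy0,
                            {"p_inlet": 200.0, "p_outlet": 0.0})
            means[label] = float(np.abs(st.u[zone, 0]).mean())
        assert means["blocked"] < 1e-3 * means["open"]


class TestRunFluid:
    def test_decay_with_zero_motion_and_equal_pressures(self, default_geom):
        """No wall motion and equal port pressures: velocities decay and
        the residual volume stays within 0.5% over one period."""
        from cardioloop.mechanics import MechResult

        cfg = RunConfig()
        n = 50
        times = np.arange(n) * (1.247 / n)
        xy = np.tile(default_geom.wall_nodes()[None], (n, 1, 1))
        mech = MechResult(times=times, node_xy=xy,
                          p_chamber=np.full(n, 1000.0),
                          p_inlet=np.full(n, 1000.0),
                          p_outlet=np.full(n, 1000.0),
                          V=np.zeros(n), Q_mv=np.zeros(n), Q_ao=np.zeros(n),
                          cycle_index=0, geom=default_geom, T_cycle=1.247)
        res = run_fluid(mech, cfg, n_cycles=1)
        assert np.abs(res.state.u).max() < 1e-6
        v0 = res.residual_volume_ml[0]
        assert np.abs(res.residual_volume_ml - v0).max() < 0.005 * v0

    def test_global_mass_balance_each_step(self, short_mech):
        """Net port outflow balances the chamber volume rate: checked via
        the post-projection divergence residual, which bounds the global
        defect."""
        cfg = RunConfig()
        res = run_fluid(short_mech, cfg, n_cycles=1)
        assert res.state.div_residual < 1e-6

    def test_cycle_periodicity(self, settled_mech):
        """Wall pressure traces approach a limit cycle: cycles 3 and 4
        differ less (L2) than cycles 1 and 2."""
        cfg = RunConfig()
        res = run_fluid(settled_mech, cfg, n_cycles=4)
        wp = res.wall_pressure_cycles
        d12 = np.linalg.norm(wp[1] - wp[0])
        d34 = np.linalg.norm(wp[3] - wp[2])
        assert d34 < d12
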