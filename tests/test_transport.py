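"""Species transport: residence time, platelets, coagulant, bound platelets."""

import numpy as np
import pytest

from thromboflow.cases import stagnant_rt_benchmark
from thromboflow.constitutive import FluidProps, ThrombosisParams
from thromboflow.flow import FieldState, WallState
from thromboflow.geometry import build_channel
from thromboflow.transport import TransportSolver, cycle_averaged_shear


def make_channel(nx=40, ny=8, L=0.04, h=0.008):
    grid = build_channel(L, h, nx, ny)
    params = ThrombosisParams()
    fluid = FluidProps(newtonian_mu=3.5e-3)
    state = FieldState.initial(grid, fluid, params)
    return grid, params, state


class TestResidenceTime:
    def test_stagnant_box_tracks_elapsed_time(self):
        assert stagnant_rt_benchmark(5.0)["rt_rel_err"] < 1e-3

    def test_inlet_cells_stay_near_zero(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.02)
        state.u[:] = 0.1   # plug flow
        for _ in range(100):
            ts.update_residence_time(state)
        # inflow carries RT = 0 through the inlet
        assert state.RT[0].max() < 0.8 * grid.dx / 0.1 * 2

    def test_plug_flow_outlet_transit_time(self):
        grid, params, state = make_channel(nx=60, ny=6, L=0.06)
        U = 0.1
        state.u[:] = U
        dt = 0.3 * grid.dx / U
        ts = TransportSolver(grid, params, dt=dt)
        steps = int(3.0 * (0.06 / U) / dt)
        for _ in range(steps):
            ts.update_residence_time(state)
        transit = 0.06 / U
        out_rt = state.RT[-1].mean()
        assert out_rt == pytest.approx(transit, rel=0.03)


class TestPlatelets:
    def test_uniform_rest_state_unchanged(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.05)
        for _ in range(20):
            ts.update_platelets(state)
        assert np.allclose(state.RP_rel[grid.mask], 1.0, atol=1e-12)
        assert np.allclose(state.AP_rel[grid.mask], 0.05, atol=1e-12)

    def test_inlet_activation_level(self):
        grid, params, state = make_channel()
        state.u[:] = 0.1          # plug flow, transit time 0.4 s
        state.AP_rel[:] = 0.0     # flushed domain refills from the inlet
        ts = TransportSolver(grid, params, dt=0.002)
        for _ in range(700):
            ts.update_platelets(state)
        assert state.AP_rel[0].mean() == pytest.approx(0.05, rel=0.02)
        assert state.AP_rel[-1].mean() == pytest.approx(0.05, rel=0.02)

    def test_advection_is_conservative(self):
        """MUSCL transport of an interior blob conserves total mass exactly."""
        grid, params, state = make_channel(nx=50, ny=8, L=0.05)
        U = 0.1
        state.u[:] = U
        dt = 0.25 * grid.dx / U
        ts = TransportSolver(grid, params, dt=dt)
        phi = np.zeros((grid.nx, grid.ny))
        phi[10:16, 2:6] = 1.0
        total0 = phi.sum()
        for _ in range(10):       # blob stays far from the boundaries
            phi = phi + dt * ts._advect(phi, state.u, state.v, 0.0)
        assert phi.sum() == pytest.approx(total0, rel=1e-12)
        assert phi.min() > -1e-12, "limited scheme stays monotone"
        assert phi[:13].sum() < 0.4 * total0, "blob moved downstream"


class TestCoagulant:
    def test_no_source_stays_zero(self):
        grid, params, state = make_channel()
        wall = WallState.zeros(grid.n_wall)
        wall.tawss[:] = 0.5       # all walls above the TAWSS threshold
        ts = TransportSolver(grid, params, dt=0.05)
        for _ in range(30):
            ts.update_coagulant(state, wall)
        assert np.abs(state.C).max() == 0.0

    def test_wall_flux_fills_no_flow_box(self):
        # unaugmented diffusivity so nothing reaches the open inlet
        params = ThrombosisParams(f_aug=1.0)
        grid, _, state = make_channel(nx=8, ny=6, L=0.008, h=0.006)
        wall = WallState.zeros(grid.n_wall)
        wall.tawss[:] = 0.5
        mid = np.argmin(np.abs(grid.wall_i - grid.nx // 2))
        wall.tawss[mid] = 0.0     # exactly one emitting wall face, mid-channel
        dt = 0.05
        ts = TransportSolver(grid, params, dt=dt)
        n = 40
        for _ in range(n):
            ts.update_coagulant(state, wall)
        area = grid.dx * grid.dy
        face_len = grid.wall_len[mid]
        expected_total = params.k_c_wall * face_len / area * dt * n * area
        got_total = state.C.sum() * area
        assert got_total == pytest.approx(expected_total, rel=1e-9)

    def test_high_shear_seed_decays(self):
        grid, params, state = make_channel()
        wall = WallState.zeros(grid.n_wall)
        wall.tawss[:] = 0.5
        ts = TransportSolver(grid, params, dt=0.01)
        ts.gamma_avg[:] = 500.0   # high averaged shear: consumption active
        state.C[:] = np.where(grid.mask, 5.0, 0.0)
        c0 = state.C.max()
        for _ in range(20):
            ts.update_coagulant(state, wall)
        assert state.C.max() < c0


class TestBoundPlatelets:
    def test_immobile_without_source(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.05)
        bp0 = np.where(grid.mask, 30.0, 0.0)
        bp0[5, 3] = 77.0
        state.BP = bp0.copy()
        ts.eligible[:] = True
        state.C[:] = 0.0          # no coagulant: zero rate
        ts.update_bound_platelets(state)
        np.testing.assert_array_equal(state.BP, bp0)

    def test_gated_cell_does_not_grow(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.05)
        state.C[:] = 1e4
        ts.gamma_avg[:] = 80.0
        ts.eligible[:] = False    # wall TAWSS 0.25 Pa, no neighbour, bulk gate shut
        rate = ts.update_bound_platelets(state)
        assert np.abs(rate).max() == 0.0

    def test_saturated_growth_rate(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.05)
        state.AP_rel[:] = np.where(grid.mask, 1.0, 0.0)
        state.C[:] = np.where(grid.mask, 1e6, 0.0)
        ts.gamma_avg[:] = 0.0
        ts.eligible[:] = True
        bp0 = state.BP.copy()
        ts.update_bound_platelets(state)
        inc = (state.BP - bp0)[grid.mask]
        np.testing.assert_allclose(inc, params.k_BP * ts.dt, rtol=1e-6)

    def test_monotone_nondecreasing(self):
        grid, params, state = make_channel()
        ts = TransportSolver(grid, params, dt=0.05)
        state.C[:] = np.where(grid.mask, 100.0, 0.0)
        ts.eligible[:] = True
        prev = state.BP.copy()
        for _ in range(5):
            ts.update_bound_platelets(state)
            assert np.all(state.BP >= prev)
            prev = state.BP.copy()


class TestCycleAveragedShear:
    def test_constant(self):
        s = cycle_averaged_shear([np.full((3, 3), 50.0)] * 7)
        np.testing.assert_allclose(s, 50.0)

    def test_sinusoid_matches_quadrature(self):
        t = np.linspace(0, 1, 5001)[:-1]
        samples = [np.full((2, 2), 10 + 5 * np.sin(2 * np.pi * tk)) for tk in t]
        np.testing.assert_allclose(cycle_averaged_shear(samples), 10.0, rtol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cycle_averaged_shear(np.empty((0, 2, 2)))
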