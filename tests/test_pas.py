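"""Particle tracing and the cumulative platelet-activation index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thromboflow.constitutive import FluidProps, InvalidInputError, PASParams, ThrombosisParams
from thromboflow.flow import FieldState
from thromboflow.geometry import build_channel
from thromboflow.pas import (
    VelocitySampler,
    inlet_seeds,
    pas_index,
    shear_along_path,
    trace_particles,
)

PAS = PASParams()


def uniform_snapshots(grid, U=0.1, V=0.0, n=2, T=1.0):
    snaps = []
    for k in range(n):
        s = FieldState.initial(grid, FluidProps(), ThrombosisParams())
        s.u[:] = U
        s.v[:] = V
        s.t = k * T / n
        snaps.append(s)
    return snaps


class TestTracing:
    def test_uniform_field_is_exact(self):
        grid = build_channel(0.1, 0.02, 20, 8)
        snaps = uniform_snapshots(grid, U=0.05)
        tr = trace_particles(snaps, grid, [(0.005, 0.01)], [0.0],
                             dt_particle=0.01, max_cycles=5, period=1.0)[0]
        np.testing.assert_allclose(tr.x, 0.005 + 0.05 * (tr.times - tr.times[0]),
                                   rtol=1e-12)
        np.testing.assert_allclose(tr.y, 0.01, atol=1e-15)
        assert tr.exit_flag == "left-domain"

    def test_solid_body_rotation_closes_orbit(self):
        # square cavity with a rigid-rotation velocity field about its centre
        grid = build_channel(0.02, 0.02, 40, 40)
        omega = 2.0
        xc = yc = 0.01
        s = FieldState.initial(grid, FluidProps(), ThrombosisParams())
        xf = np.arange(grid.nx + 1) * grid.dx
        ycen = grid.y_centers
        s.u = -omega * (ycen[None, :] - yc) * np.ones((grid.nx + 1, 1))
        xcen = grid.x_centers
        yf = np.arange(grid.ny + 1) * grid.dy
        s.v = omega * (xcen[:, None] - xc) * np.ones((1, grid.ny + 1))
        s.t = 0.0
        period = 2 * np.pi / omega
        x0, y0 = 0.014, 0.01
        tr = trace_particles([s], grid, [(x0, y0)], [0.0],
                             dt_particle=period / 2000, max_cycles=1,
                             period=period)[0]
        r0 = np.hypot(x0 - xc, y0 - yc)
        r = np.hypot(tr.x - xc, tr.y - yc)
        assert np.abs(r - r0).max() / r0 < 1e-6
        assert np.hypot(tr.x[-1] - x0, tr.y[-1] - y0) < 1e-6 * r0

    def test_zero_velocity_flags_stuck(self):
        grid = build_channel(0.1, 0.02, 10, 6)
        snaps = uniform_snapshots(grid, U=0.0)
        tr = trace_particles(snaps, grid, [(0.05, 0.01)], [0.0],
                             dt_particle=0.05, max_cycles=2, period=1.0)[0]
        assert tr.exit_flag == "stuck"

    def test_seed_in_solid_is_error_record(self):
        grid = build_channel(0.1, 0.02, 10, 6)
        snaps = uniform_snapshots(grid)
        trajs = trace_particles(snaps, grid, [(-0.01, 0.01), (0.01, 0.01)], [0.0],
                                dt_particle=0.05, max_cycles=1, period=1.0)
        flags = sorted(t.exit_flag for t in trajs)
        assert "seed-error" in flags
        assert len(trajs) == 2


class TestShearAlongPath:
    def test_poiseuille_shear_profile(self):
        grid = build_channel(0.1, 0.01, 16, 64)
        mu = 3.5e-3
        U = 0.1
        h = 0.01
        s = FieldState.initial(grid, FluidProps(newtonian_mu=mu), ThrombosisParams())
        y = grid.y_centers
        s.u[:] = (6 * U * y * (h - y) / h ** 2)[None, :]
        s.mu[:] = mu
        s.gamma[:] = np.abs(6 * U * (h - 2 * y) / h ** 2)[None, :]
        tr = trace_particles([s], grid, [(0.01, 0.0025)], [0.0],
                             dt_particle=0.005, max_cycles=1, period=1.0)[0]
        tau = shear_along_path(tr, [s], grid, period=1.0)
        tau_exact = mu * 6 * U * (h - 2 * 0.0025) / h ** 2
        assert np.median(tau) == pytest.approx(tau_exact, rel=0.02)

    def test_centerline_and_wall_ordering(self):
        grid = build_channel(0.1, 0.01, 16, 64)
        s = FieldState.initial(grid, FluidProps(newtonian_mu=3.5e-3), ThrombosisParams())
        y = grid.y_centers
        s.u[:] = (6 * 0.1 * y * (0.01 - y) / 0.01 ** 2)[None, :]
        s.mu[:] = 3.5e-3
        s.gamma[:] = np.abs(6 * 0.1 * (0.01 - 2 * y) / 0.01 ** 2)[None, :]
        sampler = VelocitySampler([s], grid, 1.0)
        tau_center = sampler.shear_stress(0.05, 0.005, 0.0)
        tau_wall = sampler.shear_stress(0.05, 0.0004, 0.0)
        assert tau_center < 0.05 * tau_wall


class TestPasIndex:
    def test_unit_load_returns_printed_constant(self):
        t = np.linspace(0, 1, 1001)
        assert pas_index(t, np.ones_like(t), PAS) == pytest.approx(1e-5, rel=1e-3)

    def test_zero_load_keeps_initial_activation(self):
        t = np.linspace(0, 10, 100)
        assert pas_index(t, np.zeros_like(t), PAS) == 0.0
        p = PASParams(PAS_0=0.2)
        assert pas_index(t, np.zeros_like(t), p) == pytest.approx(0.2, rel=1e-9)

    def test_two_pascal_closed_form(self):
        t = np.linspace(0, 1, 2001)
        expected = 1e-5 * 2 ** 0.6256
        assert pas_index(t, np.full_like(t, 2.0), PAS) == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(1.542e-5, rel=1e-3)

    def test_piecewise_constant_quadrature_oracle(self):
        """Exact closed form for piecewise-constant τ: the load integral is
        a sum of τ_k^{b/a}·Δt_k."""
        rng = np.random.default_rng(7)
        taus = rng.uniform(0.1, 5.0, 5)
        widths = rng.uniform(0.2, 1.0, 5)
        dt = 1e-4
        segs_t, segs_tau, t0 = [], [], 0.0
        for tau, w in zip(taus, widths):
            n = int(w / dt)
            tt = t0 + np.arange(n) * dt
            segs_t.append(tt)
            segs_tau.append(np.full(n, tau))
            t0 = tt[-1] + dt
        t = np.concatenate(segs_t)
        tau = np.concatenate(segs_tau)
        got = pas_index(t, tau, PAS)
        load = sum(tk ** (PAS.b / PAS.a) * (w - w % dt)
                   for tk, w in zip(taus, widths))
        # trapezoid over the jumps differs from the exact sum at O(dt)
        exact = PAS.C * load ** PAS.a
        assert got == pytest.approx(exact, rel=1e-3)

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, taus):
        t = np.arange(len(taus), dtype=float)
        series = pas_index(t, np.array(taus), PAS, return_series=True)
        assert np.all(np.diff(series) >= -1e-18)
        assert series[0] >= 0.0 and series[-1] <= 1.0

    def test_dt_refinement_converges(self):
        tau_fn = lambda t: 1.0 + 0.5 * np.sin(3 * t)
        t1 = np.linspace(0, 2, 401)
        t2 = np.linspace(0, 2, 801)
        p1 = pas_index(t1, tau_fn(t1), PAS)
        p2 = pas_index(t2, tau_fn(t2), PAS)
        assert abs(p1 - p2) / p2 < 1e-2

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            pas_index([0, 1], [-1.0, 0.0], PAS)
        with pytest.raises(InvalidInputError):
            pas_index([0, 0], [1.0, 1.0], PAS)


class TestDissectionActivation:
    def test_fl_crossing_platelets_more_activated(self, s1_result):
        """Particles diverted through the tear into the FL accumulate more
        shear load than those transiting the true lumen."""
        res = s1_result
        cfg = res.config
        T = cfg.waveform.T
        per = cfg.run.snapshots_per_cycle
        snaps = res.snapshots[:per]           # first growth cycle: tear open
        grid = res.grid
        seeds = inlet_seeds(grid, 12)
        t0 = snaps[0].t
        phases = [t0 + f * T for f in (0.0, 0.15, 0.30, 0.45)]
        trajs = trace_particles(snaps, grid, seeds, phases, dt_particle=T / 200,
                                max_cycles=4, period=T)
        flap_top = cfg.geometry.lumen_height + cfg.geometry.flap_thickness
        fl_pas, tl_pas = [], []
        for tr in trajs:
            if tr.exit_flag == "seed-error":
                continue
            shear_along_path(tr, snaps, grid, T)
            final = pas_index(tr.times, tr.tau, cfg.pas)
            if tr.y.max() > flap_top:
                fl_pas.append(final)
            else:
                tl_pas.append(final)
        assert fl_pas, "some particles should enter the false lumen"
        assert tl_pas, "some particles should stay in the true lumen"
        assert np.mean(fl_pas) > np.mean(tl_pas)
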