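"""Pointwise constitutive laws: pinned values and order/bound properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thromboflow.constitutive import (
    ConfigurationError,
    FluidProps,
    InvalidInputError,
    PASParams,
    ThrombosisParams,
    bound_platelet_source,
    clot_porosity,
    coagulant_bulk_source,
    coagulant_wall_flux,
    momentum_sink,
    quemada_viscosity,
    switch_down,
    switch_up,
)

P = ThrombosisParams()
F = FluidProps()


class TestDefaults:
    def test_published_parameter_set(self):
        assert P.k_c == 200.0
        assert P.k_c_wall == 20.0
        assert P.k_M == 1e7
        assert P.D_c == 1e-8
        assert P.BP_t == 20.0
        assert P.gamma_t == 50.0
        assert P.tawss_t == 0.2
        assert P.BP_complete == 200.0
        assert P.eps_min == 0.75
        assert P.f_aug == 150.0
        assert P.D_c_eff == pytest.approx(1.5e-6)
        pas = PASParams()
        assert (pas.a, pas.b, pas.C) == (1.3198, 0.6256, 1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ThrombosisParams(k_M=-1.0)
        with pytest.raises(ConfigurationError):
            ThrombosisParams(eps_min=0.0)
        with pytest.raises(ConfigurationError):
            ThrombosisParams(BP_t=300.0)  # above BP_complete
        with pytest.raises(ConfigurationError):
            FluidProps(hematocrit=1.2)


class TestQuemada:
    def test_high_shear_limit(self):
        mu_inf = 1.2e-3 * (1 - 0.5 * 2.07 * 0.45) ** -2
        assert quemada_viscosity(1e9, F) == pytest.approx(mu_inf, rel=1e-4)
        assert mu_inf == pytest.approx(4.204e-3, rel=1e-3)

    def test_no_cells_limit(self):
        f0 = FluidProps(hematocrit=0.0)
        for g in (0.0, 1.0, 100.0):
            assert quemada_viscosity(g, f0) == pytest.approx(f0.mu_plasma)

    def test_critical_shear_rate_midpoint(self):
        # at γ̇ = γ̇_c the intrinsic viscosity is the mean of k0, k_inf
        k = 0.5 * (F.k0 + F.k_inf)
        mu = F.mu_plasma * (1 - 0.5 * k * F.hematocrit) ** -2
        assert quemada_viscosity(F.gamma_c, F) == pytest.approx(mu, rel=1e-12)

    def test_bounded_by_analytic_limits(self):
        lo = quemada_viscosity(1e12, F)
        hi = quemada_viscosity(F.gamma_min, F)
        g = np.geomspace(F.gamma_min, 1e6, 200)
        mu = quemada_viscosity(g, F)
        assert np.all(mu <= hi + 1e-12) and np.all(mu >= lo - 1e-12)
        assert np.all(np.diff(mu) < 0), "strictly decreasing in shear rate"

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            quemada_viscosity(np.nan, F)
        with pytest.raises(InvalidInputError):
            quemada_viscosity(-1.0, F)


class TestPorosity:
    @pytest.mark.parametrize("bp,expected", [
        (0.0, 1.0),                 # no thrombus
        (20.0, 0.75),               # completely formed clot at the threshold
        (200.0, 0.75),              # and anywhere above it
        (10.0, 0.875),              # linear ramp in between
    ])
    def test_pinned_values(self, bp, expected):
        assert clot_porosity(bp, P) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, b1, b2):
        e1, e2 = clot_porosity(b1, P), clot_porosity(b2, P)
        assert 0.75 <= e1 <= 1.0
        if b1 <= b2:
            assert e1 >= e2

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            clot_porosity(-0.1, P)


class TestSwitches:
    @pytest.mark.parametrize("x,xt,n,expected", [
        (0.0, 5.0, 2, 0.0),
        (5.0, 5.0, 2, 0.5),
        (20.0, 20.0, 2, 0.5),       # ϕ_BP at the BP threshold
    ])
    def test_anchor_points(self, x, xt, n, expected):
        assert switch_up(x, xt, n) == pytest.approx(expected)

    @given(st.floats(0, 1e6), st.floats(1e-6, 1e4), st.integers(1, 4))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity(self, x, xt, n):
        up = switch_up(x, xt, n)
        dn = switch_down(x, xt, n)
        assert 0.0 <= up <= 1.0 and 0.0 <= dn <= 1.0
        assert up + dn == pytest.approx(1.0, abs=1e-12)

    def test_bad_scale(self):
        with pytest.raises(ConfigurationError):
            switch_up(1.0, 0.0, 2)


class TestMomentumSink:
    def test_zero_cases(self):
        assert momentum_sink(0.0, 1.0, P) == 0.0
        assert momentum_sink(100.0, 0.0, P) == 0.0

    def test_saturation_magnitude(self):
        # fully thrombosed: |S_M| -> k_M |u|
        s = momentum_sink(1e6, 1e-3, P)
        assert s == pytest.approx(-P.k_M * 1e-3, rel=1e-6)

    @given(st.floats(0, 1e3), st.floats(-1, 1))
    @settings(max_examples=200, deadline=None)
    def test_odd_in_velocity_opposes_flow(self, bp, u):
        s = momentum_sink(bp, u, P)
        assert s == pytest.approx(-momentum_sink(bp, -u, P), abs=1e-9)
        assert s * u <= 0.0

    def test_magnitude_nondecreasing_in_bp(self):
        bps = np.linspace(0, 500, 100)
        mags = np.abs(momentum_sink(bps, 1.0, P))
        assert np.all(np.diff(mags) >= 0)


class TestCoagulantWallFlux:
    @pytest.mark.parametrize("tawss,bp,expected", [
        (0.05, 0.0, 20.0),       # low shear, clean wall: full release
        (0.05, 250.0, 0.0),      # complete thrombosis shuts the flux off
        (0.5, 0.0, 0.0),         # high shear: no release
        (0.19999, 200.0, 20.0),  # at the shutoff boundary (BP <= complete)
        (0.2, 0.0, 0.0),         # threshold is strict
    ])
    def test_gated_values(self, tawss, bp, expected):
        assert coagulant_wall_flux(tawss, bp, P) == expected

    def test_vectorized_region_identity(self):
        t = np.linspace(0, 1, 101)
        bp = np.linspace(0, 400, 101)
        fx = coagulant_wall_flux(t[:, None], bp[None, :], P)
        dead = (t[:, None] >= 0.2) | (bp[None, :] > 200.0)
        assert np.all(fx[dead] == 0.0)
        assert np.all(fx[~dead] == 20.0)


class TestBulkSources:
    def test_coagulant_rest_state(self):
        assert coagulant_bulk_source(0.0, 0.0, 0.0, P) == 0.0

    def test_production_saturates_at_kc(self):
        assert coagulant_bulk_source(0.0, 1e6, 0.0, P) == pytest.approx(200.0, rel=1e-6)

    def test_consumption_in_high_shear(self):
        r = coagulant_bulk_source(5.0, 0.0, 1e4, P)
        assert r < 0.0
        assert r == pytest.approx(-P.k_c * 5.0 / P.C_t, rel=1e-3)

    def test_bp_growth_linear_in_ap(self):
        r1 = bound_platelet_source(0.3, 50.0, 10.0, P)
        r2 = bound_platelet_source(0.6, 50.0, 10.0, P)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)
        assert bound_platelet_source(0.0, 50.0, 10.0, P) == 0.0
        assert bound_platelet_source(1.0, 0.0, 10.0, P) == 0.0

    def test_bp_growth_shear_suppression(self):
        r0 = bound_platelet_source(1.0, 1e4, 0.0, P)
        r500 = bound_platelet_source(1.0, 1e4, 500.0, P)
        # switch_down(500, 50, 2) = 1/101
        assert r500 / r0 == pytest.approx(1.0 / 101.0, rel=1e-9)
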