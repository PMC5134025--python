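"""Constitutive laws of the haemodynamics-based thrombosis model.

The model tracks a growing thrombus through the local concentration of
*bound platelets* (BP, nmol l⁻¹).  BP feeds back on the flow in two ways:
it lowers the local clot porosity ε (from 1 for open lumen down to 0.75
for a fully formed clot) and it switches on a Darcy/Brinkman momentum
sink that resists flow through the clot.  Thrombus growth itself is
gated by haemodynamics: a *coagulant* species C is released at wall
faces whose time-averaged wall shear stress (TAWSS) over the previous
cardiac cycle is below 0.2 Pa, is produced inside forming thrombus at
low cycle-averaged shear rate, and is consumed wherever the
cycle-averaged shear rate is high.  Activated platelets then bind
(AP → BP) where coagulant is present and averaged shear is below
50 s⁻¹.

All thresholds and kinetic constants live in :class:`ThrombosisParams`;
blood rheology (Quemada) in :class:`FluidProps`; the Lagrangian platelet
activation constants in :class:`PASParams`.  Every law in this module is
a pointwise, side-effect-free function so it can be tested in isolation
and applied to whole numpy fields by broadcasting.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "FluidProps",
    "ThrombosisParams",
    "PASParams",
    "quemada_viscosity",
    "clot_porosity",
    "switch_up",
    "switch_down",
    "momentum_sink",
    "coagulant_wall_flux",
    "coagulant_bulk_source",
    "bound_platelet_source",
]


class InvalidInputError(ValueError):
    """Raised when a constitutive law receives a physically invalid input."""


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class FluidProps:
    """Blood as an incompressible shear-thinning (Quemada) fluid.

    Parameters
    ----------
    rho
        Density, kg m⁻³.
    mu_plasma
        Plasma viscosity μ_p, Pa s.
    hematocrit
        Red-cell volume fraction H, dimensionless, in (0, 1).
    k0, k_inf
        Quemada intrinsic-viscosity constants at zero / infinite shear.
    gamma_c
        Critical shear rate γ̇_c of the Quemada model, s⁻¹.
    gamma_min
        Floor applied to the shear rate before evaluating the viscosity,
        s⁻¹; keeps the zero-shear limit finite on stagnant cells.
    newtonian_mu
        If set, overrides the Quemada law with a constant viscosity
        (used by the analytic verification cases).
    """

    rho: float = 1060.0
    mu_plasma: float = 1.2e-3
    hematocrit: float = 0.45
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88
    gamma_min: float = 1e-3
    newtonian_mu: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu_plasma <= 0:
            raise ConfigurationError("density and plasma viscosity must be positive")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ConfigurationError("hematocrit must lie in [0, 1)")
        if self.gamma_c <= 0 or self.gamma_min <= 0:
            raise ConfigurationError("Quemada shear-rate scales must be positive")


@dataclass(frozen=True)
class ThrombosisParams:
    """Kinetic constants and thresholds of the thrombosis model.

    Defaults reproduce the model's standard parameter set: coagulant
    kinetic constant k_c = 200 nmol l⁻¹ s⁻¹, wall-kinetic constant
    k̄_c = 20 nmol m⁻¹ l⁻¹ s⁻¹, momentum-source constant k_M = 10⁷
    kg m⁻³ s⁻¹, coagulant diffusivity D_c = 10⁻⁸ m² s⁻¹, BP threshold
    BP_t = 20 nmol l⁻¹ and bulk shear-rate threshold γ̇_t = 50 s⁻¹, with
    wall growth gated at TAWSS < 0.2 Pa, flux shut-off beyond
    BP = 200 nmol l⁻¹ and clot porosity bounded below by 0.75.  The
    coagulant diffusivity is augmented by ``f_aug`` (×150) to accelerate
    the kinetics so that thrombosis completes within tens of cardiac
    cycles instead of hours.
    """

    k_c: float = 200.0            # coagulant kinetic constant, nmol l⁻¹ s⁻¹
    k_c_wall: float = 20.0        # coagulant wall-kinetic constant, nmol m⁻¹ l⁻¹ s⁻¹
    k_M: float = 1e7              # momentum source constant, kg m⁻³ s⁻¹
    D_c: float = 1e-8             # coagulant diffusivity, m² s⁻¹
    f_aug: float = 150.0          # kinetic acceleration on D_c
    BP_t: float = 20.0            # bound-platelet threshold, nmol l⁻¹
    BP_complete: float = 200.0    # complete-thrombosis level, nmol l⁻¹
    tawss_t: float = 0.2          # TAWSS wall-growth threshold, Pa
    gamma_t: float = 50.0         # bulk shear-rate threshold, s⁻¹
    eps_min: float = 0.75         # porosity of a completely formed clot
    C_t: float = 1.0              # coagulant switching scale, nmol l⁻¹
    k_BP: float = 80.0            # bound-platelet kinetic constant, nmol l⁻¹ s⁻¹
    D_p: float = 1e-9             # platelet diffusivity, m² s⁻¹
    D_RT: float = 1e-9            # residence-time diffusivity, m² s⁻¹
    n_sw: float = 2.0             # switching-function exponent
    N_pool: float = 1e4           # platelet pool capacity, nmol l⁻¹ BP per unit rel. conc.

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be non-negative")
        if not 0.0 < self.eps_min <= 1.0:
            raise ConfigurationError("eps_min must lie in (0, 1]")
        if not self.BP_complete > self.BP_t > 0:
            raise ConfigurationError("need BP_complete > BP_t > 0")
        if self.n_sw < 1:
            raise ConfigurationError("switching exponent must be >= 1")

    @property
    def D_c_eff(self) -> float:
        """Effective (augmented) coagulant diffusivity f_aug · D_c, m² s⁻¹."""
        return self.f_aug * self.D_c


@dataclass(frozen=True)
class PASParams:
    """Constants of the cumulative platelet-activation-state power law.

    ``a``, ``b`` and ``C`` are the Grigioni/Nobili calibration
    (a = 1.3198, b = 0.6256, C = 10⁻⁵); ``PAS_0`` is the activation a
    platelet carries when released (zero for inlet-fresh platelets).
    """

    a: float = 1.3198
    b: float = 0.6256
    C: float = 1e-5
    PAS_0: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.C <= 0:
            raise ConfigurationError("PAS constants a, b, C must be positive")
        if not 0.0 <= self.PAS_0 <= 1.0:
            raise ConfigurationError("PAS_0 must lie in [0, 1]")


def _check_nonneg(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"{name} must be finite")
    if np.any(x < 0):
        raise InvalidInputError(f"{name} must be non-negative")
    return x


def quemada_viscosity(gamma_dot, props: FluidProps):
    """Quemada apparent viscosity μ(γ̇) of whole blood, Pa s.

    μ = μ_p (1 − ½ k(γ̇) H)⁻² with the shear-dependent intrinsic
    viscosity k(γ̇) = (k₀ + k_∞ √(γ̇/γ̇_c)) / (1 + √(γ̇/γ̇_c)).  The
    shear rate is clamped below at ``props.gamma_min`` so the
    (finite) zero-shear plateau is returned on stagnant cells.
    Strictly decreasing in γ̇ between the two analytic limits.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("shear rate must be finite")
    if np.any(g < 0):
        raise InvalidInputError("shear rate must be non-negative")
    if props.newtonian_mu is not None:
        return np.broadcast_to(np.float64(props.newtonian_mu), g.shape).copy() if g.ndim else float(props.newtonian_mu)
    g = np.maximum(g, props.gamma_min)
    root = np.sqrt(g / props.gamma_c)
    k = (props.k0 + props.k_inf * root) / (1.0 + root)
    mu = props.mu_plasma * (1.0 - 0.5 * k * props.hematocrit) ** -2
    return float(mu) if np.ndim(gamma_dot) == 0 else mu


def clot_porosity(BP, params: ThrombosisParams):
    """Local porosity ε of the (forming) clot as a function of BP.

    Linear ramp from ε = 1 at BP = 0 down to ε = ε_min (0.75, a
    completely formed clot) at BP = BP_t, constant beyond:
    ε = 1 − (1 − ε_min) · min(BP/BP_t, 1).
    """
    bp = _check_nonneg("BP", BP)
    eps = 1.0 - (1.0 - params.eps_min) * np.minimum(bp / params.BP_t, 1.0)
    return float(eps) if np.ndim(BP) == 0 else eps


def switch_up(x, x_t: float, n: float):
    """Saturating switch xⁿ/(xⁿ + x_tⁿ): 0 at x=0, ½ at x=x_t, →1 as x→∞."""
    if x_t <= 0:
        raise ConfigurationError("switching scale x_t must be positive")
    xs = _check_nonneg("x", x)
    r = (xs / x_t) ** n
    out = r / (r + 1.0)
    return float(out) if np.ndim(x) == 0 else out


def switch_down(x, x_t: float, n: float):
    """Complementary switch 1 − switch_up: 1 at x=0, ½ at x=x_t, →0 as x→∞."""
    if x_t <= 0:
        raise ConfigurationError("switching scale x_t must be positive")
    xs = _check_nonneg("x", x)
    r = (xs / x_t) ** n
    out = 1.0 / (r + 1.0)
    return float(out) if np.ndim(x) == 0 else out


def momentum_sink(BP, u, params: ThrombosisParams):
    """Brinkman resistance S_M = −k_M · ϕ_BP(BP) · u, kg m⁻² s⁻².

    ϕ_BP = switch_up(BP, BP_t, n) so the sink vanishes in clot-free
    blood and saturates at −k_M u inside a fully formed clot.  Odd in
    u; magnitude non-decreasing in BP.
    """
    bp = _check_nonneg("BP", BP)
    phi = switch_up(bp, params.BP_t, params.n_sw)
    out = -params.k_M * phi * np.asarray(u, dtype=float)
    return float(out) if np.ndim(u) == 0 and np.ndim(BP) == 0 else out


def coagulant_wall_flux(tawss, BP_wall, params: ThrombosisParams):
    """Coagulant release rate at a wall face, nmol m⁻¹ l⁻¹ s⁻¹ (2D: per
    unit wall length).

    flux = k̄_c · 1[TAWSS < τ_w_t] · 1[BP_wall ≤ BP_complete]: the wall
    emits coagulant at the fixed rate 20 nmol m⁻¹ l⁻¹ s⁻¹ only while the
    previous-cycle TAWSS is below 0.2 Pa, and shuts off once the local
    thrombus is complete (BP > 200 nmol l⁻¹).
    """
    t = _check_nonneg("TAWSS", tawss)
    bp = _check_nonneg("BP_wall", BP_wall)
    flux = params.k_c_wall * ((t < params.tawss_t) & (bp <= params.BP_complete))
    return float(flux) if np.ndim(tawss) == 0 and np.ndim(BP_wall) == 0 else flux


def coagulant_bulk_source(C, BP, gamma_avg, params: ThrombosisParams):
    """Net bulk coagulant rate, nmol l⁻¹ s⁻¹.

    Production k_c · ϕ_BP(BP) · ϕ_γ̇↓(γ̇_avg) inside forming thrombus at
    low cycle-averaged shear, minus consumption k_c · (C/C_t) ·
    ϕ_γ̇↑(γ̇_avg) which prevents coagulant accumulating in high-shear
    regions.
    """
    c = _check_nonneg("C", C)
    bp = _check_nonneg("BP", BP)
    g = _check_nonneg("gamma_avg", gamma_avg)
    prod = params.k_c * switch_up(bp, params.BP_t, params.n_sw) * switch_down(g, params.gamma_t, params.n_sw)
    cons = params.k_c * (c / params.C_t) * switch_up(g, params.gamma_t, params.n_sw)
    out = prod - cons
    scalar = np.ndim(C) == 0 and np.ndim(BP) == 0 and np.ndim(gamma_avg) == 0
    return float(out) if scalar else out


def bound_platelet_source(AP_rel, C, gamma_avg, params: ThrombosisParams):
    """Platelet-binding rate dBP/dt, nmol l⁻¹ s⁻¹.

    rate = k_BP · AP_rel · ϕ_c↑(C) · ϕ_γ̇↓(γ̇_avg): linear in the local
    activated-platelet level, requires coagulant (zero at C = 0) and is
    suppressed where the cycle-averaged shear rate exceeds γ̇_t.
    """
    ap = _check_nonneg("AP_rel", AP_rel)
    c = _check_nonneg("C", C)
    g = _check_nonneg("gamma_avg", gamma_avg)
    out = params.k_BP * ap * switch_up(c, params.C_t, params.n_sw) * switch_down(g, params.gamma_t, params.n_sw)
    scalar = np.ndim(AP_rel) == 0 and np.ndim(C) == 0 and np.ndim(gamma_avg) == 0
    return float(out) if scalar else out
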