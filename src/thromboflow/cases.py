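"""Canned cases and analytic benchmarks.

Everything here is generated programmatically: channel verification
cases with closed-form solutions (Poiseuille, Womersley), the steady
backward-facing-step thrombosis calibration configuration, and the two
idealized-dissection cases — a single proximal tear (the admission-stage
analog) and a proximal + middle tear with a pre-thrombosed proximal
false-lumen cap and 1% initial wall coagulant (the follow-up-stage
restart protocol).
"""

from __future__ import annotations

import numpy as np

from .config import CaseConfig, GeometryConfig, RunParams
from .constitutive import FluidProps, PASParams, ThrombosisParams
from .flow import FieldState, FlowSolver
from .geometry import WaveformParams, build_channel
from .pas import pas_index
from .transport import TransportSolver

__all__ = [
    "poiseuille_case", "womersley_case", "bfs_thrombosis_case",
    "dissection_s1_case", "dissection_s4_case",
    "poiseuille_benchmark", "womersley_benchmark", "stagnant_rt_benchmark",
    "pas_closed_form_error", "run_benchmarks",
]

_MU_NEWT = 3.5e-3      # Newtonian-override viscosity for verification, Pa s
_RHO = 1060.0


def poiseuille_case(ny: int = 64, height: float = 0.01, length: float = 0.05,
                    u_mean: float = 0.01):
    """Steady channel config plus the exact parabolic profile u(y)."""
    cfg = CaseConfig(
        fluid=FluidProps(newtonian_mu=_MU_NEWT),
        geometry=GeometryConfig(kind="channel", length=length, height=height,
                                nx=max(ny // 2, 8), ny=ny),
        waveform=WaveformParams(Q_mean=u_mean * height, steady=True),
        run=RunParams(n_cycles=0, thrombosis=False),
    )

    def exact(y):
        return 6.0 * u_mean * y * (height - y) / height ** 2

    return cfg, exact


def womersley_case(alpha: float = 5.0, ny: int = 64, height: float = 0.01,
                   u_mean: float = 0.01, u_osc: float = 0.01):
    """Oscillatory channel flow with its analytic velocity profile.

    The flow rate is Q(t) = (u_mean + u_osc cos ωt)·h with ω chosen so
    the Womersley number (on the half-height) equals ``alpha``.  The
    exact solution is the Poiseuille profile of the mean part plus the
    oscillatory Stokes-layer series; it is also imposed as the inlet
    profile, making it an exact solution on the whole channel.
    """
    nu = _MU_NEWT / _RHO
    H = height / 2.0
    omega = alpha ** 2 * nu / H ** 2
    T = 2.0 * np.pi / omega
    beta = np.sqrt(1j * omega / nu)
    Qosc = u_osc * height
    denom = 2.0 * H - 2.0 * np.tanh(beta * H) / beta
    Cc = Qosc / denom

    def exact(y, t):
        yy = np.asarray(y) - H
        osc = Cc * (1.0 - np.cosh(beta * yy) / np.cosh(beta * H))
        upois = 6.0 * u_mean * np.asarray(y) * (height - np.asarray(y)) / height ** 2
        return upois + np.real(osc * np.exp(1j * omega * t))

    cfg = CaseConfig(
        fluid=FluidProps(newtonian_mu=_MU_NEWT),
        geometry=GeometryConfig(kind="channel", length=0.02, height=height,
                                nx=12, ny=ny),
        waveform=WaveformParams(T=T, Q_mean=u_mean * height, steady=True),
        run=RunParams(n_cycles=0, thrombosis=False, theta=0.5),
    )
    return cfg, exact, T


def bfs_thrombosis_case(sim_time: float = 40.0, newtonian: bool = False,
                        u_mean: float = 0.2, resolution: float = 5e-4) -> CaseConfig:
    """Steady backward-facing-step thrombosis calibration configuration.

    Accelerated kinetics (coagulant diffusivity augmented ×150) under
    steady inflow; the default 40 s of simulated time maps to roughly
    90 min of real time through the augmentation factor.
    """
    T = 1.054
    geo = GeometryConfig(kind="backward_facing_step", inlet_height=0.004,
                         step_height=0.002, upstream_len=0.01,
                         downstream_len=0.024, resolution=resolution)
    fluid = FluidProps(newtonian_mu=_MU_NEWT) if newtonian else FluidProps()
    return CaseConfig(
        fluid=fluid,
        thrombosis=ThrombosisParams(f_aug=150.0),
        geometry=geo,
        waveform=WaveformParams(T=T, Q_mean=u_mean * geo.inlet_height, steady=True),
        run=RunParams(n_cycles=int(round(sim_time / T)), spin_cycles=1,
                      dt_velocity_factor=1.8, dt_safety=0.4),
    )


_DISSECTION_GEO = dict(lumen_height=0.008, fl_height=0.008, flap_thickness=0.002,
                       length=0.06)

# Mean true-lumen velocity: physiological aortic order (wall shear rate
# ≈ 6U/h ≈ 150 s⁻¹), which keeps the open lumen well above both shear
# gates — slower flows let the coagulant survive in the lumen interior.
_U_TL = 0.2


def dissection_s1_case(n_cycles: int = 20, resolution: float = 1e-3,
                       u_mean: float = _U_TL) -> CaseConfig:
    """Single proximal tear, 20-cycle protocol (admission-stage analog)."""
    return CaseConfig(
        geometry=GeometryConfig(kind="dissection", tear_positions=(0.010,),
                                tear_widths=(0.006,), resolution=resolution,
                                **_DISSECTION_GEO),
        waveform=WaveformParams(T=1.054, Q_mean=u_mean * 0.008,
                                systolic_fraction=0.45),
        run=RunParams(n_cycles=n_cycles, spin_cycles=2, dt_velocity_factor=1.5,
                      dt_safety=0.4),
    )


def dissection_s4_case(n_cycles: int = 20, resolution: float = 1e-3,
                       u_mean: float = _U_TL,
                       initial_wall_C: float = 250.0) -> CaseConfig:
    """Proximal + middle tear with the follow-up-stage restart protocol.

    The proximal false-lumen cap (up to the first tear) starts fully
    thrombosed with the wall flux shut off there; every wall cell is
    seeded with ``initial_wall_C`` (1% of the maximum coagulant reached
    in the single-tear run, measurable via that case), and coagulant
    production/consumption runs for two cycles before platelet binding
    is enabled.
    """
    return CaseConfig(
        geometry=GeometryConfig(kind="dissection",
                                tear_positions=(0.010, 0.038),
                                tear_widths=(0.006, 0.006),
                                resolution=resolution, **_DISSECTION_GEO),
        waveform=WaveformParams(T=1.054, Q_mean=u_mean * 0.008,
                                systolic_fraction=0.45),
        run=RunParams(n_cycles=n_cycles, spin_cycles=2, coagulant_pre_cycles=2,
                      initial_wall_C=initial_wall_C, pre_thrombosed_x=0.010,
                      dt_velocity_factor=1.5, dt_safety=0.4),
    )


# ---------------------------------------------------------------- benchmarks

def _steady_solve(cfg: CaseConfig, dt: float, steps: int):
    from .config import build_grid

    grid = build_grid(cfg.geometry)
    solver = FlowSolver(grid, cfg.fluid, cfg.thrombosis, cfg.waveform, dt,
                        theta=cfg.run.theta)
    state = FieldState.initial(grid, cfg.fluid, cfg.thrombosis)
    for _ in range(steps):
        solver.step_flow(state)
    return grid, solver, state


def poiseuille_benchmark(ny: int = 64, steps: int = 800, dt: float = 0.05) -> dict:
    """Errors of the steady channel solution against the parabolic profile."""
    cfg, exact = poiseuille_case(ny=ny)
    grid, solver, state = _steady_solve(cfg, dt, steps)
    i = int(0.8 * grid.nx)
    u_num = 0.5 * (state.u[i] + state.u[i + 1])
    u_ex = exact(grid.y_centers)
    prof_err = float(np.linalg.norm(u_num - u_ex) / np.linalg.norm(u_ex))
    center_err = float(abs(u_num.max() - u_ex.max()) / u_ex.max())
    _, wss = solver.shear_fields(state)
    mid = (grid.wall_i > 0.6 * grid.nx) & (grid.wall_i < 0.9 * grid.nx)
    h = cfg.geometry.height
    u_mean = cfg.waveform.Q_mean / h
    wss_ex = 6.0 * _MU_NEWT * u_mean / h
    wss_err = float(np.abs(wss[mid] - wss_ex).max() / wss_ex)
    div = solver.divergence(state.u, state.v)
    q_in = cfg.waveform.Q_mean
    mass_resid = float(np.abs(div[grid.mask]).sum() * grid.dx * grid.dy / q_in)
    return dict(profile_l2=prof_err, centerline=center_err, wss=wss_err,
                mass_residual=mass_resid)


def womersley_benchmark(alpha: float = 5.0, ny: int = 64,
                        steps_per_cycle: int = 600, n_cycles: int = 3) -> dict:
    """L2 error of the pulsatile channel solution against the analytic series."""
    from .config import build_grid

    cfg, exact, T = womersley_case(alpha=alpha, ny=ny)
    grid = build_grid(cfg.geometry)
    dt = T / steps_per_cycle
    y = grid.y_centers
    solver = FlowSolver(grid, cfg.fluid, cfg.thrombosis, cfg.waveform, dt,
                        theta=cfg.run.theta,
                        inlet_profile=lambda yy, t: exact(yy, t))
    state = FieldState.initial(grid, cfg.fluid, cfg.thrombosis)
    i = grid.nx // 2
    num = 0.0
    den = 0.0
    total = steps_per_cycle * n_cycles
    for k in range(total):
        solver.step_flow(state)
        if k >= total - steps_per_cycle and k % (steps_per_cycle // 8) == 0:
            u_num = 0.5 * (state.u[i] + state.u[i + 1])
            u_ex = exact(y, state.t)
            num += float(np.sum((u_num - u_ex) ** 2))
            den += float(np.sum(u_ex ** 2))
    return dict(l2=np.sqrt(num / den), alpha=alpha)


def stagnant_rt_benchmark(n_periods: float = 5.0) -> dict:
    """Residence time in a stagnant channel grows exactly like elapsed time."""
    grid = build_channel(0.02, 0.01, 8, 6)
    params = ThrombosisParams()
    fluid = FluidProps(newtonian_mu=_MU_NEWT)
    T = 1.054
    dt = T / 40.0
    ts = TransportSolver(grid, params, dt)
    state = FieldState.initial(grid, fluid, params)
    steps = int(round(n_periods * T / dt))
    for _ in range(steps):
        ts.update_residence_time(state)
    interior = grid.mask.copy()
    interior[0, :] = False          # inlet cells are held at RT = 0
    err = float(np.abs(state.RT[interior] / T - n_periods).max() / n_periods)
    return dict(rt_rel_err=err)


def pas_closed_form_error() -> dict:
    """Quadrature PAS vs the constant-load closed form C τ^b t^a."""
    p = PASParams()
    t = np.linspace(0.0, 1.0, 2001)
    worst = 0.0
    for tau0 in (0.5, 1.0, 2.0, 5.0):
        got = pas_index(t, np.full_like(t, tau0), p)
        ref = p.C * tau0 ** p.b * 1.0 ** p.a
        worst = max(worst, abs(got - ref) / ref)
    return dict(pas_rel_err=worst)


def run_benchmarks(fast: bool = False) -> dict:
    """The analytic verification suite (used by the ``validate`` command).

    Returns a dict of named error metrics with their pass thresholds.
    """
    ny = 32 if fast else 64
    checks = {}
    pb = poiseuille_benchmark(ny=ny, steps=400 if fast else 800)
    checks["poiseuille_profile_l2"] = (pb["profile_l2"], 5e-3)
    checks["poiseuille_wss"] = (pb["wss"], 1e-2)
    wb = womersley_benchmark(ny=ny, steps_per_cycle=300 if fast else 600,
                             n_cycles=2 if fast else 3)
    checks["womersley_l2"] = (wb["l2"], 2e-2)
    checks["stagnant_rt"] = (stagnant_rt_benchmark()["rt_rel_err"], 1e-3)
    checks["pas_closed_form"] = (pas_closed_form_error()["pas_rel_err"], 1e-3)
    return checks
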