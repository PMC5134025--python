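"""Incompressible pulsatile flow with clot feedback on a staggered grid.

The momentum equation is the Navier–Stokes system augmented with the
thrombosis feedback terms: a porosity-scaled transient (Brinkman
superficial-velocity form, ρ/ε ∂u/∂t), shear-thinning Quemada
viscosity, and a bound-platelet-dependent Darcy sink −k_M ϕ_BP(BP) u
that brings the velocity down to the percolation scale inside a formed
clot.  Time stepping is an incremental Chorin projection:

1. predictor — implicit (θ-scheme) variable-viscosity diffusion and
   implicit sink, explicit first-order upwind convection, old pressure
   gradient; solved per component by preconditioned CG;
2. pressure correction — a porosity-weighted Poisson problem, direct
   (sparse LU) solve, with zero-pressure Dirichlet at the outlet and
   Neumann everywhere else; the LU is refactorized only when the
   porosity field has drifted, and the face porosity used in the
   velocity correction is always the one inside the matrix, so the
   discrete divergence is zero to LU round-off at every step.

Inlet velocity is a plug profile scaled to the pulsatile waveform (or
an arbitrary profile callable, used by the analytic verification
cases); walls are rigid no-slip; the outlet holds zero relative
pressure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import cg, splu

from .constitutive import (
    FluidProps,
    ThrombosisParams,
    clot_porosity,
    quemada_viscosity,
    switch_up,
)
from .geometry import CaseGrid, WaveformParams, inflow_rate

__all__ = ["FieldState", "WallState", "FlowSolver", "cfl_dt", "update_tawss", "SolverError"]

# neighbour kinds for staggered-face stencils
_LINK, _KNOWN, _REFLECT, _ZGRAD, _INLET = 0, 1, 2, 3, 4


class SolverError(RuntimeError):
    """Raised when the flow solve fails (divergence, non-finite fields)."""


@dataclass
class FieldState:
    """All fields of the coupled model at one time level."""

    u: np.ndarray          # x-face velocities, (nx+1, ny), m/s
    v: np.ndarray          # y-face velocities, (nx, ny+1), m/s
    p: np.ndarray          # cell pressure, (nx, ny), Pa
    mu: np.ndarray         # cell viscosity, Pa s
    gamma: np.ndarray      # cell shear rate, 1/s
    eps: np.ndarray        # cell porosity
    RT: np.ndarray         # residence time, s
    RP_rel: np.ndarray     # resting platelets / inlet concentration
    AP_rel: np.ndarray     # activated platelets / inlet concentration
    C: np.ndarray          # coagulant, nmol/l
    BP: np.ndarray         # bound platelets, nmol/l
    t: float = 0.0

    FIELD_NAMES = ("u", "v", "p", "mu", "gamma", "eps", "RT", "RP_rel", "AP_rel", "C", "BP")

    @classmethod
    def initial(cls, grid: CaseGrid, fluid: FluidProps, params: ThrombosisParams,
                ap_background: float = 0.05) -> "FieldState":
        nx, ny = grid.nx, grid.ny
        z = lambda: np.zeros((nx, ny))
        m = grid.mask.astype(float)
        mu0 = quemada_viscosity(np.zeros((nx, ny)), fluid)
        if np.ndim(mu0) == 0:
            mu0 = np.full((nx, ny), float(mu0))
        return cls(
            u=np.zeros((nx + 1, ny)), v=np.zeros((nx, ny + 1)), p=z(),
            mu=mu0, gamma=z(), eps=np.ones((nx, ny)),
            RT=z(), RP_rel=1.0 * m, AP_rel=ap_background * m, C=z(), BP=z(),
        )

    def copy(self) -> "FieldState":
        return FieldState(**{n: getattr(self, n).copy() for n in self.FIELD_NAMES},
                          t=self.t)


@dataclass
class WallState:
    """Per-wall-face shear bookkeeping over cardiac cycles.

    ``tawss`` always holds the previous cycle's time average — the value
    the coagulant wall-flux law is allowed to see.
    """

    wss: np.ndarray
    integral: np.ndarray
    tawss: np.ndarray

    @classmethod
    def zeros(cls, n_wall: int) -> "WallState":
        return cls(np.zeros(n_wall), np.zeros(n_wall), np.zeros(n_wall))


def update_tawss(wall: WallState, wss_now: np.ndarray, dt: float,
                 at_cycle_end: bool, T: float) -> WallState:
    """Accumulate ∫|τ_w| dt; at a cycle boundary commit TAWSS = ∫/T and reset."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    wall.wss = np.asarray(wss_now, dtype=float)
    wall.integral = wall.integral + wall.wss * dt
    if at_cycle_end:
        wall.tawss = wall.integral / T
        wall.integral = np.zeros_like(wall.integral)
    return wall


def cfl_dt(state: FieldState, grid: CaseGrid, safety: float,
           fluid: FluidProps, params: ThrombosisParams) -> float:
    """Stability-limited time step: min of convective, viscous and sink limits."""
    if not 0 < safety <= 1:
        raise ValueError("safety must lie in (0, 1]")
    h = min(grid.dx, grid.dy)
    umax = max(np.abs(state.u).max(), np.abs(state.v).max())
    dt_conv = h / umax if umax > 0 else np.inf
    numax = (state.mu[grid.mask] / fluid.rho).max() if grid.mask.any() else 0.0
    dt_visc = h * h / (4.0 * numax) if numax > 0 else np.inf
    phi = switch_up(state.BP, params.BP_t, params.n_sw)
    phimax = phi[grid.mask].max() if grid.mask.any() else 0.0
    dt_sink = (fluid.rho * state.eps[grid.mask].min() / (params.k_M * phimax)
               if phimax > 0 and params.k_M > 0 else np.inf)
    return safety * min(dt_conv, dt_visc, dt_sink)


class _FaceSystem:
    """Neighbour bookkeeping for one staggered velocity component.

    Precomputes, per active face and per stencil direction, the flat
    index to read the neighbour value from, a sign (−1 for no-slip
    reflection ghosts) and a kind code controlling how the implicit
    matrix treats that direction.
    """

    def __init__(self, own_flat: np.ndarray, shape: tuple[int, int]):
        self.shape = shape
        self.own = own_flat
        self.n = own_flat.size
        self.row_of = -np.ones(shape[0] * shape[1], dtype=np.int64)
        self.row_of[own_flat] = np.arange(self.n)
        self.dirs: dict[str, dict[str, np.ndarray]] = {}

    def add_dir(self, name, vnbr, sign, kind):
        self.dirs[name] = {"vnbr": vnbr, "sign": sign.astype(float), "kind": kind,
                           "nbr_row": self.row_of[vnbr]}

    def values(self, field_flat: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name, d in self.dirs.items():
            out[name] = d["sign"] * field_flat[d["vnbr"]]
        return out

    def assemble(self, diag0: np.ndarray, coefs: dict[str, np.ndarray],
                 field_flat: np.ndarray):
        """Backward-Euler style operator: (diag0 + Σ f·c) u − Σ_link c u_nbr.

        Returns the sparse matrix and the RHS contribution of Dirichlet
        (inlet) neighbours.
        """
        rows = [np.arange(self.n)]
        cols = [np.arange(self.n)]
        diag = diag0.copy()
        rhs = np.zeros(self.n)
        data = [None]  # placeholder for diag
        for name, d in self.dirs.items():
            c = coefs[name]
            kind = d["kind"]
            fac = np.ones(self.n)
            fac[kind == _ZGRAD] = 0.0
            fac[kind == _REFLECT] = 2.0
            diag += fac * c
            link = kind == _LINK
            rows.append(np.flatnonzero(link))
            cols.append(d["nbr_row"][link])
            data.append(-c[link])
            inl = kind == _INLET
            if inl.any():
                rhs[inl] += c[inl] * field_flat[d["vnbr"][inl]]
        data[0] = diag
        A = csr_matrix((np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                       shape=(self.n, self.n))
        return A, rhs

    def explicit_diffusion(self, coefs, vals, own_vals):
        out = np.zeros(self.n)
        for name, d in self.dirs.items():
            c = coefs[name].copy()
            c[d["kind"] == _ZGRAD] = 0.0
            out += c * (vals[name] - own_vals)
        return out


def _corner_avg(cell_field: np.ndarray) -> np.ndarray:
    """Average a (nx, ny) cell field to the (nx+1, ny+1) corners (edge-padded)."""
    pad = np.pad(cell_field, 1, mode="edge")
    return 0.25 * (pad[:-1, :-1] + pad[1:, :-1] + pad[:-1, 1:] + pad[1:, 1:])


class FlowSolver:
    """Time-marches the momentum/continuity system on one :class:`CaseGrid`.

    Parameters
    ----------
    grid, fluid, params, waveform
        Geometry, rheology, thrombosis constants and the inlet waveform.
    dt
        Fixed time step, s.  A fixed step keeps the pressure operator
        factorization valid across steps.
    theta
        Implicitness of the viscous term (1 = backward Euler, 0.5 =
        Crank–Nicolson; the sink is always fully implicit).
    inlet_profile
        Optional ``f(y_centers, t) -> u`` overriding the plug profile
        (used by the Womersley verification case).
    """

    def __init__(self, grid: CaseGrid, fluid: FluidProps, params: ThrombosisParams,
                 waveform: WaveformParams, dt: float, theta: float = 1.0,
                 inlet_profile: Callable | None = None, eps_refactor_tol: float = 5e-3):
        self.grid = grid
        self.fluid = fluid
        self.params = params
        self.waveform = waveform
        self.dt = float(dt)
        self.theta = float(theta)
        self.inlet_profile = inlet_profile
        self.eps_refactor_tol = eps_refactor_tol
        self._build_u_system()
        self._build_v_system()
        self._build_p_maps()
        self._eps_lag = None   # cell porosity baked into the pressure operator
        self._plu = None

    # ------------------------------------------------------------------ setup

    def _build_u_system(self) -> None:
        g = self.grid
        nx, ny = g.nx, g.ny
        shape = (nx + 1, ny)
        act = g.u_active
        own = np.flatnonzero(act.ravel())
        sysm = _FaceSystem(own, shape)
        I, J = np.unravel_index(own, shape)
        self._u_ij = (I, J)

        def flat(i, j):
            return i * ny + j

        solid = ~g.mask

        # east / west neighbours (same row of faces)
        for name, di in (("E", +1), ("W", -1)):
            ni = I + di
            vnbr = flat(ni, J)
            sign = np.ones(own.size)
            kind = np.full(own.size, _KNOWN, dtype=np.int8)
            kind[act.ravel()[vnbr]] = _LINK
            if di > 0:
                kind[g.u_outlet.ravel()[vnbr]] = _ZGRAD
            else:
                kind[g.u_inlet.ravel()[vnbr]] = _INLET
            sysm.add_dir(name, vnbr, sign, kind)

        # north / south neighbours (tangential wall handling)
        for name, dj in (("N", +1), ("S", -1)):
            nj = J + dj
            inb = (nj >= 0) & (nj < ny)
            njc = np.clip(nj, 0, ny - 1)
            vnbr = flat(I, njc)
            kind = np.full(own.size, _KNOWN, dtype=np.int8)
            kind[~inb] = _REFLECT
            lnk = inb & act.ravel()[vnbr]
            kind[lnk] = _LINK
            # both cells beside the neighbour face solid -> wall plane between
            # rows: reflect ghost
            both_solid = inb & solid[np.clip(I - 1, 0, nx - 1), njc] & solid[np.clip(I, 0, nx - 1), njc]
            # I ranges 1..nx-1 for active faces so I-1, I are valid cells
            kind[both_solid & ~lnk] = _REFLECT
            refl = kind == _REFLECT
            vnbr = np.where(refl, own, vnbr)
            sign = np.where(refl, -1.0, 1.0)
            sysm.add_dir(name, vnbr, sign, kind)
        self.usys = sysm

    def _build_v_system(self) -> None:
        g = self.grid
        nx, ny = g.nx, g.ny
        shape = (nx, ny + 1)
        act = g.v_active
        own = np.flatnonzero(act.ravel())
        sysm = _FaceSystem(own, shape)
        I, J = np.unravel_index(own, shape)
        self._v_ij = (I, J)
        solid = ~g.mask

        def flat(i, j):
            return i * (ny + 1) + j

        for name, dj in (("N", +1), ("S", -1)):
            nj = J + dj            # within 0..ny for active j in 1..ny-1
            vnbr = flat(I, nj)
            kind = np.full(own.size, _KNOWN, dtype=np.int8)
            kind[act.ravel()[vnbr]] = _LINK
            sysm.add_dir(name, vnbr, np.ones(own.size), kind)

        out_rows = g.outlet_j
        for name, di in (("E", +1), ("W", -1)):
            ni = I + di
            inb = (ni >= 0) & (ni < nx)
            nic = np.clip(ni, 0, nx - 1)
            vnbr = flat(nic, J)
            kind = np.full(own.size, _KNOWN, dtype=np.int8)
            lnk = inb & act.ravel()[vnbr]
            kind[lnk] = _LINK
            both_solid = inb & solid[nic, J - 1] & solid[nic, np.clip(J, 0, ny - 1)]
            kind[both_solid & ~lnk] = _REFLECT
            if di > 0:
                at_out = ~inb & out_rows[J - 1] & out_rows[np.clip(J, 0, ny - 1)]
                kind[~inb] = _REFLECT
                kind[at_out] = _ZGRAD
            else:
                kind[~inb] = _REFLECT   # inlet plane or closed end: v = 0 there
            refl = kind == _REFLECT
            zg_self = (kind == _ZGRAD) & ~inb
            vnbr = np.where(refl | zg_self, own, vnbr)
            sign = np.where(refl, -1.0, 1.0)
            sysm.add_dir(name, vnbr, sign, kind)
        self.vsys = sysm

    def _build_p_maps(self) -> None:
        g = self.grid
        self._pidx = -np.ones((g.nx, g.ny), dtype=np.int64)
        cells = np.flatnonzero(g.mask.ravel())
        self._pidx.ravel()[...] = -1
        self._pidx[g.mask] = np.arange(cells.size)
        self._n_p = cells.size
        self._pI, self._pJ = np.nonzero(g.mask)

    # --------------------------------------------------------------- pressure

    def _face_eps(self, eps: np.ndarray):
        g = self.grid
        epu = np.ones((g.nx + 1, g.ny))
        epu[1:-1] = 0.5 * (eps[:-1] + eps[1:])
        epu[0] = eps[0]
        epu[-1] = eps[-1]
        epv = np.ones((g.nx, g.ny + 1))
        epv[:, 1:-1] = 0.5 * (eps[:, :-1] + eps[:, 1:])
        epv[:, 0] = eps[:, 0]
        epv[:, -1] = eps[:, -1]
        return epu, epv

    def _factor_pressure(self, eps: np.ndarray) -> None:
        g, dt, rho = self.grid, self.dt, self.fluid.rho
        self._eps_lag = eps.copy()
        self._epsf_u, self._epsf_v = self._face_eps(eps)
        I, J = self._pI, self._pJ
        n = self._n_p
        rows, cols, data = [], [], []
        diag = np.zeros(n)
        cx = dt / (rho * g.dx * g.dx)
        cy = dt / (rho * g.dy * g.dy)

        # one pass per face direction; outlet faces add a Dirichlet-ghost term
        for di, dj, faces_active, faces_out, cf, eff in (
            (+1, 0, g.u_active[1:, :], g.u_outlet[1:, :], cx, self._epsf_u[1:, :]),
            (-1, 0, g.u_active[:-1, :], g.u_inlet[:-1, :] & False, cx, self._epsf_u[:-1, :]),
            (0, +1, g.v_active[:, 1:], np.zeros_like(g.mask), cy, self._epsf_v[:, 1:]),
            (0, -1, g.v_active[:, :-1], np.zeros_like(g.mask), cy, self._epsf_v[:, :-1]),
        ):
            fa = faces_active[I, J]
            c = cf * eff[I, J]
            ni = I + di
            nj = J + dj
            valid = fa
            nrow = np.full(n, -1, dtype=np.int64)
            okn = valid & (ni >= 0) & (ni < g.nx) & (nj >= 0) & (nj < g.ny)
            nrow[okn] = self._pidx[ni[okn], nj[okn]]
            diag += np.where(valid, c, 0.0)
            link = nrow >= 0
            rows.append(np.flatnonzero(link))
            cols.append(nrow[link])
            data.append(-c[link])
            if di == +1:
                out = faces_out[I, J]
                diag += np.where(out, 2.0 * c, 0.0)
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        data.append(diag)
        A = csr_matrix((np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n, n)).tocsc()
        self._plu = splu(A)

    # ------------------------------------------------------------------- step

    def inlet_velocity(self, t: float) -> np.ndarray:
        """Inlet u over the open rows at time t (plug unless overridden)."""
        g = self.grid
        jj = np.flatnonzero(g.inlet_j & g.mask[0])
        if self.inlet_profile is not None:
            return np.asarray(self.inlet_profile(g.y_centers[jj], t), dtype=float)
        q = inflow_rate(t, self.waveform)
        return np.full(jj.size, q / g.inlet_width)

    def shear_fields(self, state: FieldState):
        """Cell shear-rate magnitude γ̇ = √(2 D:D) and wall-face WSS."""
        g = self.grid
        u, v = state.u, state.v
        dudx = (u[1:] - u[:-1]) / g.dx
        dvdy = (v[:, 1:] - v[:, :-1]) / g.dy
        # corner cross-derivatives with no-slip reflection at domain edges
        upad = np.concatenate([-u[:, :1], u, -u[:, -1:]], axis=1)
        dudy_c = (upad[:, 1:] - upad[:, :-1]) / g.dy        # (nx+1, ny+1)
        vpad = np.concatenate([-v[:1], v, -v[-1:]], axis=0)
        dvdx_c = (vpad[1:] - vpad[:-1]) / g.dx              # (nx+1, ny+1)
        cross = dudy_c + dvdx_c
        cross_cc = 0.25 * (cross[:-1, :-1] + cross[1:, :-1] + cross[:-1, 1:] + cross[1:, 1:])
        gamma = np.sqrt(2.0 * dudx ** 2 + 2.0 * dvdy ** 2 + cross_cc ** 2)
        gamma[~g.mask] = 0.0

        mu = state.mu
        i, j, ax = g.wall_i, g.wall_j, g.wall_axis
        ucc = 0.5 * (u[i, j] + u[i + 1, j])
        vcc = 0.5 * (v[i, j] + v[i, j + 1])
        tang = np.where(ax == 1, ucc, vcc)
        dist = np.where(ax == 1, 0.5 * g.dy, 0.5 * g.dx)
        wss = mu[i, j] * np.abs(tang) / dist
        return gamma, wss

    def update_material(self, state: FieldState) -> None:
        """Refresh γ̇, μ(γ̇) and ε(BP) from the current velocity/BP fields."""
        gamma, wss = self.shear_fields(state)
        self.last_wss = wss
        state.gamma = gamma
        mu = quemada_viscosity(gamma, self.fluid)
        state.mu = mu
        eps = clot_porosity(state.BP, self.params)
        eps[~self.grid.mask] = 1.0
        state.eps = eps

    def _visc_coefs(self, mu: np.ndarray, sysm: _FaceSystem, comp: str):
        g = self.grid
        mupad = np.pad(mu, 1, mode="edge")
        mu_c = _corner_avg(mu)
        I, J = (self._u_ij if comp == "u" else self._v_ij)
        if comp == "u":
            # u-face (i,j): E cell (i,j), W cell (i-1,j); N/S corner viscosities
            cE = mupad[I + 1, J + 1]                  # cell (I, J)
            cW = mupad[I, J + 1]                      # cell (I-1, J)
            cN = mu_c[I, J + 1]
            cS = mu_c[I, J]
            return {"E": cE / g.dx ** 2, "W": cW / g.dx ** 2,
                    "N": cN / g.dy ** 2, "S": cS / g.dy ** 2}
        else:
            cN = mupad[I + 1, J + 1]                  # cell (I, J)
            cS = mupad[I + 1, J]                      # cell (I, J-1)
            cE = mu_c[I + 1, J]
            cW = mu_c[I, J]
            return {"E": cE / g.dx ** 2, "W": cW / g.dx ** 2,
                    "N": cN / g.dy ** 2, "S": cS / g.dy ** 2}

    def _convection_u(self, u, v, vals, uP):
        g = self.grid
        I, J = self._u_ij
        vat = 0.25 * (v[I - 1, J] + v[I - 1, J + 1] + v[I, J] + v[I, J + 1])
        dudx = np.where(uP >= 0, (uP - vals["W"]) / g.dx, (vals["E"] - uP) / g.dx)
        dudy = np.where(vat >= 0, (uP - vals["S"]) / g.dy, (vals["N"] - uP) / g.dy)
        return uP * dudx + vat * dudy

    def _convection_v(self, u, v, vals, vP):
        g = self.grid
        I, J = self._v_ij
        uat = 0.25 * (u[I, J - 1] + u[I + 1, J - 1] + u[I, J] + u[I + 1, J])
        dvdx = np.where(uat >= 0, (vP - vals["W"]) / g.dx, (vals["E"] - vP) / g.dx)
        dvdy = np.where(vP >= 0, (vP - vals["S"]) / g.dy, (vals["N"] - vP) / g.dy)
        return uat * dvdx + vP * dvdy

    def _solve_spd(self, A, b, x0):
        x, info = cg(A, b, x0=x0, rtol=1e-10, atol=0.0, maxiter=2000)
        if info != 0:
            x, info = cg(A, b, x0=x, rtol=1e-8, atol=1e-300, maxiter=5000)
            if info != 0:
                raise SolverError(f"CG failed to converge (info={info})")
        return x

    def divergence(self, u, v):
        g = self.grid
        div = (u[1:] - u[:-1]) / g.dx + (v[:, 1:] - v[:, :-1]) / g.dy
        div[~g.mask] = 0.0
        return div

    def step_flow(self, state: FieldState) -> FieldState:
        """Advance velocity and pressure by one time step."""
        g, dt, rho = self.grid, self.dt, self.fluid.rho
        th = self.theta
        self.update_material(state)

        if self._plu is None or np.abs(state.eps - self._eps_lag).max() > self.eps_refactor_tol:
            self._factor_pressure(state.eps)

        t_new = state.t + dt
        u = state.u.copy()
        v = state.v.copy()
        jj = np.flatnonzero(g.inlet_j & g.mask[0])
        u[0, jj] = self.inlet_velocity(t_new)

        phi = switch_up(state.BP, self.params.BP_t, self.params.n_sw)
        phipad = np.pad(phi, 1, mode="edge")
        epad = np.pad(self._eps_lag, 1, mode="edge")

        uflat = u.ravel()
        vflat = v.ravel()

        # ---- u predictor
        Iu, Ju = self._u_ij
        uP = uflat[self.usys.own]
        coefs = self._visc_coefs(state.mu, self.usys, "u")
        vals = self.usys.values(uflat)
        eps_f = 0.5 * (epad[Iu, Ju + 1] + epad[Iu + 1, Ju + 1])
        phi_f = 0.5 * (phipad[Iu, Ju + 1] + phipad[Iu + 1, Ju + 1])
        trans = rho / (eps_f * dt)
        diag0 = trans + self.params.k_M * phi_f
        A, rhs_bc = self.usys.assemble(diag0, {k: th * c for k, c in coefs.items()}, uflat)
        conv = self._convection_u(u, v, vals, uP)
        gradp = (state.p[Iu, Ju] - state.p[Iu - 1, Ju]) / g.dx
        rhs = trans * uP - rho * conv - gradp + th * rhs_bc
        if th < 1.0:
            rhs += (1.0 - th) * self.usys.explicit_diffusion(coefs, vals, uP)
        ustar = self._solve_spd(A, rhs, uP)
        u.ravel()[self.usys.own] = ustar

        # ---- v predictor
        Iv, Jv = self._v_ij
        vP = vflat[self.vsys.own]
        coefs = self._visc_coefs(state.mu, self.vsys, "v")
        vals = self.vsys.values(vflat)
        eps_f = 0.5 * (epad[Iv + 1, Jv] + epad[Iv + 1, Jv + 1])
        phi_f = 0.5 * (phipad[Iv + 1, Jv] + phipad[Iv + 1, Jv + 1])
        trans = rho / (eps_f * dt)
        diag0 = trans + self.params.k_M * phi_f
        A, rhs_bc = self.vsys.assemble(diag0, {k: th * c for k, c in coefs.items()}, vflat)
        conv = self._convection_v(u, v, vals, vP)
        gradp = (state.p[Iv, Jv] - state.p[Iv, Jv - 1]) / g.dy
        rhs = trans * vP - rho * conv - gradp + th * rhs_bc
        if th < 1.0:
            rhs += (1.0 - th) * self.vsys.explicit_diffusion(coefs, vals, vP)
        vstar = self._solve_spd(A, rhs, vP)
        v.ravel()[self.vsys.own] = vstar

        # outlet faces: zero-gradient predictor value
        oj = np.flatnonzero(g.outlet_j & g.mask[-1])
        u[g.nx, oj] = u[g.nx - 1, oj]

        # ---- pressure correction
        div = self.divergence(u, v)
        dp = self._plu.solve(-div[self._pI, self._pJ])
        dpf = np.zeros((g.nx, g.ny))
        dpf[self._pI, self._pJ] = dp

        cu = dt * self._epsf_u / (rho * g.dx)
        cv = dt * self._epsf_v / (rho * g.dy)
        act = g.u_active
        du = np.zeros_like(u)
        du[1:-1, :] = cu[1:-1, :] * (dpf[1:, :] - dpf[:-1, :])
        u[act] -= du[act]
        u[g.nx, oj] += 2.0 * cu[g.nx, oj] * dpf[g.nx - 1, oj]
        dv = np.zeros_like(v)
        dv[:, 1:-1] = cv[:, 1:-1] * (dpf[:, 1:] - dpf[:, :-1])
        v[g.v_active] -= dv[g.v_active]

        p = state.p + dpf
        if not (np.isfinite(u).all() and np.isfinite(v).all() and np.isfinite(p).all()):
            raise SolverError(f"non-finite fields at t={t_new:.6f}")

        state.u, state.v, state.p = u, v, p
        state.t = t_new
        return state
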