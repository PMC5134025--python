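"""Convection–diffusion–reaction transport of the model species.

Four Eulerian scalars are transported: residence time RT (source +1 per
unit time, zero at the inlet), resting and activated platelets RP/AP
(relative to the inlet platelet concentration: RP_rel = 1 and
AP_rel = 0.05 at the inlet, the 5% background activation level), and
the coagulant C (zero at the inlet, released at low-TAWSS wall faces as
a Neumann flux, produced/consumed in the bulk).  Bound platelets BP are
a non-transported (bound-phase) field integrated pointwise.

Discretization: explicit second-order upwind (MUSCL, van Leer limiter)
advection, implicit (backward Euler) diffusion with porosity-scaled
storage ∂(εφ)/∂t, solved by preconditioned CG.  Coagulant convection is
scaled by the saturation switch on the cycle-averaged shear rate, which
turns transport diffusion-limited inside low-shear (reaction-zone)
pockets.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import cg

from .constitutive import (
    ThrombosisParams,
    bound_platelet_source,
    coagulant_bulk_source,
    coagulant_wall_flux,
    switch_up,
)
from .flow import FieldState, SolverError, WallState
from .geometry import CaseGrid

__all__ = ["TransportSolver", "cycle_averaged_shear"]


def cycle_averaged_shear(samples) -> np.ndarray:
    """Arithmetic time average of shear-rate snapshots over one cycle."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim < 1 or arr.shape[0] == 0:
        raise ValueError("need at least one shear-rate sample")
    return arr.mean(axis=0)


class TransportSolver:
    """Scalar transport on the masked staggered grid at a fixed time step."""

    def __init__(self, grid: CaseGrid, params: ThrombosisParams, dt: float,
                 ap_inlet: float = 0.05):
        self.grid = grid
        self.params = params
        self.dt = float(dt)
        self.ap_inlet = ap_inlet
        self.clip_events = 0
        # cycle-averaged shear rate seen by the kinetics; refreshed by the
        # growth coupler at cycle boundaries (spin-up average before that)
        self.gamma_avg = np.zeros((grid.nx, grid.ny))
        # eligibility mask for BP deposition (wall/bulk/neighbour gates)
        self.eligible = np.zeros((grid.nx, grid.ny), bool)
        self._prep_stencil()
        # map wall faces to their fluid cells for the coagulant flux source
        g = grid
        self._wall_src = g.wall_len / (g.dx * g.dy)

    # ------------------------------------------------------------- diffusion

    def _prep_stencil(self) -> None:
        g = self.grid
        m = g.mask
        nx, ny = g.nx, g.ny
        self._cI, self._cJ = np.nonzero(m)
        n = self._cI.size
        self.n_cells = n
        idx = -np.ones((nx, ny), dtype=np.int64)
        idx[m] = np.arange(n)
        self._idx = idx
        self._links = []          # (nbr_row, invdx2) per direction, masked rows
        self._inlet_rows = None
        inlet_cells = np.zeros((nx, ny), bool)
        inlet_cells[0, g.inlet_j] = m[0, g.inlet_j]
        for di, dj, inv2 in ((1, 0, 1 / g.dx ** 2), (-1, 0, 1 / g.dx ** 2),
                             (0, 1, 1 / g.dy ** 2), (0, -1, 1 / g.dy ** 2)):
            ni, nj = self._cI + di, self._cJ + dj
            ok = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
            nrow = np.full(n, -1, dtype=np.int64)
            nrow[ok] = idx[ni[ok], nj[ok]]
            self._links.append((nrow, inv2))
        self._is_inlet_cell = inlet_cells[self._cI, self._cJ]
        self._inv_dx2 = 1 / g.dx ** 2

    def _diffuse_implicit(self, rhs_cells: np.ndarray, D: float, eps_cells: np.ndarray,
                          inlet_value: float | None, x0: np.ndarray) -> np.ndarray:
        """Solve (ε/dt) φ − ∇·(D∇φ) = rhs with Neumann walls/outlet and
        Dirichlet inlet (ghost at the inlet face)."""
        n = self.n_cells
        diag = eps_cells / self.dt
        rows = [np.arange(n)]
        cols = [np.arange(n)]
        data = [None]
        rhs = rhs_cells.copy()
        if D > 0:
            dtmp = np.zeros(n)
            for nrow, inv2 in self._links:
                link = nrow >= 0
                dtmp[link] += D * inv2
                rows.append(np.flatnonzero(link))
                cols.append(nrow[link])
                data.append(np.full(link.sum(), -D * inv2))
            diag = diag + dtmp
            if inlet_value is not None:
                c = 2.0 * D * self._inv_dx2
                diag = diag + np.where(self._is_inlet_cell, c, 0.0)
                rhs[self._is_inlet_cell] += c * inlet_value
        data[0] = diag
        A = csr_matrix((np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n, n))
        x, info = cg(A, rhs, x0=x0, rtol=1e-12, atol=0.0, maxiter=2000)
        if info != 0:
            raise SolverError(f"scalar diffusion CG failed (info={info})")
        return x

    # -------------------------------------------------------------- advection

    def _advect(self, phi: np.ndarray, u: np.ndarray, v: np.ndarray,
                inlet_value: float, face_scale_u: np.ndarray | None = None,
                face_scale_v: np.ndarray | None = None) -> np.ndarray:
        """−∇·(uφ) by MUSCL/van Leer; returns the cell tendency (1/s units of φ)."""
        g = self.grid
        nx, ny = g.nx, g.ny
        m = g.mask

        def limited_face(phiC, phiD, phiU, lowres):
            dd = phiD - phiC
            du = phiC - phiU
            denom = np.where(dd == 0.0, 1.0, dd)
            r = du / denom
            psi = (r + np.abs(r)) / (1.0 + np.abs(r))
            psi = np.where((dd == 0.0) | lowres, 0.0, psi)
            return phiC + 0.5 * psi * dd

        P = np.pad(phi, 2, mode="edge")
        fluid = np.pad(m, 2, mode="constant", constant_values=False)

        # ---- x faces, shape (nx+1, ny)
        uf = u.copy()
        if face_scale_u is not None:
            uf = uf * face_scale_u
        i = np.arange(nx + 1)[:, None]
        j = np.arange(ny)[None, :]
        # cells left of face: i-1 ; right: i  (padded offset +2)
        phiL = P[i + 1, j + 2]
        phiR = P[i + 2, j + 2]
        phiLL = P[i, j + 2]
        phiRR = P[i + 3, j + 2]
        okLL = fluid[i, j + 2]
        okRR = fluid[i + 3, j + 2]
        face_pos = limited_face(phiL, phiR, phiLL, ~okLL)
        face_neg = limited_face(phiR, phiL, phiRR, ~okRR)
        phif = np.where(uf >= 0, face_pos, face_neg)
        # boundary faces: inlet carries the inlet concentration on inflow
        inlet_face = g.u_inlet
        phif = np.where(inlet_face & (uf >= 0), inlet_value, phif)
        Fx = uf * phif

        # ---- y faces, shape (nx, ny+1)
        vf = v.copy()
        if face_scale_v is not None:
            vf = vf * face_scale_v
        i = np.arange(nx)[:, None]
        j = np.arange(ny + 1)[None, :]
        phiB = P[i + 2, j + 1]
        phiT = P[i + 2, j + 2]
        phiBB = P[i + 2, j]
        phiTT = P[i + 2, j + 3]
        okBB = fluid[i + 2, j]
        okTT = fluid[i + 2, j + 3]
        face_pos = limited_face(phiB, phiT, phiBB, ~okBB)
        face_neg = limited_face(phiT, phiB, phiTT, ~okTT)
        phif_y = np.where(vf >= 0, face_pos, face_neg)
        Fy = vf * phif_y

        div = (Fx[1:] - Fx[:-1]) / g.dx + (Fy[:, 1:] - Fy[:, :-1]) / g.dy
        div[~m] = 0.0
        return -div

    # ------------------------------------------------------------ species ops

    def _clip(self, arr: np.ndarray, name: str) -> np.ndarray:
        neg = arr < 0
        if neg.any():
            self.clip_events += int(neg.sum())
            arr = np.where(neg, 0.0, arr)
        return arr

    def _update_scalar(self, phi, state: FieldState, D, inlet_value, source,
                       face_scale_u=None, face_scale_v=None):
        g = self.grid
        eps_c = state.eps[self._cI, self._cJ]
        adv = self._advect(phi, state.u, state.v, inlet_value,
                           face_scale_u, face_scale_v)
        rhs = eps_c * phi[self._cI, self._cJ] / self.dt \
            + adv[self._cI, self._cJ] + source[self._cI, self._cJ]
        if D * self.dt / min(g.dx, g.dy) ** 2 < 1e-2:
            # diffusion number far below stability: explicit is exact enough
            new = (rhs + self._explicit_diffusion(phi, D, inlet_value)) \
                * self.dt / eps_c
        else:
            new = self._diffuse_implicit(rhs, D, eps_c, inlet_value,
                                         phi[self._cI, self._cJ])
        out = np.zeros_like(phi)
        out[self._cI, self._cJ] = new
        return out

    def _explicit_diffusion(self, phi, D, inlet_value):
        if D == 0.0:
            return 0.0
        pc = phi[self._cI, self._cJ]
        out = np.zeros(self.n_cells)
        for nrow, inv2 in self._links:
            link = nrow >= 0
            out[link] += D * inv2 * (pc[nrow[link]] - pc[link])
        if inlet_value is not None:
            c = 2.0 * D * self._inv_dx2
            out[self._is_inlet_cell] += c * (inlet_value - pc[self._is_inlet_cell])
        return out

    def update_residence_time(self, state: FieldState) -> FieldState:
        """RT transport with unit source: ∂(εRT)/∂t + ∇·(uRT) = ∇·(D∇RT) + ε."""
        src = state.eps * self.grid.mask
        rt = self._update_scalar(state.RT, state, self.params.D_RT, 0.0, src)
        state.RT = self._clip(rt, "RT")
        return state

    def update_platelets(self, state: FieldState) -> FieldState:
        """Advect/diffuse RP_rel and AP_rel; consume where platelets bind.

        The binding sink converts the local platelet pool to BP at
        rate/N_pool (relative units), drawing activated platelets first.
        """
        p = self.params
        rate = bound_platelet_source(state.AP_rel, state.C, self.gamma_avg, p)
        rate = np.where(self.eligible, rate, 0.0)
        sink_rel = rate / p.N_pool
        ap_sink = np.minimum(sink_rel, state.AP_rel / self.dt)
        rp_sink = np.minimum(sink_rel - ap_sink, state.RP_rel / self.dt)
        ap = self._update_scalar(state.AP_rel, state, p.D_p, self.ap_inlet, -ap_sink)
        rp = self._update_scalar(state.RP_rel, state, p.D_p, 1.0, -rp_sink)
        state.AP_rel = self._clip(ap, "AP_rel")
        state.RP_rel = self._clip(rp, "RP_rel")
        return state

    def update_coagulant(self, state: FieldState, wall: WallState) -> FieldState:
        """Coagulant with shear-gated convection, wall flux and bulk kinetics.

        Convection is scaled by ϕ_γ̇↑(γ̇_avg): in low-shear pockets the
        species moves by (augmented) diffusion only.  The wall flux uses
        the previous cycle's TAWSS and shuts off over complete thrombus.
        """
        g, p = self.grid, self.params
        s_cell = switch_up(self.gamma_avg, p.gamma_t, p.n_sw)
        spad = np.pad(s_cell, 1, mode="edge")
        fsu = 0.5 * (spad[:-1, 1:-1] + spad[1:, 1:-1])       # (nx+1, ny)
        fsv = 0.5 * (spad[1:-1, :-1] + spad[1:-1, 1:])       # (nx, ny+1)
        src = coagulant_bulk_source(state.C, state.BP, self.gamma_avg, p)
        src = np.where(g.mask, src, 0.0)
        flux = coagulant_wall_flux(wall.tawss, state.BP[g.wall_i, g.wall_j], p)
        wall_src = np.zeros_like(state.C)
        np.add.at(wall_src, (g.wall_i, g.wall_j), flux * self._wall_src)
        c = self._update_scalar(state.C, state, p.D_c_eff, 0.0, src + wall_src,
                                face_scale_u=fsu, face_scale_v=fsv)
        state.C = self._clip(c, "C")
        return state

    def update_bound_platelets(self, state: FieldState) -> np.ndarray:
        """Grow the immobile BP field where the deposition gates allow.

        Returns the deposition-rate field (nmol l⁻¹ s⁻¹) so the caller
        can audit which gate admitted each deposition event.  BP is
        monotone non-decreasing.
        """
        p = self.params
        rate = bound_platelet_source(state.AP_rel, state.C, self.gamma_avg, p)
        rate = np.where(self.eligible & self.grid.mask, rate, 0.0)
        state.BP = state.BP + self.dt * rate
        return rate
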