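"""Structured 2D staggered (MAC) grids for the idealized case geometries.

Three planar geometries are supported: a straight channel (solver
verification), a backward-facing step (thrombosis calibration under
steady flow) and an idealized aortic dissection — two parallel channels,
a *true lumen* (TL) open at inlet and outlet and a *false lumen* (FL)
closed at both ends, separated by a solid flap pierced by one or two
tears.  Solid parts are embedded in the Cartesian grid by cell masking;
all region intervals are half-open ``[start, end)`` on cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constitutive import ConfigurationError

__all__ = [
    "CaseGrid",
    "WaveformParams",
    "build_channel",
    "build_backward_facing_step",
    "build_idealized_dissection",
    "inflow_rate",
    "womersley_number",
]


@dataclass
class CaseGrid:
    """A masked uniform Cartesian grid with boundary tags and regions.

    ``mask`` is True on fluid cells, shape (nx, ny) with x varying along
    axis 0.  ``inlet_j`` / ``outlet_j`` flag the rows (at i = 0 and
    i = nx-1) whose boundary faces are open; every other solid/fluid or
    domain-boundary face is a rigid no-slip wall.  ``regions`` maps
    names (``true_lumen``, ``false_lumen``, ``tear_1`` ...) to boolean
    cell masks; ``meta`` carries the generating dimensions.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    mask: np.ndarray
    inlet_j: np.ndarray          # bool (ny,): inlet faces at i = 0
    outlet_j: np.ndarray         # bool (ny,): outlet faces at i = nx-1
    regions: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.nx, self.ny):
            raise ConfigurationError("mask shape must be (nx, ny)")
        if not (self.inlet_j & self.mask[0]).any():
            raise ConfigurationError("grid has no inlet faces")
        if not (self.outlet_j & self.mask[-1]).any():
            raise ConfigurationError("grid has no outlet faces")
        for name, reg in self.regions.items():
            if np.any(reg & ~self.mask):
                raise ConfigurationError(f"region {name!r} includes solid cells")
        self._check_connectivity()
        self._build_faces()

    def _check_connectivity(self) -> None:
        labels, _ = ndimage.label(self.mask)
        inlet_labels = set(labels[0, self.inlet_j & self.mask[0]])
        fluid_labels = set(labels[self.mask])
        if fluid_labels - inlet_labels:
            raise ConfigurationError("fluid cells not reachable from the inlet")

    def _build_faces(self) -> None:
        """Classify staggered faces and enumerate rigid wall faces."""
        nx, ny, m = self.nx, self.ny, self.mask
        # u-faces (x-normal), shape (nx+1, ny): active iff both cells fluid
        self.u_active = np.zeros((nx + 1, ny), bool)
        self.u_active[1:nx] = m[:-1] & m[1:]
        self.u_inlet = np.zeros((nx + 1, ny), bool)
        self.u_inlet[0] = m[0] & self.inlet_j
        self.u_outlet = np.zeros((nx + 1, ny), bool)
        self.u_outlet[nx] = m[-1] & self.outlet_j
        # v-faces (y-normal), shape (nx, ny+1)
        self.v_active = np.zeros((nx, ny + 1), bool)
        self.v_active[:, 1:ny] = m[:, :-1] & m[:, 1:]

        # Rigid wall faces: fluid cell against solid cell or closed domain
        # boundary.  axis 0 → x-normal wall (tangential velocity v),
        # axis 1 → y-normal wall (tangential velocity u).  side = -1 means
        # the wall sits on the low-coordinate side of the fluid cell.
        wi, wj, wax, wside = [], [], [], []
        solid = np.pad(~m, 1, constant_values=True)  # domain exterior is solid
        solid[0, 1 + np.flatnonzero(self.inlet_j)] = False
        solid[-1, 1 + np.flatnonzero(self.outlet_j)] = False
        I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        for ax, side, di, dj in ((0, -1, 0, 1), (0, +1, 2, 1), (1, -1, 1, 0), (1, +1, 1, 2)):
            hit = m & solid[di:di + nx, dj:dj + ny]
            wi.append(I[hit]); wj.append(J[hit])
            wax.append(np.full(hit.sum(), ax)); wside.append(np.full(hit.sum(), side))
        self.wall_i = np.concatenate(wi)
        self.wall_j = np.concatenate(wj)
        self.wall_axis = np.concatenate(wax)
        self.wall_side = np.concatenate(wside)
        self.wall_len = np.where(self.wall_axis == 0, self.dy, self.dx)
        self.n_wall = self.wall_i.size

    @property
    def n_fluid(self) -> int:
        return int(self.mask.sum())

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def inlet_width(self) -> float:
        """Total open inlet span, m."""
        return float((self.inlet_j & self.mask[0]).sum()) * self.dy

    def region(self, name: str) -> np.ndarray:
        return self.regions[name]


def _span(coords: np.ndarray, start: float, end: float) -> np.ndarray:
    """Half-open interval membership [start, end) on cell centres."""
    return (coords >= start) & (coords < end)


def build_channel(length: float, height: float, nx: int, ny: int) -> CaseGrid:
    """Rectangular channel: left inlet, right outlet, top/bottom walls."""
    if length <= 0 or height <= 0:
        raise ConfigurationError("channel dimensions must be positive")
    if nx < 4 or ny < 4:
        raise ConfigurationError("need nx, ny >= 4")
    mask = np.ones((nx, ny), bool)
    open_j = np.ones(ny, bool)
    grid = CaseGrid(nx, ny, length / nx, height / ny, mask, open_j, open_j.copy())
    grid.meta.update(kind="channel", length=length, height=height)
    return grid


def build_backward_facing_step(
    inlet_height: float,
    step_height: float,
    upstream_len: float,
    downstream_len: float,
    resolution: float,
) -> CaseGrid:
    """L-shaped backward-facing step; flow enters the narrow upper channel.

    The ``step_recirculation`` region tags 0–8 step heights downstream of
    the step lip, below lip level — where the separated shear layer
    recirculates and the thrombosis model is expected to act.
    ``resolution`` is the target cell size in metres.
    """
    if step_height <= 0 or inlet_height <= 0:
        raise ConfigurationError("heights must be positive")
    if downstream_len < 10 * step_height:
        raise ConfigurationError("downstream length must be >= 10 step heights")
    dx = dy = float(resolution)
    H = inlet_height + step_height
    nx = max(int(round((upstream_len + downstream_len) / dx)), 8)
    ny = max(int(round(H / dy)), 6)
    dx = (upstream_len + downstream_len) / nx
    dy = H / ny
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    mask = np.ones((nx, ny), bool)
    # lower-left solid block upstream of the step
    mask[np.ix_(_span(xc, 0.0, upstream_len), _span(yc, 0.0, step_height))] = False
    inlet_j = _span(yc, step_height, H)
    outlet_j = np.ones(ny, bool)
    recirc = np.zeros((nx, ny), bool)
    recirc[np.ix_(_span(xc, upstream_len, upstream_len + 8 * step_height),
                  _span(yc, 0.0, step_height))] = True
    grid = CaseGrid(nx, ny, dx, dy, mask, inlet_j, outlet_j,
                    regions={"step_recirculation": recirc})
    grid.meta.update(
        kind="backward_facing_step",
        inlet_height=inlet_height, step_height=step_height,
        upstream_len=upstream_len, downstream_len=downstream_len,
        expansion_ratio=H / inlet_height,
    )
    return grid


def build_idealized_dissection(
    lumen_height: float,
    fl_height: float,
    flap_thickness: float,
    tear_positions: list[float],
    tear_widths: list[float],
    length: float,
    resolution: float,
) -> CaseGrid:
    """Idealized dissection: TL below, solid flap, FL above, 1–2 tears.

    The true lumen spans the full length and is open at both ends; the
    false lumen is closed at both ends (its only access is through the
    tears piercing the flap).  ``tear_positions`` are the upstream edges
    of the tears along x; tears must lie strictly inside the flap span
    and must not overlap.
    """
    if not 1 <= len(tear_positions) <= 2 or len(tear_widths) != len(tear_positions):
        raise ConfigurationError("need 1 or 2 tears with matching widths")
    order = np.argsort(tear_positions)
    pos = [tear_positions[k] for k in order]
    wid = [tear_widths[k] for k in order]
    for p, w in zip(pos, wid):
        if p <= 0 or p + w >= length:
            raise ConfigurationError("tears must lie strictly inside the flap span")
    if len(pos) == 2 and pos[0] + wid[0] >= pos[1]:
        raise ConfigurationError("tears overlap")

    dx = dy = float(resolution)
    H = lumen_height + flap_thickness + fl_height
    nx = max(int(round(length / dx)), 8)
    ny = max(int(round(H / dy)), 6)
    dx = length / nx
    dy = H / ny
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy

    tl_rows = _span(yc, 0.0, lumen_height)
    flap_rows = _span(yc, lumen_height, lumen_height + flap_thickness)
    fl_rows = _span(yc, lumen_height + flap_thickness, H)
    if not flap_rows.any():
        raise ConfigurationError("flap thinner than one cell row")

    mask = np.ones((nx, ny), bool)
    mask[:, flap_rows] = False
    regions: dict[str, np.ndarray] = {}
    for k, (p, w) in enumerate(zip(pos, wid), start=1):
        cols = _span(xc, p, p + w)
        if not cols.any():
            raise ConfigurationError("tear narrower than one cell column")
        mask[np.ix_(cols, flap_rows)] = True
        tear = np.zeros((nx, ny), bool)
        tear[np.ix_(cols, flap_rows)] = True
        regions[f"tear_{k}"] = tear

    tl = np.zeros((nx, ny), bool)
    tl[:, tl_rows] = True
    fl = np.zeros((nx, ny), bool)
    fl[:, fl_rows] = True
    regions["true_lumen"] = tl
    regions["false_lumen"] = fl

    inlet_j = tl_rows.copy()   # only the TL is open at the ends
    outlet_j = tl_rows.copy()
    grid = CaseGrid(nx, ny, dx, dy, mask, inlet_j, outlet_j, regions=regions)
    grid.meta.update(
        kind="dissection", lumen_height=lumen_height, fl_height=fl_height,
        flap_thickness=flap_thickness, tear_positions=pos, tear_widths=wid,
        length=length, n_tears=len(pos),
    )
    return grid


@dataclass(frozen=True)
class WaveformParams:
    """Pulsatile inlet flow: a systolic sine pulse plus a small
    retrograde early-diastolic lobe, flat (plug) velocity profile.

    ``Q_mean`` is the cycle-mean flow rate (m² s⁻¹ per unit depth in
    2D); ``systolic_fraction`` = t_s/T; ``retrograde_fraction`` is the
    reversed volume as a fraction of the forward systolic volume;
    ``steady`` collapses the waveform to constant ``Q_mean``.  The peak
    systolic flow is derived from the constraint that the waveform
    integrates to Q_mean·T over one period.
    """

    T: float = 1.054
    Q_mean: float = 1e-3
    systolic_fraction: float = 0.35
    retrograde_fraction: float = 0.05
    retro_width_fraction: float = 0.15
    steady: bool = False

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError("period must be positive")
        if not 0 < self.systolic_fraction < 1:
            raise ConfigurationError("systolic fraction must lie in (0, 1)")
        if not 0 <= self.retrograde_fraction < 1:
            raise ConfigurationError("retrograde fraction must lie in [0, 1)")

    @property
    def t_systole(self) -> float:
        return self.systolic_fraction * self.T

    @property
    def peak_flow(self) -> float:
        """Peak systolic flow rate implied by the cycle-mean constraint."""
        if self.steady:
            return self.Q_mean
        return (np.pi * self.Q_mean * self.T
                / (2.0 * self.t_systole * (1.0 - self.retrograde_fraction)))

    @property
    def peak_multiplier(self) -> float:
        return self.peak_flow / self.Q_mean


def inflow_rate(t, w: WaveformParams):
    """Inlet flow rate Q(t): periodic, cycle mean exactly ``Q_mean``."""
    if w.steady:
        return np.broadcast_to(w.Q_mean, np.shape(t)).copy() if np.ndim(t) else float(w.Q_mean)
    tau = np.asarray(t, dtype=float) % w.T
    ts = w.t_systole
    tr = w.retro_width_fraction * w.T
    A = w.peak_flow
    B = w.retrograde_fraction * A * ts / tr if tr > 0 else 0.0
    q = np.where(
        tau < ts,
        A * np.sin(np.pi * tau / ts),
        np.where(tau < ts + tr, -B * np.sin(np.pi * (tau - ts) / tr), 0.0),
    )
    return float(q) if np.ndim(t) == 0 else q


def womersley_number(half_height: float, T: float, kinematic_viscosity: float) -> float:
    """α = R √(ω/ν) with ω = 2π/T — pulsatile-frequency parameter."""
    if half_height <= 0 or T <= 0 or kinematic_viscosity <= 0:
        raise ConfigurationError("all arguments must be positive")
    return half_height * np.sqrt(2.0 * np.pi / (T * kinematic_viscosity))
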