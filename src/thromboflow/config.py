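"""Typed case configuration: geometry, fluid, kinetics, waveform, run protocol."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .constitutive import ConfigurationError, FluidProps, PASParams, ThrombosisParams
from .geometry import (
    CaseGrid,
    WaveformParams,
    build_backward_facing_step,
    build_channel,
    build_idealized_dissection,
)

__all__ = ["GeometryConfig", "RunParams", "CaseConfig", "build_grid"]


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry kind plus the dimensions its builder needs (metres)."""

    kind: str = "channel"
    # channel
    length: float = 0.1
    height: float = 0.01
    nx: int = 64
    ny: int = 16
    # backward-facing step
    inlet_height: float = 0.004
    step_height: float = 0.002
    upstream_len: float = 0.01
    downstream_len: float = 0.024
    # dissection
    lumen_height: float = 0.008
    fl_height: float = 0.008
    flap_thickness: float = 0.002
    tear_positions: tuple = (0.015,)
    tear_widths: tuple = (0.006,)
    # shared cell size for bfs / dissection
    resolution: float = 1e-3


def build_grid(geo: GeometryConfig) -> CaseGrid:
    if geo.kind == "channel":
        return build_channel(geo.length, geo.height, geo.nx, geo.ny)
    if geo.kind == "backward_facing_step":
        return build_backward_facing_step(geo.inlet_height, geo.step_height,
                                          geo.upstream_len, geo.downstream_len,
                                          geo.resolution)
    if geo.kind == "dissection":
        return build_idealized_dissection(geo.lumen_height, geo.fl_height,
                                          geo.flap_thickness, list(geo.tear_positions),
                                          list(geo.tear_widths), geo.length,
                                          geo.resolution)
    raise ConfigurationError(f"unknown geometry kind {geo.kind!r}")


@dataclass(frozen=True)
class RunParams:
    """Simulation protocol: cycle counts, time step, initial conditions.

    The standard protocol is 2 spin-up cycles with the thrombosis model
    off (to reach a periodic flow solution and initialize the
    cycle-averaged TAWSS/shear fields), optionally a number of
    coagulant-only cycles (production/consumption without platelet
    binding, used by the two-tear restart protocol), then ``n_cycles``
    of the full feedback loop.
    """

    n_cycles: int = 20
    spin_cycles: int = 2
    coagulant_pre_cycles: int = 0
    dt: float | None = None          # fixed step; None -> waveform-based estimate
    dt_safety: float = 0.3
    dt_velocity_factor: float = 2.0  # jet-speed margin over the mean inlet speed
    theta: float = 1.0               # viscous implicitness (1 = backward Euler)
    snapshots_per_cycle: int = 4
    thrombosis: bool = True
    ap_background: float = 0.05      # inlet activated fraction of platelets
    initial_wall_C: float = 0.0      # coagulant seeded on wall cells, nmol/l
    pre_thrombosed_x: float | None = None  # FL cells with x < this start thrombosed

    def __post_init__(self) -> None:
        if self.n_cycles < 0 or self.spin_cycles < 0 or self.coagulant_pre_cycles < 0:
            raise ConfigurationError("cycle counts must be non-negative")
        if self.dt is not None and self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not 0 < self.dt_safety <= 1:
            raise ConfigurationError("dt_safety must lie in (0, 1]")
        if not 0 <= self.ap_background <= 1:
            raise ConfigurationError("ap_background must lie in [0, 1]")


@dataclass(frozen=True)
class CaseConfig:
    """Everything needed to run one case, serializable to YAML."""

    fluid: FluidProps = field(default_factory=FluidProps)
    thrombosis: ThrombosisParams = field(default_factory=ThrombosisParams)
    pas: PASParams = field(default_factory=PASParams)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    run: RunParams = field(default_factory=RunParams)

    def to_dict(self) -> dict:
        return asdict(self)
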