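"""Configuration files, legacy-VTK snapshots, CSV summaries, checkpoints.

Snapshots are legacy ASCII VTK ``STRUCTURED_POINTS`` with one cell array
per field (cell-centred velocities are included for viewers; the exact
staggered face velocities ride along in a ``FIELD`` block so a snapshot
round-trips bit-exactly to float64).  Checkpoints are HDF5 containers
holding every field and cycle accumulator, enabling bit-identical
restarts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .config import CaseConfig, GeometryConfig, RunParams
from .constitutive import ConfigurationError, FluidProps, PASParams, ThrombosisParams
from .flow import FieldState
from .geometry import CaseGrid, WaveformParams

__all__ = ["load_config", "dump_config", "write_snapshot", "read_snapshot",
           "save_checkpoint", "load_checkpoint", "write_wall_csv"]

_SECTIONS = {
    "fluid": FluidProps,
    "thrombosis": ThrombosisParams,
    "pas": PASParams,
    "geometry": GeometryConfig,
    "waveform": WaveformParams,
    "run": RunParams,
}


def load_config(path) -> CaseConfig:
    """Read a YAML case configuration; unknown sections/keys are rejected.

    An empty file yields the full default configuration (the model's
    standard parameter set).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    parts = {}
    for name, cls in _SECTIONS.items():
        sub = raw.get(name) or {}
        if not isinstance(sub, dict):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - valid
        if bad:
            raise ConfigurationError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
        if name == "geometry":
            for key in ("tear_positions", "tear_widths"):
                if key in sub:
                    sub[key] = tuple(sub[key])
        parts[name] = cls(**sub)
    return CaseConfig(**parts)


def dump_config(cfg: CaseConfig, path) -> None:
    d = cfg.to_dict()
    for key in ("tear_positions", "tear_widths"):
        d["geometry"][key] = list(d["geometry"][key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ------------------------------------------------------------------ VTK

def _fmt(arr: np.ndarray) -> str:
    # 17 significant digits: exact float64 round trip through text
    return " ".join(np.format_float_scientific(x, precision=17)
                    for x in np.asarray(arr, dtype=float).ravel())


def write_snapshot(state: FieldState, grid: CaseGrid, path) -> None:
    """Write one legacy-VTK ASCII snapshot (STRUCTURED_POINTS, cell data)."""
    nx, ny = grid.nx, grid.ny
    lines = [
        "# vtk DataFile Version 3.0",
        f"thromboflow snapshot t={state.t!r}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        "ORIGIN 0.0 0.0 0.0",
        f"SPACING {grid.dx!r} {grid.dy!r} 1.0",
        f"CELL_DATA {nx * ny}",
    ]
    # VTK orders cells x-fastest: transpose our (nx, ny) arrays
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    cell_arrays = [("u", uc), ("v", vc)] + \
        [(n, getattr(state, n)) for n in ("p", "mu", "gamma", "eps",
                                          "RT", "RP_rel", "AP_rel", "C", "BP")]
    for name, arr in cell_arrays:
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(_fmt(arr.T))
    lines.append("SCALARS mask int 1")
    lines.append("LOOKUP_TABLE default")
    lines.append(" ".join(str(int(x)) for x in grid.mask.T.ravel()))
    lines.append("FIELD staggered 3")
    lines.append(f"u_face 1 {(nx + 1) * ny} double")
    lines.append(_fmt(state.u))
    lines.append(f"v_face 1 {nx * (ny + 1)} double")
    lines.append(_fmt(state.v))
    lines.append("time 1 1 double")
    lines.append(np.format_float_scientific(state.t, precision=17))
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> tuple[FieldState, np.ndarray]:
    """Read a snapshot written by :func:`write_snapshot`.

    Returns the reconstructed :class:`FieldState` and the cell mask.
    """
    text = Path(path).read_text().split("\n")
    if not text[0].startswith("# vtk DataFile"):
        raise ConfigurationError(f"{path}: not a legacy VTK file")
    it = iter(text)
    dims = None
    arrays: dict[str, np.ndarray] = {}
    mask = None
    t = 0.0
    try:
        while True:
            line = next(it)
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "DIMENSIONS":
                dims = (int(tok[1]) - 1, int(tok[2]) - 1)
            elif tok[0] == "SCALARS":
                name, typ = tok[1], tok[2]
                next(it)  # LOOKUP_TABLE
                nx, ny = dims
                vals = _read_numbers(it, nx * ny)
                arr = np.array(vals).reshape(ny, nx).T
                if name == "mask":
                    mask = arr.astype(bool)
                else:
                    arrays[name] = arr.astype(float)
            elif tok[0] == "FIELD":
                nfields = int(tok[2])
                nx, ny = dims
                for _ in range(nfields):
                    hdr = next(it).split()
                    fname, ntot = hdr[0], int(hdr[1]) * int(hdr[2])
                    vals = _read_numbers(it, ntot)
                    if fname == "u_face":
                        arrays["u_face"] = np.array(vals).reshape(nx + 1, ny)
                    elif fname == "v_face":
                        arrays["v_face"] = np.array(vals).reshape(nx, ny + 1)
                    elif fname == "time":
                        t = float(vals[0])
    except StopIteration:
        pass
    if dims is None or mask is None:
        raise ConfigurationError(f"{path}: truncated or malformed snapshot")
    try:
        state = FieldState(
            u=arrays["u_face"], v=arrays["v_face"],
            p=arrays["p"], mu=arrays["mu"], gamma=arrays["gamma"], eps=arrays["eps"],
            RT=arrays["RT"], RP_rel=arrays["RP_rel"], AP_rel=arrays["AP_rel"],
            C=arrays["C"], BP=arrays["BP"], t=t,
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing field {exc}") from exc
    return state, mask


def _read_numbers(it, n):
    vals: list[float] = []
    while len(vals) < n:
        vals.extend(float(x) for x in next(it).split())
    return vals


# ------------------------------------------------------------- checkpoints

def save_checkpoint(path, payload: dict) -> None:
    """Store arrays/scalars (and a JSON-encoded 'meta' entry) in HDF5."""
    with h5py.File(path, "w") as f:
        for key, val in payload.items():
            if key == "meta":
                f.attrs["meta"] = json.dumps(val)
            elif np.isscalar(val):
                f.attrs[key] = val
            else:
                f.create_dataset(key, data=np.asarray(val))


def load_checkpoint(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for key in f.attrs:
            out[key] = json.loads(f.attrs[key]) if key == "meta" else f.attrs[key]
        for key in f.keys():
            out[key] = f[key][...]
    return out


def write_wall_csv(grid: CaseGrid, tawss: np.ndarray, path) -> None:
    """Per-wall-face TAWSS table: face id, x, y, TAWSS (Pa)."""
    import pandas as pd

    x = (grid.wall_i + 0.5) * grid.dx
    y = (grid.wall_j + 0.5) * grid.dy
    pd.DataFrame({"face": np.arange(grid.n_wall), "x": x, "y": y,
                  "tawss": tawss}).to_csv(path, index=False)
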