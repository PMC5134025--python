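"""Shared fixtures: the expensive coupled runs are computed once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from thromboflow.cases import (
    bfs_thrombosis_case,
    dissection_s1_case,
    dissection_s4_case,
)
from thromboflow.coupler import run_case


@pytest.fixture(scope="session")
def s1_result():
    """Single-tear dissection analog, 2 spin-up + 10 growth cycles."""
    return run_case(dissection_s1_case(n_cycles=10))


@pytest.fixture(scope="session")
def s4_result(s1_result):
    """Two-tear restart protocol; initial wall coagulant is 1% of the
    maximum coagulant concentration reached in the single-tear run."""
    c_init = 0.01 * float(s1_result.state.C.max())
    return run_case(dissection_s4_case(n_cycles=10, initial_wall_C=c_init))


@pytest.fixture(scope="session")
def bfs_result():
    """Backward-facing step, steady inflow, accelerated kinetics."""
    return run_case(bfs_thrombosis_case(sim_time=8.5))


@pytest.fixture(scope="session")
def tiny_dissection_cfg():
    """A coarse, short dissection config for determinism/restart tests."""
    cfg = dissection_s1_case(n_cycles=2, resolution=2e-3)
    return cfg
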