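"""Shared (session-scoped) expensive fixtures: the production-scale AAA
flow solution and the coupled thrombin runs for both exposure cases."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thromboflow.geometry import (
    AAAGeometry,
    StructuredGrid,
    default_waveform,
    exposure_patches,
)
from thromboflow.hemodynamics import FlowSolverConfig, solve_flow
from thromboflow.kinetics import build_network
from thromboflow.rheology import CarreauYasudaParams
from thromboflow.transport import TransportConfig, run_coupled


@pytest.fixture(scope="session")
def aaa_grid():
    return StructuredGrid(AAAGeometry(), nz=200, nr=40)


@pytest.fixture(scope="session")
def aaa_flow(aaa_grid):
    """Pulsatile AAA flow: 3 washout cycles + 1 recorded cycle."""
    cfg = FlowSolverConfig(cycles=4, snapshots_per_cycle=50)
    return solve_flow(aaa_grid, default_waveform(), CarreauYasudaParams(), cfg)


@pytest.fixture(scope="session")
def coupled_results(aaa_grid, aaa_flow):
    """Coupled 18-species transport for exposure cases A and B (5 cycles)."""
    network = build_network()
    cfg = TransportConfig(cycles=5, reaction_substeps=1)
    out = {}
    for case in "AB":
        patch = exposure_patches(aaa_grid.geometry, case)
        out[case] = run_coupled(aaa_grid, aaa_flow, network, patch, config=cfg)
    return out
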