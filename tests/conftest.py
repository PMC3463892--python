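"""Shared fixtures: small geometries and models sized for fast tests."""

import numpy as np
import pytest

from ttflux.buffers import default_buffers
from ttflux.fluxes import FluxModel, IonicConditions
from ttflux.geometry import (BoxSpec, ProbeSet, TTubuleSpec, build_geometry,
                             calibrate_geometry, make_probes,
                             place_lcc_clusters)
from ttflux.solver import Simulator, SolverConfig


@pytest.fixture(scope="session")
def calibrated_specs():
    """Geometry calibrated against the printed morphometrics at the
    40 nm working resolution (deterministic, ~1 s)."""
    return calibrate_geometry(voxel_size=0.04)


@pytest.fixture(scope="session")
def mini_specs():
    """Small tubule-in-box geometry for solver tests: same structure,
    ~20x fewer voxels than the production compartment."""
    tt = TTubuleSpec(length=1.6, mean_diameter=0.42, eccentricity=1.3,
                     constriction_period=0.9,
                     mouth_center=(0.6, 0.66))
    bx = BoxSpec(dimensions=(1.2, 1.32, 2.4), outer_relief_amplitude=0.3,
                 outer_relief_wavelength=1.6)
    return tt, bx


@pytest.fixture(scope="session")
def mini_grid(mini_specs):
    tt, bx = mini_specs
    g = build_geometry(tt, bx, 0.08, seed=3)
    return place_lcc_clusters(g, n=2, diameter=0.2, pinned_depth=0.8,
                              seed=3)


@pytest.fixture(scope="session")
def mini_sim(mini_grid):
    probes = make_probes(mini_grid)
    model = FluxModel().with_leak_balanced(IonicConditions(V=-50.0))
    return Simulator(mini_grid, probes, model,
                     config=SolverConfig(snapshot_interval=10.0))


def flat_box_probes(grid) -> ProbeSet:
    """Manual probes for degenerate grids without a tubule."""
    mem = grid.membrane_faces()
    sub = np.zeros(grid.n_cytosol, dtype=bool)
    sub[grid.face_voxel[mem]] = True
    v0 = int(grid.face_voxel[mem[0]])
    frac = np.zeros(grid.n_cytosol)
    frac[sub] = min(1.0, 0.05 / grid.voxel_size)
    col = grid.cyt_index[0, 0, :]
    line = col[col >= 0]
    pos = (np.flatnonzero(col >= 0) + 0.5) * grid.voxel_size
    return ProbeSet(shell_depth=50.0, subsarc_mask=sub, shell_fraction=frac,
                    mouth_point=v0, distal_point=v0, linescan_voxels=line,
                    linescan_positions=pos, cytosol_spots=(v0, v0))
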