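"""Reaction-diffusion integrator: operator structure, conservation,
analytic diffusion oracle, steady states and determinism."""

import numpy as np
import pytest

from tests.conftest import flat_box_probes
from ttflux.buffers import default_buffers
from ttflux.fluxes import (DensityMap, FluxModel, IonicConditions, LCCParams,
                           LeakParams, NCXParams, PumpParams)
from ttflux.geometry import BoxSpec, build_geometry
from ttflux.solver import (Protocol, Simulator, SolverConfig,
                           assemble_diffusion, mass_balance_audit)

SILENT = FluxModel(ncx=NCXParams(V_max=1e-300),
                   lcc=LCCParams(amplitude={0.0: 0.0, 50.0: 0.0}),
                   pump=PumpParams(V_max_pump=0.0), leak=LeakParams(0.0),
                   density=DensityMap(lcc_mode="continuous"))


def test_diffusion_operator_rows_sum_to_zero(mini_grid):
    L = assemble_diffusion(mini_grid, 0.35)
    rows = np.asarray(L.sum(axis=1)).ravel()
    assert np.abs(rows).max() < 1e-10
    # symmetric (equal voxel volumes)
    assert (L - L.T).nnz == 0 or np.abs((L - L.T).data).max() < 1e-12


def test_uniform_field_has_zero_diffusion(mini_grid):
    L = assemble_diffusion(mini_grid, 0.35)
    u = np.full(mini_grid.n_cytosol, 0.37)
    assert np.abs(L @ u).max() < 1e-10


def test_slab_diffusion_matches_cosine_series():
    """1D relaxation of a step profile in a closed slab against the
    exact no-flux heat-equation series solution."""
    box = BoxSpec(dimensions=(0.48, 0.48, 2.4), outer_relief_amplitude=0.0)
    g = build_geometry(None, box, 0.06)
    probes = flat_box_probes(g)
    cfg = SolverConfig(dt=0.05, substeps=1, snapshot_interval=0)
    sim = Simulator(g, probes, SILENT, specs=[], config=cfg)
    st = sim.initial_state(0.0)
    z = (g.cyt_ijk[:, 2] + 0.5) * g.voxel_size
    Lz = 2.4
    st.Ca[:] = np.where(z < Lz / 2, 0.5, 0.1)
    total0 = st.Ca.sum()
    prot = Protocol(step_V=0.0)
    sim._clipped = 0.0
    t_end = 40 * cfg.dt
    for i in range(40):
        sim.step(st, prot, 0.0, None)
    # exact series for the step initial condition
    D = 0.35
    u = np.full_like(z, 0.3)
    for n in range(1, 300):
        a_n = 2 / Lz * 0.4 * np.sin(n * np.pi / 2) * Lz / (n * np.pi)
        u += a_n * np.cos(n * np.pi * z / Lz) * np.exp(-D * (n * np.pi / Lz) ** 2 * t_end)
    assert np.abs(st.Ca - u).max() < 0.4 * 0.02
    # diffusion conserves mass to solver precision
    assert st.Ca.sum() == pytest.approx(total0, rel=1e-10)


def test_equilibrated_closed_state_is_stationary(mini_grid):
    probes = flat_box_probes(mini_grid)
    sim = Simulator(mini_grid, probes, SILENT,
                    config=SolverConfig(snapshot_interval=0))
    st = sim.initial_state(0.1)
    before = st.copy()
    sim._clipped = 0.0
    for _ in range(5):
        sim.step(st, Protocol(step_V=0.0), 0.0, None)
    assert np.abs(st.Ca - before.Ca).max() < 1e-12
    for k in st.bound:
        assert np.abs(st.bound[k] - before.bound[k]).max() < 1e-10


def test_step_total_change_equals_applied_flux(mini_sim):
    sim = mini_sim
    st = sim.initial_state(0.1)
    sim._clipped = 0.0
    vol_mean = lambda s: s.Ca.mean() + sum(b.mean() for b in s.bound.values())
    t0 = vol_mean(st)
    applied = 0.0
    for i in range(10):
        _, a = sim.step(st, Protocol(step_V=0.0), 0.0, i * sim.config.dt)
        applied += a
    assert vol_mean(st) - t0 == pytest.approx(applied, abs=1e-9 * t0)


def test_run_mass_balance_and_positivity(mini_sim):
    traj = mini_sim.run(Protocol(step_V=0.0, step_duration=30.0))
    assert mass_balance_audit(traj) < 1e-6
    assert traj.global_ca.min() >= 0
    assert np.all(np.diff(traj.times) > 0)
    # transient rises from basal under the 0 mV step
    assert traj.global_ca[-1] > traj.global_ca[0]


def test_bound_never_exceeds_local_total(mini_sim):
    traj = mini_sim.run(Protocol(step_V=0.0, step_duration=20.0))
    st = traj.snapshots[-1] if traj.snapshots else None
    if st is None:
        pytest.skip("no snapshots recorded")
    for s in mini_sim.specs:
        tot = mini_sim.totals[s.name]
        assert np.all(st.bound[s.name] <= np.asarray(tot) + 1e-9)
        assert np.all(st.bound[s.name] >= 0)


def test_preequilibration_balanced_start_is_steady(mini_sim):
    st = mini_sim.initial_state(0.1)
    res = mini_sim.net_whole_cell_flux(st, Protocol(step_V=0.0), -50.0)
    assert abs(res) < 1e-10  # calibrated leak balances the hold state


def test_zero_na_run_starts_from_basal(mini_sim, caplog):
    """No steady state exists at hold with Na_i = 0 (NCX is efflux-only);
    the run proceeds from the basal equilibrium instead of erroring."""
    traj = mini_sim.run(Protocol(step_V=0.0, Na_i=0.0, step_duration=10.0))
    assert traj.global_ca[0] == pytest.approx(0.1, abs=1e-6)
    from ttflux.solver import SolverError
    with pytest.raises(SolverError):
        mini_sim.run(Protocol(step_V=0.0, Na_i=0.0, step_duration=10.0),
                     require_steady=True)


def test_runs_are_deterministic(mini_sim):
    a = mini_sim.run(Protocol(step_V=0.0, step_duration=15.0))
    b = mini_sim.run(Protocol(step_V=0.0, step_duration=15.0))
    assert np.array_equal(a.global_ca, b.global_ca)
    assert np.array_equal(a.linescan, b.linescan)
    for k in a.fluxes:
        assert np.array_equal(a.fluxes[k], b.fluxes[k])


def test_flux_components_recorded(mini_sim):
    traj = mini_sim.run(Protocol(step_V=0.0, step_duration=20.0))
    assert traj.fluxes["lcc"].max() > 0
    assert traj.fluxes["pump"].max() <= 0
    # LCC waveform starts at zero
    assert traj.fluxes["lcc"][0] == 0.0
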