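"""Membrane flux evaluators: Hill allosterics, exchanger reversal,
waveforms, unit conversion and conservative surface distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttflux.fluxes import (ConversionParams, DensityMap, FluxError,
                           IonicConditions, LCCParams, LeakParams, NCXParams,
                           PumpParams, allosteric_factor, calibrate_leak,
                           current_to_flux, distribute_surface_density,
                           flux_to_current, lcc_waveform, leak_flux,
                           ncx_flux, ncx_reversal_potential, nernst_ca,
                           pump_flux)
from ttflux.geometry import (FACE_OUTER, FACE_TTUBULE, build_geometry,
                             place_lcc_clusters)

NCX = NCXParams()


class TestAllostericFactor:
    def test_hill_midpoint_and_limits(self):
        assert allosteric_factor(NCX.K_mCaAct, NCX) == pytest.approx(0.5)
        assert allosteric_factor(1e9, NCX) == pytest.approx(1.0, abs=1e-6)
        assert allosteric_factor(0.0, NCX) == 0.0

    def test_hand_evaluated_hill_expression(self):
        # 1 / (1 + (0.29/0.1)^2) = 1 / (1 + 8.41)
        assert allosteric_factor(0.1, NCX) == pytest.approx(1 / 9.41, rel=1e-12)

    @given(st.floats(1e-4, 100.0), st.floats(1e-4, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_ca(self, a, b):
        lo, hi = sorted((a, b))
        fa, fb = allosteric_factor(lo, NCX), allosteric_factor(hi, NCX)
        assert 0 < fa < 1 and 0 < fb < 1
        if hi > lo:
            assert fb > fa


class TestNCX:
    @pytest.mark.parametrize("Na_i,Ca_i", [(10.0, 0.1), (5.0, 0.5),
                                           (20.0, 1.0)])
    def test_flux_reverses_exactly_at_reversal_potential(self, Na_i, Ca_i):
        cond = IonicConditions(Na_i=Na_i, V=0.0)
        vrev = ncx_reversal_potential(cond, Ca_i, NCX)
        at_rev = ncx_flux(Ca_i, IonicConditions(Na_i=Na_i, V=vrev), NCX)
        assert at_rev == pytest.approx(0.0, abs=1e-15)
        above = ncx_flux(Ca_i, IonicConditions(Na_i=Na_i, V=vrev + 5), NCX)
        below = ncx_flux(Ca_i, IonicConditions(Na_i=Na_i, V=vrev - 5), NCX)
        assert above > 0 > below  # reverse mode = influx above V_rev

    @pytest.mark.parametrize("V", [0.0, 50.0])
    def test_zero_na_inactivates_reverse_mode(self, V):
        cond = IonicConditions(Na_i=0.0, V=V)
        assert ncx_flux(0.1, cond, NCX) < 0  # outward only

    def test_allosteric_flag_off_is_allo_one(self):
        cond = IonicConditions(V=50.0)
        ca = 0.15
        full = ncx_flux(ca, cond, NCX, allosteric=True)
        off = ncx_flux(ca, cond, NCX, allosteric=False)
        assert full == pytest.approx(off * allosteric_factor(ca, NCX))

    def test_rejects_negative_concentration(self):
        with pytest.raises(FluxError):
            ncx_flux(-0.1, IonicConditions(), NCX)


class TestLCCWaveform:
    P = LCCParams()

    def test_zero_at_onset_and_peak_position(self):
        assert lcc_waveform(0.0, 0.0, self.P) == 0.0
        t = np.linspace(0, 200, 4001)
        j = lcc_waveform(t, 0.0, self.P)
        assert t[np.argmax(j)] == pytest.approx(15.0, abs=0.1)

    def test_decays_by_end_of_step(self):
        jp = lcc_waveform(15.0, 0.0, self.P)
        assert lcc_waveform(200.0, 0.0, self.P) / jp < 0.1

    def test_more_gradual_at_plus50(self):
        t = np.linspace(0, 200, 4001)
        tp50 = t[np.argmax(lcc_waveform(t, 50.0, self.P))]
        assert tp50 > 15.0

    def test_unknown_step_potential_rejected(self):
        with pytest.raises(FluxError):
            lcc_waveform(10.0, 30.0, self.P)


class TestPumpLeak:
    def test_pump_trivials_and_hand_value(self):
        p = PumpParams()
        assert pump_flux(0.0, p) == 0.0
        assert pump_flux(p.K_m_pump, p) == pytest.approx(-p.V_max_pump / 2)
        # hand evaluation at Ca = 0.1, Vmax 0.005, Km 0.5, n 2:
        # -0.005 * 0.01 / (0.01 + 0.25)
        assert pump_flux(0.1, p) == pytest.approx(-0.005 * 0.01 / 0.26)

    def test_pump_monotone_and_bounded(self):
        p = PumpParams()
        ca = np.linspace(0.01, 50, 100)
        j = pump_flux(ca, p)
        assert np.all(np.diff(j) < 0)
        assert np.all(np.abs(j) <= p.V_max_pump)

    def test_leak_zero_at_nernst_and_inward_below(self):
        cond = IonicConditions()
        p = LeakParams(g_leak=1e-3)
        e_ca = nernst_ca(0.1, cond.Ca_o)
        assert leak_flux(0.1, e_ca, cond, p) == pytest.approx(0.0, abs=1e-15)
        # E_Ca(0.1 uM, 2 mM) ~ +128 mV; at -50 mV the leak is inward
        assert e_ca == pytest.approx(132.0, abs=5.0)
        assert leak_flux(0.1, -50.0, cond, p) > 0
        assert leak_flux(0.1, -50.0, cond, LeakParams(0.0)) == 0.0

    def test_leak_diverges_at_zero_ca(self):
        with pytest.raises(FluxError):
            leak_flux(0.0, -50.0, IonicConditions(), LeakParams(1e-3))


class TestConversion:
    def test_linear_with_sign_flip_and_round_trip(self):
        c = ConversionParams()
        assert current_to_flux(0.0, c) == 0.0
        j1, j2 = current_to_flux(-1.0, c), current_to_flux(-2.0, c)
        assert j1 > 0 and j2 == pytest.approx(2 * j1)
        assert flux_to_current(current_to_flux(3.7, c), c) == pytest.approx(3.7)

    def test_magnitude(self):
        # 10 pA/pF inward * 4.54 pF/pL / (2 * 96485 C/mol) ~ 0.235 uM/ms
        assert current_to_flux(-10.0) == pytest.approx(0.2353, rel=1e-3)


@pytest.fixture(scope="module")
def grid(calibrated_specs):
    tt, bx = calibrated_specs
    g = build_geometry(tt, bx, 0.08, seed=7)
    return place_lcc_clusters(g, seed=7)


class TestDistribution:

    def test_uniform_multipliers_give_uniform_density(self, grid):
        dmap = DensityMap(lcc={FACE_OUTER: 1.0, FACE_TTUBULE: 1.0},
                          lcc_mode="continuous")
        w = distribute_surface_density(grid, dmap, "lcc")
        mem = grid.membrane_faces()
        assert np.allclose(w[mem], w[mem][0])

    def test_continuous_ttubule_density_is_ninefold(self, grid):
        dmap = DensityMap(lcc_mode="continuous")
        w = distribute_surface_density(grid, dmap, "lcc")
        tt = w[np.flatnonzero(grid.face_label == FACE_TTUBULE)[0]]
        out = w[np.flatnonzero(grid.face_label == FACE_OUTER)[0]]
        assert tt / out == pytest.approx(9.0)

    @pytest.mark.parametrize("dmap", [
        DensityMap(lcc_mode="continuous"),
        DensityMap(lcc_mode="clustered", cluster_density="matched"),
        DensityMap(lcc_mode="clustered", cluster_density="tubule_share"),
    ], ids=["continuous", "matched", "tubule_share"])
    def test_total_flux_conserved_to_machine_precision(self, grid, dmap):
        for which in ("lcc", "ncx", "pump"):
            w = distribute_surface_density(grid, dmap, which)
            assert w.sum() == pytest.approx(1.0, abs=1e-13)
            assert (w >= 0).all()

    def test_tubule_share_mode_concentrates_tt_share(self, grid):
        dmap = DensityMap(cluster_density="tubule_share")
        w = distribute_surface_density(grid, dmap, "lcc")
        on_patch = grid.face_patch >= 0
        a_tt = (grid.face_label == FACE_TTUBULE).sum() * grid.face_area
        a_out = (grid.face_label == FACE_OUTER).sum() * grid.face_area
        expect = 9 * a_tt / (a_out + 9 * a_tt)
        assert w[on_patch].sum() == pytest.approx(expect, rel=1e-12)

    def test_matched_mode_patch_density_is_ninefold_outer(self, grid):
        dmap = DensityMap(cluster_density="matched")
        w = distribute_surface_density(grid, dmap, "lcc")
        patch = w[np.flatnonzero(grid.face_patch >= 0)[0]]
        out = w[np.flatnonzero(grid.face_label == FACE_OUTER)[0]]
        assert patch / out == pytest.approx(9.0)
        bare_tt = (grid.face_label == FACE_TTUBULE) & (grid.face_patch < 0)
        assert np.all(w[np.flatnonzero(bare_tt)] == 0.0)

    def test_clustered_without_patches_rejected(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = build_geometry(tt, bx, 0.08)
        with pytest.raises(FluxError):
            distribute_surface_density(g, DensityMap(), "lcc")


class TestLeakCalibration:
    def test_pump_only_closed_form(self):
        cond = IonicConditions(V=-50.0)
        ncx = NCXParams(V_max=1e-300)  # exchanger effectively absent
        pump = PumpParams()
        leak = calibrate_leak(cond, ncx, pump, Ca_rest_uM=0.1)
        e_ca = nernst_ca(0.1, cond.Ca_o, ncx.rt_over_f)
        expect = pump_flux(0.1, pump) / (cond.V - e_ca)
        assert leak.g_leak == pytest.approx(expect, rel=1e-12)

    def test_no_pump_no_ncx_gives_zero_leak(self):
        leak = calibrate_leak(IonicConditions(V=-50.0),
                              NCXParams(V_max=1e-300),
                              PumpParams(V_max_pump=0.0))
        assert leak.g_leak == 0.0

    def test_default_rest_balance_residual(self):
        cond = IonicConditions(V=-50.0)
        ncx, pump = NCXParams(), PumpParams()
        leak = calibrate_leak(cond, ncx, pump)
        resid = (ncx_flux(0.1, cond, ncx) + pump_flux(0.1, pump)
                 + leak_flux(0.1, cond.V, cond, leak, ncx.rt_over_f))
        assert abs(resid) < 1e-10
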