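"""Cable-engine physics: synapse waveforms, Mg block, placement, integration."""

import math

import numpy as np
import pytest

from dendsum.biophysics import (
    AMPA_DEFAULT,
    NMDA_SINGLE_PULSE,
    ChannelParams,
    MembraneParams,
    ParameterError,
    PlacementError,
    StimulusEvent,
    SynapseSpec,
    double_pulse,
    double_pulse_events,
    dual_exp_g,
    dual_exp_peak_time,
    mg_block,
    peak_depolarization,
    place_cluster,
    simulate,
    synapse_events,
)
from dendsum.cell import CellModel, CellSpec
from dendsum.morphology import build_ball_and_stick, discretize


class TestMgBlock:
    @pytest.mark.parametrize("v,half,slope,expected", [
        (-12.0, 12.0, 10.0, 0.5),          # sigmoid midpoint
        (-22.0, 22.0, 12.0, 0.5),          # softer 2-compartment variant
        (38.0, 12.0, 10.0, 1 / (1 + math.exp(-5))),
    ])
    def test_values(self, v, half, slope, expected):
        assert mg_block(v, half, slope) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing(self):
        v = np.linspace(-100, 60, 400)
        assert np.all(np.diff(mg_block(v)) > 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            mg_block(0.0, 12.0, 0.0)


class TestDualExp:
    def test_zero_at_onset(self):
        assert dual_exp_g(0.0, AMPA_DEFAULT()) == 0.0

    def test_peak_normalization_ampa(self):
        spec = AMPA_DEFAULT()
        tstar = dual_exp_peak_time(spec.tau_rise, spec.tau_fall)
        assert dual_exp_g(tstar, spec) == pytest.approx(1.5, rel=1e-12)

    def test_peak_normalization_nmda_grid_scan(self):
        spec = NMDA_SINGLE_PULSE()
        t = np.linspace(0, 200, 2_000_001)
        assert np.max(dual_exp_g(t, spec)) == pytest.approx(spec.g_max,
                                                            abs=1e-6)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ParameterError):
            SynapseSpec("AMPA", 1.0, 2.0, 1.0)


class TestPlaceCluster:
    @pytest.fixture(scope="class")
    def morph(self):
        return build_ball_and_stick(1, 275.0, 1.0, 20.0)

    def test_single_site(self, morph):
        sites = place_cluster(morph, 1, 90.0, 1)
        assert [s.path_um for s in sites] == [90.0]

    def test_five_sites_half_micron_spacing(self, morph):
        sites = place_cluster(morph, 1, 90.0, 5)
        assert [s.path_um for s in sites] == pytest.approx(
            [89.0, 89.5, 90.0, 90.5, 91.0])

    def test_forty_site_span(self, morph):
        sites = place_cluster(morph, 1, 160.0, 40)
        pos = [s.path_um for s in sites]
        assert pos[0] == pytest.approx(150.25)
        assert pos[-1] == pytest.approx(169.75)
        assert pos[-1] - pos[0] == pytest.approx(19.5)

    def test_span_exceeding_branch_rejected(self, morph):
        with pytest.raises(PlacementError):
            place_cluster(morph, 1, 274.0, 40)


class TestSimulate:
    def test_passive_rest_is_flat_at_leak_potential(self, passive_cell):
        r = simulate(passive_cell.morphology, passive_cell.membrane, None,
                     [], duration=100.0)
        for v in r.traces.values():
            assert np.allclose(v, -70.0, atol=1e-9)

    def test_active_rest_stable_within_half_millivolt(self, cell):
        r = simulate(cell.morphology, cell.membrane, cell.channels, [],
                     duration=500.0)
        assert np.ptp(r.traces["soma"]) < 0.5

    def test_input_resistance_matches_cable_theory(self, passive_cell):
        """Steady soma response to a current step vs the sealed-end formula."""
        spec = passive_cell.spec
        mem = passive_cell.membrane
        r = simulate(passive_cell.morphology, mem, None, [], bias=0.01,
                     duration=400.0)
        r_in_sim = (r.traces["soma"][-1] - r.rest["soma"]) / 0.01  # MOhm
        rm_dend = mem.r_m_dend * 1000 / 2  # spine corrected, Ohm cm^2
        d_cm = spec.dend_diam * 1e-4
        lam = math.sqrt(rm_dend * d_cm / (4 * mem.r_a))
        r_inf = (4 * mem.r_a / (math.pi * d_cm ** 2)) * lam
        r_dend = r_inf / math.tanh(spec.dend_length * 1e-4 / lam)
        g_soma = math.pi * (spec.soma_diam * 1e-4) ** 2 / (mem.r_m_other * 1000)
        r_in = 1.0 / (g_soma + spec.n_basal / r_dend) / 1e6
        assert r_in_sim == pytest.approx(r_in, rel=0.02)

    def test_somatic_peak_grows_with_synapse_count(self, ramps):
        y = ramps[(70.0, "control")].y
        assert np.all(np.diff(y) > 0)

    def test_proximal_beats_distal_below_threshold(self, ramps):
        """Cable asymmetry: proximal sites give larger subthreshold peaks."""
        prox, dist = ramps[(70.0, "control")], ramps[(160.0, "control")]
        assert np.all(prox.y[:5] > dist.y[:5])

    def test_two_passive_inputs_sum_sublinearly(self, passive_cell):
        m, mem = passive_cell.morphology, passive_cell.membrane
        b = passive_cell.basal_ids[0]
        e1 = synapse_events(place_cluster(m, b, 60.0, 3), 5.0, 0.0, 1.5)
        e2 = synapse_events(place_cluster(m, b, 80.0, 3), 5.0, 0.0, 1.5)
        p1 = peak_depolarization(simulate(m, mem, None, e1, duration=60.0))
        p2 = peak_depolarization(simulate(m, mem, None, e2, duration=60.0))
        p12 = peak_depolarization(simulate(m, mem, None, e1 + e2,
                                           duration=60.0))
        assert p12 <= p1 + p2

    def test_dt_halving_changes_peak_below_half_percent(self, cell):
        m, mem, ch = cell.morphology, cell.membrane, cell.channels
        b = cell.basal_ids[0]
        ev = synapse_events(place_cluster(m, b, 160.0, 8), 5.0, 3.56, 1.5)
        p1 = peak_depolarization(simulate(m, mem, ch, ev, duration=60.0,
                                          dt=0.1))
        p2 = peak_depolarization(simulate(m, mem, ch, ev, duration=60.0,
                                          dt=0.05))
        assert p1 == pytest.approx(p2, rel=0.005)

    def test_discretization_convergence(self):
        """Halving the 10 um cap changes the somatic peak by < 1%."""
        mem = MembraneParams()
        ch = ChannelParams(v_shift=25.0)
        peaks = []
        for cap in (10.0, 5.0):
            m = discretize(build_ball_and_stick(4, 275.0, 0.7, 60.0), mem,
                           max_seg_um=cap)
            b = m.basal_ids[0]
            ev = synapse_events(place_cluster(m, b, 160.0, 8), 5.0, 3.56, 1.5)
            peaks.append(peak_depolarization(
                simulate(m, mem, ch, ev, duration=60.0)))
        assert peaks[0] == pytest.approx(peaks[1], rel=0.01)


class TestDoublePulse:
    def test_facilitation_schedule_doubles_nmda(self):
        m = build_ball_and_stick(1, 275.0, 1.0, 20.0)
        sites = place_cluster(m, 1, 90.0, 3)
        events = double_pulse_events(sites, t0=5.0)
        nmda = [e for e in events if e.spec.kind == "NMDA"]
        first = {e.spec.g_max for e in nmda if e.onset == 5.0}
        second = {e.spec.g_max for e in nmda if e.onset == 25.0}
        assert first == {2.23}
        assert second == {4.46}
        assert next(iter(second)) / next(iter(first)) == pytest.approx(2.0)
        ampa = {e.spec.g_max for e in events if e.spec.kind == "AMPA"}
        assert ampa == {1.5}

    def test_zero_synapses_flat_trace(self, cell):
        r = double_pulse(cell.morphology, cell.membrane, cell.channels, [])
        assert np.ptp(r.traces["soma"]) < 0.5

    def test_double_pulse_at_least_single_pulse(self, cell):
        m, mem, ch = cell.morphology, cell.membrane, cell.channels
        sites = place_cluster(m, cell.basal_ids[0], 160.0, 6)
        rd = double_pulse(m, mem, ch, sites)
        ev = synapse_events(sites, 5.0, 2.23, 1.5)
        rs = simulate(m, mem, ch, ev, duration=90.0)
        assert peak_depolarization(rd) >= peak_depolarization(rs) - 1e-9


class TestPeakDepolarization:
    def test_flat_trace_gives_zero(self, passive_cell):
        r = simulate(passive_cell.morphology, passive_cell.membrane, None,
                     [], duration=50.0)
        assert peak_depolarization(r) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_max_of_trace(self, passive_cell):
        m, mem = passive_cell.morphology, passive_cell.membrane
        ev = synapse_events(place_cluster(m, passive_cell.basal_ids[0],
                                          100.0, 2), 5.0, 0.0, 1.5)
        r = simulate(m, mem, None, ev, duration=60.0)
        v = r.traces["soma"]
        assert peak_depolarization(r) == pytest.approx(np.max(v) - v[0])
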