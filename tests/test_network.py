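"""Circuit assembly, integration, steady-state detection, conservation."""

import numpy as np
import pytest

from splitvent import (AIR, CircuitTopology, EttSpec, Limb, LungRC, Network,
                       PipeSegment, ResistorSpec, VentilatorSettings,
                       build_network, junction_residual, two_patient_topology)
from splitvent.metrics import pressure_extrema, tidal_volume_per_cycle
from splitvent.network import ConfigurationError


def tvs_of(wf):
    return {p: tidal_volume_per_cycle(wf, p)[-1] for p in wf.patients}


class TestTopology:
    def test_two_resistors_rejected(self):
        tube = PipeSegment(1.83, 0.022)
        limb = Limb(lung=LungRC(30.0), tube=tube, resistor=ResistorSpec(4.0))
        with pytest.raises(ConfigurationError):
            CircuitTopology(limb_a=limb, limb_b=limb)

    def test_symmetric_construction_packs_symmetric_params(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        net = build_network(topo, VentilatorSettings())
        import splitvent._kernels as K
        a = net.params[K.LIMB_A:K.LIMB_A + K.LIMB_STRIDE]
        b = net.params[K.LIMB_B:K.LIMB_B + K.LIMB_STRIDE]
        np.testing.assert_array_equal(a, b)

    def test_isothermal_mode_has_no_temperature_states(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        assert build_network(topo, VentilatorSettings()).n_states == 8
        assert build_network(topo, VentilatorSettings(),
                             isothermal=False).n_states == 11


class TestSymmetry:
    def test_identical_lungs_get_identical_volumes(self, symmetric_run):
        wf, _ = symmetric_run
        tv = tvs_of(wf)
        assert abs(tv["A"] - tv["B"]) / tv["A"] < 1e-3

    def test_limb_swap_symmetry(self):
        """Swapping the patients (and the resistor limb) swaps the outputs."""
        s = VentilatorSettings(pip=20, peep=5, respiratory_rate=20)
        topo = two_patient_topology(LungRC(18.0), LungRC(35.0),
                                    resistor=ResistorSpec(4.0), resistor_limb="B")
        swapped = two_patient_topology(LungRC(35.0), LungRC(18.0),
                                       resistor=ResistorSpec(4.0),
                                       resistor_limb="A")
        wf1, _ = Network(topo, s).run_to_steady_state()
        wf2, _ = Network(swapped, s).run_to_steady_state()
        tv1, tv2 = tvs_of(wf1), tvs_of(wf2)
        assert tv1["A"] == pytest.approx(tv2["B"], rel=1e-3)
        assert tv1["B"] == pytest.approx(tv2["A"], rel=1e-3)


class TestQuasiStaticLimit:
    def test_tv_approaches_compliance_times_driving_pressure(self):
        """With negligible resistance everywhere and T_insp >> R·C, each
        breath delivers C·(PIP−PEEP): 600 ml for C 30, PIP 28, PEEP 8."""
        tube = PipeSegment(0.05, 0.022)
        limb = Limb(lung=LungRC(30.0, airway_resistance=0.005),
                    tube=tube, ett=EttSpec(10.0, length=0.05))
        topo = CircuitTopology(limb_a=limb, limb_b=limb,
                               shared_tube=PipeSegment(0.05, 0.022))
        settings = VentilatorSettings(pip=28, peep=8, respiratory_rate=5,
                                      ie_ratio=(1, 1))
        wf, _ = Network(topo, settings).run_to_steady_state()
        tv = tvs_of(wf)
        assert tv["A"] == pytest.approx(600.0, rel=0.01)
        assert tv["B"] == pytest.approx(600.0, rel=0.01)


class TestSteadyState:
    def test_at_least_five_cycles(self, symmetric_run):
        _, used = symmetric_run
        assert used >= 5

    def test_unattainable_tolerance_flags(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        net = Network(topo, VentilatorSettings())
        wf, used = net.run_to_steady_state(max_cycles=6, tol=0.0)
        assert used == 6 and not wf.converged

    def test_zero_driving_pressure_gives_zero_tv(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        net = Network(topo, VentilatorSettings(pip=8, peep=8))
        wf, _ = net.run_to_steady_state(max_cycles=6)
        tv = tvs_of(wf)
        assert tv["A"] == pytest.approx(0.0, abs=1e-6)
        assert tv["B"] == pytest.approx(0.0, abs=1e-6)

    def test_fixed_cycle_simulate_returns_exact_span(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        net = Network(topo, VentilatorSettings(respiratory_rate=20))
        wf = net.simulate(n_cycles=3)
        assert wf.n_cycles == 3
        assert wf.time[-1] == pytest.approx(9.0 - 1e-3, abs=1e-6)


class TestPressureWaveforms:
    def test_resistor_limb_never_reaches_pip(self, fig5_run):
        """The no-resistor patient plateaus at the set PIP while the
        resistor slows the distal pressure build-up on the other limb."""
        wf, _ = fig5_run
        pmax_a, _ = pressure_extrema(wf, patient="A")
        pmax_b, _ = pressure_extrema(wf, patient="B")
        assert pmax_a == pytest.approx(20.0, rel=0.02)
        assert pmax_b < 20.0 * 0.98

    def test_trough_pressure_near_peep(self, fig5_run):
        wf, _ = fig5_run
        _, pmin_a = pressure_extrema(wf, patient="A")
        assert pmin_a == pytest.approx(5.0, abs=0.5)


class TestResistorEffects:
    def test_tv_non_decreasing_in_lumen_and_open_limit(self):
        s = VentilatorSettings(pip=20, peep=5, respiratory_rate=20)
        tvs = []
        for lumen in (3.0, 4.0, 5.0, 6.0, 21.9):
            topo = two_patient_topology(LungRC(18.0), LungRC(35.0),
                                        resistor=ResistorSpec(lumen))
            wf, _ = Network(topo, s).run_to_steady_state()
            tvs.append(tvs_of(wf)["B"])
        assert np.all(np.diff(tvs) > 0)
        topo_open = two_patient_topology(LungRC(18.0), LungRC(35.0))
        wf, _ = Network(topo_open, s).run_to_steady_state()
        assert tvs[-1] == pytest.approx(tvs_of(wf)["B"], rel=0.05)


class TestModeCoupling:
    def test_pc_decoupling(self, fig4_recommendation):
        """PC: changing the limb-B resistor leaves patient A's volume
        essentially untouched."""
        tv_a = fig4_recommendation.table["tv_A_ml"]
        assert (tv_a.max() - tv_a.min()) / tv_a.min() < 0.02

    def test_vc_coupling_raises_other_patients_pressure_and_volume(self):
        s = VentilatorSettings(mode="VC", pip=20, peep=5, respiratory_rate=20,
                               target_tidal_volume=800.0)
        base = two_patient_topology(LungRC(18.0), LungRC(35.0))
        with_res = two_patient_topology(LungRC(18.0), LungRC(35.0),
                                        resistor=ResistorSpec(3.5))
        wf0, _ = Network(base, s).run_to_steady_state()
        wf1, _ = Network(with_res, s).run_to_steady_state()
        pmax0, _ = pressure_extrema(wf0, patient="A")
        pmax1, _ = pressure_extrema(wf1, patient="A")
        assert pmax1 > pmax0
        assert tvs_of(wf1)["A"] > tvs_of(wf0)["A"]


class TestRateAndPeepMonotonicity:
    def test_tv_non_increasing_in_rr(self, rr_series_tvs):
        rates = sorted(rr_series_tvs)
        for pat in (0, 1):
            series = [rr_series_tvs[r][pat] for r in rates]
            assert np.all(np.diff(series) <= 1e-9)

    def test_differential_shrinks_from_rr15_to_rr30(self, rr_series_tvs):
        def diff_pct(pair):
            lo, hi = sorted(pair)
            return 100.0 * (hi - lo) / lo
        assert diff_pct(rr_series_tvs[30.0]) < diff_pct(rr_series_tvs[15.0])

    def test_tv_non_increasing_in_peep(self):
        tvs = []
        for peep in (5.0, 8.0, 12.0):
            topo = two_patient_topology(LungRC(18.0), LungRC(35.0))
            net = Network(topo, VentilatorSettings(pip=20, peep=peep,
                                                   respiratory_rate=20))
            wf, _ = net.run_to_steady_state()
            tvs.append(tvs_of(wf))
        for pat in ("A", "B"):
            series = [t[pat] for t in tvs]
            assert np.all(np.diff(series) <= 1e-9)


class TestConservation:
    def test_junction_residual_small(self, fig5_run):
        wf, _ = fig5_run
        assert junction_residual(wf) <= 1e-8

    def test_rest_state_residual_zero(self):
        topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
        net = Network(topo, VentilatorSettings(pip=8, peep=8))
        wf, _ = net.run_to_steady_state(max_cycles=5)
        assert junction_residual(wf) <= 1e-12

    def test_residual_grows_with_looser_solver_tolerance(self):
        topo = two_patient_topology(LungRC(18.0), LungRC(35.0))
        s = VentilatorSettings(pip=20, peep=5, respiratory_rate=20)
        res = {}
        for rtol in (1e-8, 1e-3):
            wf, _ = Network(topo, s).run_to_steady_state(rtol=rtol)
            res[rtol] = junction_residual(wf)
        assert res[1e-8] <= res[1e-3]


class TestEnergyMode:
    def test_energy_balance_close_to_isothermal(self):
        """Adiabatic-wall energy mode perturbs tidal volumes only mildly and
        keeps gas temperature near the reference."""
        topo = two_patient_topology(LungRC(18.0), LungRC(35.0))
        s = VentilatorSettings(pip=20, peep=5, respiratory_rate=20)
        wf_iso, _ = Network(topo, s).run_to_steady_state()
        net_e = Network(topo, s, isothermal=False)
        wf_e, _ = net_e.run_to_steady_state()
        for pat in ("A", "B"):
            assert tvs_of(wf_e)[pat] == pytest.approx(tvs_of(wf_iso)[pat],
                                                      rel=0.03)
        temps = wf_e._states[:, 8:11]
        assert np.all(np.abs(temps - AIR.reference_temperature) < 5.0)
        assert junction_residual(wf_e) <= 1e-8


class TestSinglePatient:
    def test_degenerate_topology_runs(self):
        topo = CircuitTopology(limb_a=Limb(lung=LungRC(30.0)), limb_b=None)
        net = Network(topo, VentilatorSettings(pip=20, peep=5,
                                               respiratory_rate=20))
        wf, used = net.run_to_steady_state()
        assert wf.patients == ("A",)
        assert used >= 5
        # near-quasi-static: approaches C (PIP - PEEP) = 450 ml from below
        tv = tvs_of(wf)["A"]
        assert 350.0 < tv <= 451.0


class TestWaveformSeries:
    def test_flow_recovery_matches_volume_derivative(self, fig5_run):
        """Lung inflow (recovered from the momentum balances) integrates to
        the same tidal volume as the volume trace, within 0.5%."""
        wf, _ = fig5_run
        s, e = wf.cycle_bounds(wf.n_cycles - 1)
        for pat in ("A", "B"):
            q = wf.flows[f"lung_{pat}"][s:e] / 60.0  # L/s
            t = wf.time[s:e]
            insp = np.trapezoid(np.maximum(q, 0.0), t) * 1e3  # ml
            tv = tidal_volume_per_cycle(wf, pat)[-1]
            assert insp == pytest.approx(tv, rel=5e-3)

    def test_dataframe_round_trip_columns(self, fig5_run):
        wf, _ = fig5_run
        df = wf.to_dataframe()
        assert {"time_s", "cycle", "p_shared_cmH2O", "p_limb_A_cmH2O",
                "q_lung_A_Lmin", "v_A_ml"} <= set(df.columns)
        assert len(df) == len(wf.time)
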