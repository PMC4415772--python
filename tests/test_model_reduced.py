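"""Reduced-model physics: determinism, conservation, scaling linearity,
steady-state pacing, and integrator convergence against an independent
adaptive-solver oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiofit import (
    ParameterScaling,
    SimulationSettings,
    StimulusSequence,
    decompose_currents,
    multistep_protocol,
    optimization_sequence,
    pace_to_steady_state,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from cardiofit.models.base import SolverError


class TestDeterminism:
    def test_current_clamp_bit_identical(self, reduced_model, base_state, settings, truth):
        seq = optimization_sequence()
        a = simulate_current_clamp(reduced_model, truth, base_state, seq, settings=settings)
        b = simulate_current_clamp(reduced_model, truth, base_state, seq, settings=settings)
        assert np.array_equal(a.values, b.values)

    def test_steady_state_bit_identical(self, reduced_model, settings, truth):
        a = pace_to_steady_state(reduced_model, truth, n_beats=5, settings=settings)
        b = pace_to_steady_state(reduced_model, truth, n_beats=5, settings=settings)
        assert np.array_equal(a.values, b.values)


class TestSteadyState:
    def test_final_beat_is_stationary(self, reduced_model, settings, truth):
        """One further beat changes every state variable by < 0.1 % relative."""
        s1800 = pace_to_steady_state(reduced_model, truth, settings=settings)
        s1801 = pace_to_steady_state(reduced_model, truth, n_beats=1,
                                     settings=settings, initial=s1800)
        rel = np.abs(s1801.values - s1800.values) / np.maximum(
            np.abs(s1800.values), 1e-12
        )
        assert np.all(rel < 1e-3)

    def test_early_beats_still_transient(self, reduced_model, settings, truth):
        s1 = pace_to_steady_state(reduced_model, truth, n_beats=1, settings=settings)
        s2 = pace_to_steady_state(reduced_model, truth, n_beats=2, settings=settings)
        assert not np.array_equal(s1.values, s2.values)

    def test_invalid_pacing_rejected(self, reduced_model, settings, truth):
        with pytest.raises(ValueError):
            pace_to_steady_state(reduced_model, truth, n_beats=0, settings=settings)
        with pytest.raises(ValueError):
            pace_to_steady_state(reduced_model, truth, cycle_length=0.5,
                                 settings=settings)


class TestCurrentClamp:
    def test_no_stimulus_stays_at_rest(self, reduced_model, base_state, settings, truth):
        seq = StimulusSequence((100.0,), amplitude=0.0, duration=1000.0)
        tr = simulate_current_clamp(reduced_model, truth, base_state, seq,
                                    settings=settings, prepace=False)
        assert np.all(np.abs(tr.values - tr.values[0]) < 1.0)

    def test_printed_sequence_elicits_11_upstrokes(self, reduced_model, base_state,
                                                   settings, truth):
        tr = simulate_current_clamp(reduced_model, truth, base_state,
                                    optimization_sequence(), settings=settings)
        v = tr.values
        upstrokes = np.sum((v[1:] > -20.0) & (v[:-1] <= -20.0))
        assert upstrokes == 11

    def test_prepace_excluded_from_trace(self, reduced_model, base_state, settings, truth):
        seq = StimulusSequence((100.0,), duration=1000.0)
        tr = simulate_current_clamp(reduced_model, truth, base_state, seq,
                                    settings=settings, prepace=True)
        assert tr.times[0] == 0.0
        assert tr.times[-1] == pytest.approx(1000.0)

    def test_gates_remain_in_unit_interval(self, reduced_model, base_state,
                                           settings, truth):
        _, _, _, final = reduced_model.run_current_clamp(
            truth.as_array(), base_state.values,
            optimization_sequence().onset_array(), -40.0, 1.0, 5000.0,
            record_start=0.0, dt=0.05, out_dt=0.1,
        )
        gates = final[1:8]
        assert np.all((gates >= 0.0) & (gates <= 1.0))
        assert final[8] > 0 and final[9] > 0  # calcium pools positive


class TestVoltageClamp:
    def test_near_equilibrium_hold_small_current(self, reduced_model, base_state,
                                                 settings, truth):
        from cardiofit.protocols import VoltageClampProtocol

        rest = base_state.values[0]
        proto = VoltageClampProtocol(((1000.0, rest),))
        tr = simulate_voltage_clamp(reduced_model, truth, base_state, proto,
                                    settings=settings)
        after = tr.values[tr.times >= 100.0]
        assert np.all(np.abs(after) < 0.5)

    def test_total_equals_sum_of_decomposition(self, reduced_model, base_state,
                                               settings, truth):
        proto = multistep_protocol()
        total = simulate_voltage_clamp(reduced_model, truth, base_state, proto,
                                       settings=settings)
        parts = decompose_currents(reduced_model, truth, base_state, proto,
                                   settings=settings)
        summed = np.sum([p.values for p in parts.values()], axis=0)
        assert np.max(np.abs(summed - total.values)) < 1e-9

    def test_trace_covers_protocol_proper_only(self, reduced_model, base_state,
                                               settings, truth):
        tr = simulate_voltage_clamp(reduced_model, truth, base_state,
                                    multistep_protocol(), settings=settings)
        assert tr.times[0] == 0.0
        assert tr.times[-1] == pytest.approx(6000.0)


class TestScalingLinearity:
    def test_doubling_k1_scaling_doubles_instantaneous_ik1(self, reduced_model,
                                                           base_state, truth):
        c1 = reduced_model.currents_at(base_state.values, truth.as_array())
        c2 = reduced_model.currents_at(
            base_state.values, truth.replace(s_K1=2.0).as_array()
        )
        assert c2["I_K1"] == pytest.approx(2.0 * c1["I_K1"], rel=1e-12)
        for name in ("I_Na", "I_CaL", "I_Kr", "I_NaCa"):
            assert c2[name] == c1[name]

    @pytest.mark.parametrize("pname, cname", [
        ("s_Na", "I_Na"), ("s_CaL", "I_CaL"), ("s_CaT", "I_CaT"),
        ("s_Kr", "I_Kr"), ("s_Ks", "I_Ks"), ("s_Kp", "I_Kp"), ("s_pCa", "I_pCa"),
    ])
    def test_each_scaling_enters_multiplicatively(self, reduced_model, truth,
                                                  pname, cname):
        state = np.array([-20.0, 0.5, 0.3, 0.4, 0.6, 0.5, 0.1, 0.2, 2e-4, 1.5])
        c1 = reduced_model.currents_at(state, truth.as_array())
        c3 = reduced_model.currents_at(
            state, truth.replace(**{pname: 3.0}).as_array()
        )
        assert c3[cname] == pytest.approx(3.0 * c1[cname], rel=1e-12)


class TestIntegratorAccuracy:
    def test_matches_adaptive_oracle_on_stimulated_segment(self, reduced_model, truth):
        """Fine-step kernel vs scipy LSODA on the same equations (100 ms, 1 AP)."""
        y0 = reduced_model.initial_state().values
        seq = StimulusSequence((5.0,), duration=100.0)
        t_out, v_kernel, _, _ = reduced_model.run_current_clamp(
            truth.as_array(), y0, seq.onset_array(), -40.0, 1.0, 100.0,
            record_start=0.0, dt=0.001, out_dt=0.1,
        )

        def rhs(t, y):
            istim = -40.0 if 5.0 <= t < 6.0 else 0.0
            return reduced_model.rhs(t, y, truth.as_array(), istim)

        sol = solve_ivp(rhs, (0.0, 100.0), y0, method="LSODA", t_eval=t_out,
                        rtol=1e-9, atol=1e-10, max_step=1.0)
        assert sol.success
        assert np.max(np.abs(sol.y[0] - v_kernel)) < 0.5

    def test_step_halving_converged_on_clamp_protocol(self, reduced_model,
                                                      base_state, truth):
        proto = multistep_protocol()
        coarse = simulate_voltage_clamp(reduced_model, truth, base_state, proto,
                                        settings=SimulationSettings(dt=0.05))
        fine = simulate_voltage_clamp(reduced_model, truth, base_state, proto,
                                      settings=SimulationSettings(dt=0.025))
        # compare away from step transitions where the clamp current is discontinuous
        from cardiofit.objective import mask_capacitance_transients

        masked = mask_capacitance_transients(coarse, proto, window=2.0)
        diff = np.abs(coarse.values - fine.values)[masked.mask]
        assert np.max(diff) < 0.1


class TestFailureHandling:
    def test_solver_error_names_time(self, reduced_model, base_state, settings):
        # pathologically large sodium conductance at a huge step drives overflow
        wild = ParameterScaling(s_Na=2.99, s_K1=1e-4, s_Kr=1e-4, s_Ks=1e-4,
                                s_Kp=1e-4, s_pCa=2.99, s_SERCA=2.99)
        seq = StimulusSequence(tuple(np.arange(0.0, 4999.0, 100.0)),
                               amplitude=-500.0, duration=5000.0)
        try:
            simulate_current_clamp(reduced_model, wild, base_state, seq,
                                   settings=settings, prepace=False)
        except SolverError as e:
            assert "ms" in str(e)
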