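import numpy as np
import pytest

from cardiofit import ParameterScaling, Trace
from cardiofit.experiment_io import (
    RecordedTrace,
    SINGLE_AP_SEQUENCE,
    TraceParseError,
    TrialSet,
    generate_synthetic_target,
    load_state,
    make_objective_target,
    read_trace,
    save_state,
    select_best_trial,
    write_trace,
)
from cardiofit.objective import error_combined


class TestTraceFiles:
    def _trace(self):
        t = np.array([0.0, 0.1, 0.25, 1.0, 2.0])
        v = np.array([-84.123456789, -84.0, 12.5, -20.0, -84.1])
        return Trace(t, v, "mV")

    def test_round_trip_is_lossless(self, tmp_path):
        rec = RecordedTrace(self._trace(), cell_id="cell-2",
                            mode="current-clamp", protocol_ref="optimization")
        path = tmp_path / "trace.csv"
        write_trace(rec, path)
        back = read_trace(path)
        assert np.array_equal(back.times, rec.times)
        assert np.array_equal(back.values, rec.values)
        assert back.unit == "mV"
        assert back.cell_id == "cell-2"
        assert back.mode == "current-clamp"

    def test_bare_trace_round_trip(self, tmp_path):
        path = tmp_path / "bare.csv"
        write_trace(self._trace(), path)
        back = read_trace(path)
        assert np.array_equal(back.values, self._trace().values)

    def test_decreasing_time_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_ms,mV\n0.0,1.0\n0.2,2.0\n0.1,3.0\n")
        with pytest.raises(TraceParseError, match=":4"):
            read_trace(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "noheader.csv"
        path.write_text("0.0,1.0\n0.1,2.0\n")
        with pytest.raises(TraceParseError, match="header"):
            read_trace(path)

    def test_unknown_unit_rejected(self, tmp_path):
        path = tmp_path / "badunit.csv"
        path.write_text("time_ms,furlongs\n0.0,1.0\n")
        with pytest.raises(TraceParseError, match="unit"):
            read_trace(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("time_ms,mV\n0.0,1.0\n0.1,2.0,3.0\n")
        with pytest.raises(TraceParseError, match="2 columns"):
            read_trace(path)

    def test_voltage_trace_in_current_slot_fails_downstream(self, tmp_path):
        from cardiofit.objective import error_voltage_clamp

        path = tmp_path / "v.csv"
        write_trace(self._trace(), path)
        rec = read_trace(path)
        with pytest.raises(ValueError, match="unit"):
            error_voltage_clamp(rec.trace, rec.trace)


class TestTrialSelection:
    def _trial(self, peak_offset, ref="multistep"):
        t = np.arange(595.0, 630.0, 0.1)
        v = np.zeros_like(t)
        # inward sodium spike at 600 + offset
        spike = np.exp(-((t - (600.0 + peak_offset)) / 0.4) ** 2)
        v -= 30.0 * spike
        return RecordedTrace(Trace(t, v, "A/F"), protocol_ref=ref)

    def test_shortest_time_to_peak_selected(self):
        trials = TrialSet((self._trial(1.1), self._trial(0.9), self._trial(1.3)))
        assert select_best_trial(trials) is trials.trials[1]

    def test_identical_trials_tie_break_first(self):
        trials = TrialSet((self._trial(1.0), self._trial(1.0), self._trial(1.0)))
        assert select_best_trial(trials) is trials.trials[0]

    def test_time_shifted_copies_prefer_unshifted(self):
        base = self._trial(0.8)
        shifted1 = self._trial(0.8 + 0.5)
        shifted2 = self._trial(0.8 + 1.0)
        trials = TrialSet((shifted1, base, shifted2))
        assert select_best_trial(trials) is base

    def test_missing_window_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        short = RecordedTrace(Trace(t, np.zeros_like(t), "A/F"),
                              protocol_ref="multistep")
        trials = TrialSet((short, short, short))
        with pytest.raises(ValueError, match="window"):
            select_best_trial(trials)

    def test_mismatched_protocols_rejected(self):
        with pytest.raises(ValueError, match="protocols"):
            TrialSet((self._trial(1.0, "a"), self._trial(1.0, "b"),
                      self._trial(1.0, "a")))


class TestSyntheticTarget:
    def test_truth_candidate_scores_zero(self, reduced_model, settings, truth,
                                         synth_target, context):
        e = context.evaluate(truth, synth_target.target)
        assert e.total == 0.0

    def test_same_seed_bit_identical(self, reduced_model, settings, truth):
        a = generate_synthetic_target(reduced_model, truth, noise_sd=(0.5, 0.1),
                                      seed=11, settings=settings)
        b = generate_synthetic_target(reduced_model, truth, noise_sd=(0.5, 0.1),
                                      seed=11, settings=settings)
        assert np.array_equal(a.target.voltage.values, b.target.voltage.values)
        assert np.array_equal(a.target.current.values, b.target.current.values)

    def test_masks_attached(self, synth_target):
        # 11 stimuli x 13 samples, 11 transitions x 12 samples
        assert (~synth_target.target.voltage.mask).sum() == 143
        assert (~synth_target.target.current.mask).sum() == 132

    def test_voltage_noise_raises_error_by_chi_square_expectation(
            self, reduced_model, settings, truth, context, synth_target):
        noisy = generate_synthetic_target(reduced_model, truth,
                                          noise_sd=(1.0, 0.0), seed=5,
                                          settings=settings)
        e = context.evaluate(truth, noisy.target)
        n_inc = int(noisy.target.voltage.mask.sum())
        # E[sum of squares] = N * sd^2; relative sampling error ~ sqrt(2/N)
        assert e.cc == pytest.approx(n_inc * 1.0, rel=0.02)
        assert e.vc == 0.0

    def test_negative_noise_rejected(self, reduced_model, settings, truth):
        with pytest.raises(ValueError):
            generate_synthetic_target(reduced_model, truth, noise_sd=(-1.0, 0.0),
                                      settings=settings)

    def test_variant_selection(self, synth_target):
        stoch = make_objective_target(synth_target, "stochastic")
        assert stoch.voltage is not None and stoch.current is None
        vc = make_objective_target(synth_target, "vclamp")
        assert vc.voltage is None and vc.current is not None
        with pytest.raises(ValueError):
            make_objective_target(synth_target, "nope")

    def test_single_ap_sequence_shape(self):
        assert len(SINGLE_AP_SEQUENCE) == 1
        assert SINGLE_AP_SEQUENCE.duration == 500.0


class TestStateSnapshots:
    def test_round_trip_bit_exact(self, reduced_model, base_state, tmp_path):
        path = tmp_path / "state.txt"
        save_state(base_state, path)
        back = load_state(path, reduced_model)
        assert np.array_equal(back.values, base_state.values)
        assert back.names == base_state.names

    def test_wrong_model_rejected(self, flagship_model, base_state, tmp_path):
        path = tmp_path / "state.txt"
        save_state(base_state, path)
        with pytest.raises(ValueError, match="model"):
            load_state(path, flagship_model)
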