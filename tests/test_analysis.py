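import numpy as np
import pytest

from cardiofit import ParameterScaling
from cardiofit.analysis import (
    SENSITIVITY_LEVELS,
    correlation_analysis,
    local_sensitivity,
    median_absolute_recovery_error,
    multi_parameter_sensitivity,
    progression_analysis,
    recovery_report,
)
from cardiofit.ga import GAConfig, GARunResult, GenerationStats, Individual, run_ga
from cardiofit.objective import ErrorValue
from cardiofit.parameters import N_PARAMETERS, PARAMETER_NAMES


def _individuals(rows):
    return [Individual(ParameterScaling.from_array(r), ErrorValue(cc=1.0))
            for r in rows]


class TestRecoveryReport:
    def test_degenerate_ensemble_contains_truth_with_zero_sd(self):
        truth = ParameterScaling()
        rep = recovery_report(_individuals([np.ones(9), np.ones(9)]), truth)
        assert np.all(rep.sd == 0)
        assert rep.n_contained == 9

    def test_containment_is_mean_plus_minus_sd(self):
        truth = ParameterScaling()
        rows = [np.ones(9) * 0.9, np.ones(9) * 1.05, np.ones(9) * 1.1]
        rep = recovery_report(_individuals(rows), truth)
        mean, sd = np.mean([0.9, 1.05, 1.1]), np.std([0.9, 1.05, 1.1], ddof=1)
        expected = abs(mean - 1.0) <= sd
        assert np.all(rep.contained == expected)

    def test_ttest_of_identical_samples_is_p1(self):
        rep = recovery_report(
            _individuals([np.ones(9)] * 3), ParameterScaling(),
            prediction_errors=[1.0, 2.0, 3.0],
            reference_prediction_errors=[1.0, 2.0, 3.0],
        )
        assert rep.ttest == (0.0, 1.0)

    def test_ttest_detects_separated_samples(self):
        rep = recovery_report(
            _individuals([np.ones(9)] * 3), ParameterScaling(),
            prediction_errors=[1.0, 1.1, 0.9, 1.05],
            reference_prediction_errors=[10.0, 10.5, 9.5, 10.2],
        )
        stat, p = rep.ttest
        assert p < 0.05 and stat < 0

    def test_median_absolute_recovery_error(self):
        rows = [np.ones(9) * 1.2, np.ones(9) * 0.8]
        assert median_absolute_recovery_error(
            _individuals(rows), ParameterScaling()
        ) == pytest.approx(0.0)  # means cancel to 1.0
        rows = [np.ones(9) * 1.2, np.ones(9) * 1.2]
        assert median_absolute_recovery_error(
            _individuals(rows), ParameterScaling()
        ) == pytest.approx(0.2)


class TestCorrelation:
    def test_duplicated_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0.5, 1.5, 40)
        mat = rng.uniform(0.5, 1.5, (40, 9))
        mat[:, 1] = mat[:, 0] = col
        res = correlation_analysis(mat)
        assert res.matrix[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(res.matrix) == 1.0)
        assert np.allclose(res.matrix, res.matrix.T, equal_nan=True)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0.5, 1.5, (2000, 9))
        res = correlation_analysis(mat)
        off = res.matrix[~np.eye(9, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08

    def test_constant_column_flagged_undefined(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(0.5, 1.5, (30, 9))
        mat[:, 4] = 1.0
        res = correlation_analysis(mat)
        assert not res.defined[4, 0]
        assert np.isnan(res.matrix[4, 0])
        assert not res.significant[4, 0]

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            correlation_analysis(np.ones((5, 9)))

    def test_pooled_best_fraction_from_runs(self):
        rng = np.random.default_rng(3)

        def fake_run(seed):
            pop = rng.uniform(0.5, 1.5, (100, 9))
            errs = rng.uniform(0, 1, 100)
            return GARunResult(seed=seed, history=[], best=None,
                               final_population=pop, final_errors=errs)

        res = correlation_analysis([fake_run(k) for k in range(3)],
                                   top_fraction=0.1)
        assert res.n_individuals == 30


class TestProgression:
    def _run_with_pops(self, pops):
        return GARunResult(seed=0, history=[], best=None,
                           final_population=pops[-1],
                           final_errors=np.zeros(len(pops[-1])),
                           populations=pops)

    def test_constant_parameter_has_zero_cv(self):
        pop = np.ones((20, 9))
        res = progression_analysis([self._run_with_pops([pop, pop])])
        assert np.allclose(res.cv_squared, 0.0)

    def test_uniform_generation0_matches_moments(self):
        rng = np.random.default_rng(0)
        a, b = 1e-4, 2.99
        pop = rng.uniform(a, b, (20000, 9))
        res = progression_analysis([self._run_with_pops([pop])])
        expected = ((b - a) ** 2 / 12) / ((a + b) / 2) ** 2
        assert np.allclose(res.cv_squared[:, 0], expected, rtol=0.05)

    def test_requires_stored_populations(self):
        run = GARunResult(seed=0, history=[], best=None,
                          final_population=np.ones((5, 9)),
                          final_errors=np.zeros(5))
        with pytest.raises(ValueError):
            progression_analysis([run])

    def test_converged_run_shrinks_cv(self, context, synth_target):
        from cardiofit.experiment_io import make_objective_target

        cfg = GAConfig(population_size=20, generations=8, seed=2)
        res = run_ga(cfg, make_objective_target(synth_target, "stochastic"),
                     context, store_populations=True)
        prog = progression_analysis([res])
        # the best-converged parameter tightens from generation 0 to the end
        shrink = prog.cv_squared[:, -1] / prog.cv_squared[:, 0]
        assert shrink.min() < 1.0


@pytest.fixture(scope="module")
def sens(reduced_model, synth_target, settings):
    return local_sensitivity(reduced_model, synth_target,
                             variant="combined", settings=settings)


class TestLocalSensitivity:

    def test_shape_and_nonnegativity(self, sens):
        assert sens.errors.shape == (9, len(SENSITIVITY_LEVELS))
        assert np.all(sens.errors >= 0)
        assert np.all(sens.errors > 0)  # every parameter observable

    def test_larger_perturbations_cost_more(self, sens):
        # 20% vs 5% on the same side, for every parameter
        lv = list(sens.levels)
        assert sens.errors[:, lv.index(0.80)].min() > 0
        worse = sens.errors[:, lv.index(0.80)] >= sens.errors[:, lv.index(0.95)]
        assert worse.all()

    def test_calcium_signal_ranks_calcium_parameters_first(
            self, reduced_model, synth_target, settings):
        res = local_sensitivity(reduced_model, synth_target, variant="combined",
                                signal="calcium", settings=settings)
        top3 = set(res.ranking()[:3])
        assert top3 & {"s_CaL", "s_SERCA", "s_pCa"}


class TestMultiParameterSensitivity:
    def test_pinned_parameters_not_significant(self, reduced_model, synth_target,
                                               settings):
        spans = np.zeros(N_PARAMETERS)
        spans[PARAMETER_NAMES.index("s_Kr")] = 0.3
        res = multi_parameter_sensitivity(
            reduced_model, synth_target, n_samples=60, seed=4, spans=spans,
            settings=settings,
        )
        kr = PARAMETER_NAMES.index("s_Kr")
        assert res.significant[kr]
        assert not res.significant[np.arange(9) != kr].any()

    def test_deterministic_for_seed(self, reduced_model, synth_target, settings):
        a = multi_parameter_sensitivity(reduced_model, synth_target,
                                        n_samples=50, seed=9, settings=settings)
        b = multi_parameter_sensitivity(reduced_model, synth_target,
                                        n_samples=50, seed=9, settings=settings)
        assert np.array_equal(a.effects, b.effects)
        assert np.array_equal(a.pvalues, b.pvalues)

    def test_small_sample_rejected(self, reduced_model, synth_target, settings):
        with pytest.raises(ValueError):
            multi_parameter_sensitivity(reduced_model, synth_target,
                                        n_samples=10, settings=settings)

    def test_all_pinned_rejected(self, reduced_model, synth_target, settings):
        with pytest.raises(ValueError):
            multi_parameter_sensitivity(
                reduced_model, synth_target, n_samples=50,
                spans=np.zeros(N_PARAMETERS), settings=settings,
            )
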