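"""Identifiability and convergence diagnostics.

These analyses explain *why* particular conductances are well or poorly
determined by a protocol: local single-parameter sensitivity of the
objective, joint multi-parameter sensitivity with significance calls,
per-parameter convergence speed of the GA population (squared coefficient of
variation across generations), pairwise parameter correlations among
low-error individuals (compensatory parameter pairs), and ensemble recovery
reports with two-sample t-tests on prediction errors.

All analyses are pure functions of run artifacts or of fresh simulations and
can be re-run offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .ga import GARunResult, Individual, SimulationContext
from .models.base import IonicModel, SimulationSettings
from .objective import error_combined
from .parameters import N_PARAMETERS, PARAMETER_NAMES, ParameterScaling
from .experiment_io import SyntheticTarget, make_objective_target
from .simulation import simulate_current_clamp, simulate_voltage_clamp
from .trace import Trace

#: Scaling levels probed by the local sensitivity analysis (fractions of baseline).
SENSITIVITY_LEVELS = (0.80, 0.90, 0.95, 1.05, 1.10, 1.20)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class SensitivityResult:
    parameters: Tuple[str, ...]
    levels: Tuple[float, ...]
    errors: np.ndarray  # (n_parameters, n_levels)
    variant: str
    signal: str

    def ranking(self) -> List[str]:
        """Parameters ordered from most to least sensitive (summed error)."""
        order = np.argsort(-self.errors.sum(axis=1), kind="stable")
        return [self.parameters[i] for i in order]


def local_sensitivity(
    model: IonicModel,
    synth: SyntheticTarget,
    variant: str = "combined",
    signal: str = "membrane",
    levels: Sequence[float] = SENSITIVITY_LEVELS,
    settings: SimulationSettings = SimulationSettings(),
) -> SensitivityResult:
    """Objective error from perturbing one parameter at a time.

    ``signal='membrane'`` scores the usual voltage/current objective;
    ``signal='calcium'`` substitutes the intracellular calcium concentration
    into the same sum-of-squares, probing which parameters a fluorescence
    objective would constrain.
    """
    target = make_objective_target(synth, variant)
    base = synth.base_state
    use_cc = target.voltage is not None
    use_vc = target.current is not None

    def responses(scaling):
        out = {}
        if use_cc:
            v, ca = simulate_current_clamp(
                model, scaling, base, target.stimuli, settings=settings,
                prepace=True, record_ca=True,
            )
            out["cc"] = ca if signal == "calcium" else v
            out["cc_mask"] = target.voltage.mask
        if use_vc:
            i, ca = simulate_voltage_clamp(
                model, scaling, base, target.protocol, settings=settings,
                record_ca=True,
            )
            out["vc"] = ca if signal == "calcium" else i
            out["vc_mask"] = target.current.mask
        return out

    ref = responses(synth.truth)
    errors = np.zeros((N_PARAMETERS, len(levels)))
    for ip, name in enumerate(PARAMETER_NAMES):
        for il, level in enumerate(levels):
            scaling = synth.truth.replace(
                **{name: getattr(synth.truth, name) * level}
            )
            pert = responses(scaling)
            e = 0.0
            for part in ("cc", "vc"):
                if part in ref:
                    m = ref[part + "_mask"]
                    d = ref[part].values[m] - pert[part].values[m]
                    e += float(np.dot(d, d))
            errors[ip, il] = e
    return SensitivityResult(
        PARAMETER_NAMES, tuple(levels), errors, variant, signal
    )


@dataclass
class MultiParameterSensitivity:
    parameters: Tuple[str, ...]
    effects: np.ndarray  # standardized regression coefficients on log error
    pvalues: np.ndarray
    significant: np.ndarray  # bool, at the 0.05 level
    n_samples: int


def multi_parameter_sensitivity(
    model: IonicModel,
    synth: SyntheticTarget,
    n_samples: int = 100,
    seed: int = 0,
    span: float = 0.2,
    variant: str = "combined",
    settings: SimulationSettings = SimulationSettings(),
    spans: Optional[np.ndarray] = None,
) -> MultiParameterSensitivity:
    """Joint random perturbation of all parameters with regression read-out.

    Scalings are drawn jointly uniform within ±``span`` of the truth
    (per-parameter overridable through ``spans``; a zero span pins that
    parameter) and the objective error is computed for each draw.  Because
    the error is V-shaped around the truth, ``log10(error)`` is regressed on
    the standardized *absolute deviations* |s - truth|; the reported effect
    sizes are those standardized coefficients, and parameters with p < 0.05
    are flagged significant.
    """
    import statsmodels.api as sm

    if n_samples < 50:
        raise ValueError("n_samples must be >= 50 for a stable regression")
    target = make_objective_target(synth, variant)
    context = SimulationContext(model, synth.base_state, settings)
    rng = np.random.default_rng(seed)
    truth = synth.truth.as_array()
    if spans is None:
        spans = np.full(N_PARAMETERS, span)
    spans = np.asarray(spans, float)
    lo = truth * (1.0 - spans)
    hi = truth * (1.0 + spans)
    X = rng.uniform(lo, hi, size=(n_samples, N_PARAMETERS))
    y = np.empty(n_samples)
    for k in range(n_samples):
        e = context.evaluate(ParameterScaling.from_array(X[k]), target)
        y[k] = np.log10(max(e.total, 1e-300))

    D = np.abs(X - truth)
    sd = D.std(axis=0, ddof=1)
    varying = sd > 0
    if not varying.any():
        raise ValueError("all parameters pinned; regression design is singular")
    Z = (D[:, varying] - D[:, varying].mean(axis=0)) / sd[varying]
    fit = sm.OLS(y, sm.add_constant(Z)).fit()
    effects = np.zeros(N_PARAMETERS)
    pvalues = np.ones(N_PARAMETERS)
    effects[varying] = fit.params[1:]
    pvalues[varying] = fit.pvalues[1:]
    return MultiParameterSensitivity(
        PARAMETER_NAMES, np.abs(effects), pvalues,
        pvalues < SIGNIFICANCE_LEVEL, n_samples,
    )


@dataclass
class ProgressionResult:
    parameters: Tuple[str, ...]
    cv_squared: np.ndarray  # (n_parameters, n_generations), mean over runs
    defined: np.ndarray  # bool mask; False where a zero-mean population occurred


def progression_analysis(results: Sequence[GARunResult]) -> ProgressionResult:
    """Squared coefficient of variation per parameter per generation.

    Fast-shrinking dispersion marks parameters the objective constrains
    strongly; slowly converging parameters are weakly determined.  Requires
    runs executed with ``store_populations=True``.
    """
    if not results or results[0].populations is None:
        raise ValueError("progression analysis needs stored per-generation populations")
    n_gen = len(results[0].populations)
    acc = np.zeros((N_PARAMETERS, n_gen))
    defined = np.ones((N_PARAMETERS, n_gen), dtype=bool)
    for res in results:
        for g, pop in enumerate(res.populations):
            mean = pop.mean(axis=0)
            var = pop.var(axis=0)
            zero = mean == 0
            defined[zero, g] = False
            safe_mean = np.where(zero, 1.0, mean)
            acc[:, g] += np.where(zero, np.nan, var / safe_mean**2)
    return ProgressionResult(PARAMETER_NAMES, acc / len(results), defined)


@dataclass
class CorrelationResult:
    parameters: Tuple[str, ...]
    matrix: np.ndarray  # (9, 9) Pearson r
    pvalues: np.ndarray
    significant: np.ndarray
    defined: np.ndarray  # False where a parameter column was constant
    n_individuals: int


def correlation_analysis(
    source,
    top_fraction: float = 0.05,
) -> CorrelationResult:
    """Pairwise linear correlations among low-error individuals.

    ``source`` is either a sequence of :class:`GARunResult` (final
    populations are pooled and the best ``top_fraction`` by error retained)
    or a raw (n, 9) scaling matrix.  Negative off-diagonal entries flag
    compensatory parameter pairs (one conductance trading off against
    another while the objective stays flat).
    """
    if isinstance(source, np.ndarray):
        mat = source
    else:
        pops = np.vstack([r.final_population for r in source])
        errs = np.concatenate([r.final_errors for r in source])
        keep = max(int(round(top_fraction * len(errs))), 2)
        mat = pops[np.argsort(errs, kind="stable")[:keep]]
    n = mat.shape[0]
    if n < 10:
        raise ValueError("need at least 10 parameter vectors for correlations")
    r = np.eye(N_PARAMETERS)
    p = np.zeros((N_PARAMETERS, N_PARAMETERS))
    defined = np.ones((N_PARAMETERS, N_PARAMETERS), dtype=bool)
    sd = mat.std(axis=0)
    for i in range(N_PARAMETERS):
        for j in range(i + 1, N_PARAMETERS):
            if sd[i] == 0 or sd[j] == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                continue
            rr, pp = stats.pearsonr(mat[:, i], mat[:, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    with np.errstate(invalid="ignore"):
        significant = np.where(np.isnan(p), False, p < SIGNIFICANCE_LEVEL)
    return CorrelationResult(PARAMETER_NAMES, r, p, significant, defined, n)


@dataclass
class RecoveryReport:
    parameters: Tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    truth: np.ndarray
    contained: np.ndarray  # truth within mean +/- SD
    prediction_errors: Optional[np.ndarray] = None
    ttest: Optional[Tuple[float, float]] = None  # (statistic, p) vs reference

    @property
    def n_contained(self) -> int:
        return int(self.contained.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": self.sd,
                "truth": self.truth,
                "contained": self.contained,
            },
            index=list(self.parameters),
        )


def recovery_report(
    individuals: Sequence[Individual],
    truth: ParameterScaling,
    prediction_errors: Optional[Sequence[float]] = None,
    reference_prediction_errors: Optional[Sequence[float]] = None,
) -> RecoveryReport:
    """Per-parameter mean ± SD of an ensemble's best individuals vs truth.

    When two sets of prediction errors are supplied (e.g. combined-objective
    vs single-AP fits), an unpaired two-sample t-test at the 0.05 level
    compares them.
    """
    mat = np.array([ind.scaling.as_array() for ind in individuals])
    mean = mat.mean(axis=0)
    sd = (
        mat.std(axis=0, ddof=1) if mat.shape[0] >= 2 else np.zeros(N_PARAMETERS)
    )
    tr = truth.as_array()
    contained = np.abs(mean - tr) <= sd
    ttest = None
    pe = None
    if prediction_errors is not None:
        pe = np.asarray(prediction_errors, float)
        if reference_prediction_errors is not None:
            ref = np.asarray(reference_prediction_errors, float)
            if np.array_equal(pe, ref):
                ttest = (0.0, 1.0)
            else:
                t, p = stats.ttest_ind(pe, ref)
                ttest = (float(t), float(p))
    return RecoveryReport(PARAMETER_NAMES, mean, sd, tr, contained, pe, ttest)


def median_absolute_recovery_error(
    individuals: Sequence[Individual], truth: ParameterScaling
) -> float:
    """Median over the 9 parameters of |mean estimate - truth|."""
    mat = np.array([ind.scaling.as_array() for ind in individuals])
    return float(np.median(np.abs(mat.mean(axis=0) - truth.as_array())))


# ---------------------------------------------------------------------------
# Figures (kept deliberately simple; styling is not part of the contract)

def plot_error_progression(results: Sequence[GARunResult], path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for res in results:
        ax.semilogy([h.generation for h in res.history],
                    [h.best for h in res.history], lw=1)
    ax.set_xlabel("generation")
    ax.set_ylabel("best-individual error")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_parameter_estimates(report: RecoveryReport, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(report.parameters))
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.errorbar(x, report.mean, yerr=report.sd, fmt="o", capsize=3)
    ax.axhline(1.0, ls="--", c="k", lw=0.8)
    ax.set_xticks(x, [p[2:] for p in report.parameters], rotation=45)
    ax.set_ylabel("parameter scaling")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
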