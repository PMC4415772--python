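"""Genetic-algorithm estimation of the nine conductance/flux scalings.

A real-coded GA searches the nine-dimensional scaling space against an
:class:`~cardiofit.objective.ObjectiveTarget`.  Defaults follow the
production-scale settings (population 500, 100 generations, per-parameter
bounds 0.01–299 % of baseline, 10 runs per problem); the operator suite is
tournament selection (size 2), two-point crossover (rate 0.9), per-gene
Gaussian mutation (rate 1/9, SD 10 % of the bound width, clipped to bounds)
and single-individual elitism — all configurable.

Because the GA is stochastic it is run as an ensemble of independent seeded
runs; the per-parameter span of the ensemble's best individuals can be fed
back as refined bounds for a second, local, set of runs (iterative
refinement).  Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models.base import IonicModel, ModelState, SimulationSettings, SolverError
from .objective import ErrorValue, ObjectiveTarget, error_combined
from .parameters import N_PARAMETERS, PARAMETER_NAMES, ParameterScaling
from .simulation import simulate_current_clamp, simulate_voltage_clamp

logger = logging.getLogger(__name__)

#: Default per-parameter search bounds: 0.01 % to 299 % of the baseline value.
DEFAULT_BOUNDS = (1.0e-4, 2.99)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 500
    generations: int = 100
    bounds: Tuple[Tuple[float, float], ...] = tuple([DEFAULT_BOUNDS] * N_PARAMETERS)
    crossover_rate: float = 0.9
    crossover_kind: str = "blend"  # "blend" (BLX-alpha) or "two_point"
    blend_alpha: float = 0.3
    mutation_rate: float = 1.0 / N_PARAMETERS
    mutation_width: float = 0.1  # SD as a fraction of the bound width
    mutation_decay: float = 0.95  # per-generation multiplier on the width
    tournament_size: int = 2
    elite_count: int = 5
    seed: int = 0
    n_runs: int = 10

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        b = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(b) != N_PARAMETERS:
            raise ValueError(f"need {N_PARAMETERS} bound pairs")
        if any(lo >= hi for lo, hi in b):
            raise ValueError("each bound must satisfy low < high")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        object.__setattr__(self, "bounds", b)

    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])


@dataclass
class Individual:
    scaling: ParameterScaling
    error: Optional[ErrorValue] = None

    @property
    def fitness(self) -> float:
        return np.inf if self.error is None else self.error.total


@dataclass
class GenerationStats:
    generation: int
    best: float
    mean: float
    best_cc: float
    best_vc: float


@dataclass
class GARunResult:
    """History and outcome of one GA run."""

    seed: int
    history: List[GenerationStats]
    best: Individual
    final_population: np.ndarray  # (N, 9) scalings
    final_errors: np.ndarray  # (N,) totals
    populations: Optional[List[np.ndarray]] = None  # per-generation (N, 9)
    population_errors: Optional[List[np.ndarray]] = None

    @property
    def best_errors(self) -> np.ndarray:
        return np.array([h.best for h in self.history])


@dataclass
class SimulationContext:
    """Everything needed to simulate a candidate against a target.

    The base state is the baseline-model steady-state snapshot; every
    candidate is pre-paced for 9 beats (current clamp) / held 5 s at -80 mV
    (voltage clamp) from this state before its response is scored, damping
    the transients introduced by the parameter change.
    """

    model: IonicModel
    base_state: ModelState
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    def simulate(self, scaling: ParameterScaling, target: ObjectiveTarget):
        v = i = None
        if target.voltage is not None:
            v = simulate_current_clamp(
                self.model, scaling, self.base_state, target.stimuli,
                settings=self.settings, prepace=True,
            )
        if target.current is not None:
            i = simulate_voltage_clamp(
                self.model, scaling, self.base_state, target.protocol,
                settings=self.settings,
            )
        return v, i

    def evaluate(self, scaling: ParameterScaling, target: ObjectiveTarget) -> ErrorValue:
        v, i = self.simulate(scaling, target)
        return error_combined(target, v, i)


# ---------------------------------------------------------------------------
# GA operators (array-based; one row per individual, canonical gene order)

def initialize_population(config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random scalings within bounds, shape (population, 9)."""
    lo, hi = config.lower(), config.upper()
    return rng.uniform(lo, hi, size=(config.population_size, N_PARAMETERS))


def evaluate_population(
    population: np.ndarray,
    target: ObjectiveTarget,
    context: SimulationContext,
    sentinel: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Evaluate each row; returns (totals, (cc, vc) components, sentinel).

    Evaluation is pure per individual, so order of evaluation cannot change
    the result.  A failed simulation receives a sentinel error (10x the worst
    finite error seen in the first evaluated generation) and the run
    continues.
    """
    n = population.shape[0]
    totals = np.empty(n)
    comps = np.empty((n, 2))
    failed = np.zeros(n, dtype=bool)
    for k in range(n):
        try:
            e = context.evaluate(ParameterScaling.from_array(population[k]), target)
            totals[k] = e.total
            comps[k] = (e.cc, e.vc)
            if not np.isfinite(totals[k]):
                failed[k] = True
        except SolverError as exc:
            logger.warning("individual %d failed: %s", k, exc)
            failed[k] = True
    finite = totals[~failed]
    if sentinel is None:
        worst = finite.max() if finite.size else 0.0
        sentinel = 10.0 * worst if worst > 0 else 1.0
    totals[failed] = sentinel
    comps[failed] = sentinel
    return totals, comps, sentinel


def next_generation(
    population: np.ndarray,
    totals: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> np.ndarray:
    """Tournament selection + two-point crossover + Gaussian mutation + elitism.

    The mutation width anneals geometrically with the generation index so the
    search transitions from global exploration to local refinement.
    """
    n, ng = population.shape
    lo, hi = config.lower(), config.upper()
    width = config.mutation_width * config.mutation_decay ** generation
    elite_idx = np.argsort(totals, kind="stable")[: config.elite_count]
    elites = population[elite_idx].copy()

    n_offspring = n - config.elite_count
    if n_offspring <= 0:
        return elites[:n]

    # tournament selection of parents
    draws = rng.integers(0, n, size=(n_offspring, config.tournament_size))
    parents = population[draws[np.arange(n_offspring), np.argmin(totals[draws], axis=1)]].copy()

    # crossover on consecutive pairs
    for a in range(0, n_offspring - 1, 2):
        if rng.random() < config.crossover_rate:
            if config.crossover_kind == "two_point":
                c1, c2 = sorted(rng.integers(0, ng + 1, size=2).tolist())
                if c1 != c2:
                    seg = parents[a, c1:c2].copy()
                    parents[a, c1:c2] = parents[a + 1, c1:c2]
                    parents[a + 1, c1:c2] = seg
            else:  # BLX-alpha: children drawn from the expanded parental span
                p1, p2 = parents[a], parents[a + 1]
                gmin = np.minimum(p1, p2)
                gmax = np.maximum(p1, p2)
                d = (gmax - gmin) * config.blend_alpha
                parents[a] = rng.uniform(gmin - d, gmax + d)
                parents[a + 1] = rng.uniform(gmin - d, gmax + d)

    # per-gene Gaussian mutation, clipped to bounds
    mutate = rng.random(parents.shape) < config.mutation_rate
    noise = rng.normal(0.0, width * (hi - lo), size=parents.shape)
    parents = np.clip(np.where(mutate, parents + noise, parents), lo, hi)

    return np.vstack([elites, parents])


def run_ga(
    config: GAConfig,
    target: ObjectiveTarget,
    context: SimulationContext,
    seed: Optional[int] = None,
    store_populations: bool = True,
) -> GARunResult:
    """Full GA loop; elitism guarantees a non-increasing best-error sequence."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    population = initialize_population(config, rng)
    totals, comps, sentinel = evaluate_population(population, target, context)
    history = []
    pops = [] if store_populations else None
    pop_errs = [] if store_populations else None

    def record(gen):
        b = int(np.argmin(totals))
        history.append(
            GenerationStats(gen, float(totals[b]), float(totals.mean()),
                            float(comps[b, 0]), float(comps[b, 1]))
        )
        if store_populations:
            pops.append(population.copy())
            pop_errs.append(totals.copy())

    record(0)
    for gen in range(1, config.generations + 1):
        population = next_generation(population, totals, config, rng, generation=gen - 1)
        totals, comps, _ = evaluate_population(
            population, target, context, sentinel=sentinel
        )
        record(gen)

    b = int(np.argmin(totals))
    best = Individual(
        ParameterScaling.from_array(population[b]),
        ErrorValue(cc=float(comps[b, 0]), vc=float(comps[b, 1])),
    )
    return GARunResult(
        seed=seed, history=history, best=best,
        final_population=population, final_errors=totals,
        populations=pops, population_errors=pop_errs,
    )


def run_ensemble(
    config: GAConfig,
    target: ObjectiveTarget,
    context: SimulationContext,
    store_populations: bool = False,
) -> List[GARunResult]:
    """n_runs independent GA runs with seeds seed+0 .. seed+n_runs-1."""
    return [
        run_ga(config, target, context, seed=config.seed + k,
               store_populations=store_populations)
        for k in range(config.n_runs)
    ]


def best_individuals(results: Sequence[GARunResult]) -> List[Individual]:
    return [r.best for r in results]


@dataclass
class RefinedBounds:
    bounds: Tuple[Tuple[float, float], ...]

    def as_config(self, config: GAConfig) -> GAConfig:
        return replace(config, bounds=self.bounds)


def refine_bounds(
    individuals: Sequence[Individual],
    parent: Optional[GAConfig] = None,
    epsilon: float = 0.01,
) -> RefinedBounds:
    """Per-parameter [min, max] span of an ensemble's best individuals.

    A zero-width span is widened by ±epsilon of the parent bound width (or of
    the default bounds when no parent config is given) so the second search
    stage remains non-degenerate; widened bounds are kept inside the parent's.
    """
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals to span refined bounds")
    mat = np.array([ind.scaling.as_array() for ind in individuals])
    lo = mat.min(axis=0)
    hi = mat.max(axis=0)
    plo = parent.lower() if parent else np.full(N_PARAMETERS, DEFAULT_BOUNDS[0])
    phi = parent.upper() if parent else np.full(N_PARAMETERS, DEFAULT_BOUNDS[1])
    width = phi - plo
    degenerate = hi - lo <= 0
    lo = np.where(degenerate, np.maximum(lo - epsilon * width, plo), lo)
    hi = np.where(degenerate, np.minimum(hi + epsilon * width, phi), hi)
    return RefinedBounds(tuple(zip(lo.tolist(), hi.tolist())))


def summarize_ensemble(individuals: Sequence[Individual]):
    """Per-parameter mean ± SD of the best individuals (reporting convention)."""
    mat = np.array([ind.scaling.as_array() for ind in individuals])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(N_PARAMETERS)
    return {
        name: (float(m), float(s))
        for name, m, s in zip(PARAMETER_NAMES, mean, sd)
    }
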