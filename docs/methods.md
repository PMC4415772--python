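# Methods

## Problem and approach

A ventricular cardiomyocyte's electrical phenotype is largely set by the
densities of its membrane currents and calcium transporters. `cardiofit`
estimates nine such density parameters for a single cell — dimensionless
scalings of the maximal conductances of I_Na, I_CaL, I_CaT, I_K1, I_Kr,
I_Ks, I_Kp, I_pCa and of the maximal SERCA uptake flux J_SERCA — by fitting
a whole-cell ionic model to two dynamically rich recordings from that cell:

1. a **stochastic current-clamp sequence**: 5 s of 1 ms / −40 A/F square
   pulses whose inter-stimulus intervals are uniform on 100–700 ms, which
   rapidly samples the rate- and history-dependence of the action potential;
2. a **multi-step voltage clamp**: a 6000 ms sequence of 11 holding
   potentials, each chosen to make one current dominate the total membrane
   current (−120 mV → I_K1; +20 mV → I_CaL; +40/−30 mV pairs → I_Ks),
   preceded by 5 s at −80 mV so the model settles after parameter changes.

The fit minimizes a sum-of-squares objective with a genetic algorithm (GA).
Kinetics are held at their published values; only the nine multiplicative
densities move. The package validates the whole procedure in silico
(generate a target from known truth scalings, check they are recovered) and
provides the identifiability diagnostics that explain which parameters a
given protocol constrains.

## Objective functions

For current-clamp data the error is

    E1 = Σ_t (V_target(t) − V_candidate(t))²

summed over the full protocol span on a 0.1 ms grid, in mV². For the
combined objective the voltage-clamp term is added unweighted:

    E2 = E1 + Σ_t (I_target(t) − I_candidate(t))²

with currents in A/F. The two terms have different units; they are summed
into a single dimensionless error rather than treated as competing
objectives, because both are minimal over the same parameter region. A
weight hook exists (`error_combined(..., cc_weight, vc_weight)`) but
defaults to 1. The sums are plain sums, not means, over mask-included
samples.

Exclusion masks remove measurement artifacts deterministically from
protocol metadata, never by detection: a 1.3 ms window after each stimulus
onset (stimulus artifact; 13 samples at 0.1 ms) and a 1.2 ms window after
each commanded-potential change (capacitance transient; 12 samples). The
voltage-clamp protocol start counts as a potential change, so 11 windows
are masked in the 11-step protocol. Candidate traces are linearly
interpolated onto the target's sample grid before differencing; unit
mismatches are errors, never silent conversions.

## Models

Both models fix the ionic milieu to the experimental solutions — K+_o 5.4,
Ca2+_o 2.0, Na+_o 139.4, Na+_i 10, K+_i 136 mmol/l, 35 °C — and hold
Na+_i/K+_i constant (pipette-dialysed); only the calcium pools evolve.
Both expose the same contract (named state vector, current-clamp and
voltage-clamp runners, per-current decomposition), so every operation in
the package is model-agnostic.

**Flagship** (`faber-rudy`): a 14-state guinea-pig ventricular model in the
Faber–Rudy / dynamic-Luo–Rudy lineage: LR91 I_Na (m³hj), GHK-driven I_CaL
with calcium-dependent inactivation plus its K+/Na+ permeation components,
I_CaT, I_Kr, two-gate Ca2+-sensitive I_Ks, I_K1, I_Kp, Na/Ca exchange, Na/K
pump, sarcolemmal Ca2+ pump, background Ca2+/Na+ currents, and a two-pool
sarcoplasmic reticulum (junctional release + network uptake pools,
calsequestrin buffering) with a simplified Ca-induced-Ca-release flux gated
by the L-type channel's gates. Release kinetics are a deliberate
simplification; the behaviours this package relies on — action-potential
morphology under stochastic pacing and per-step current isolation under the
clamp — are insensitive to the release formulation, and the model
reproduces the designed isolation pattern (I_K1 ≈ 92 % of the total at
−120 mV; I_CaL and I_Ks dominant at their steps).

**Reduced** (`reduced`): a 10-state guinea-pig-like model with the same
nine scalable currents/fluxes, built for the in-silico recovery studies
where thousands of 20-second evaluations are needed. Simplifications:
merged Na+ inactivation (single h gate), single activation gates for
I_Kr/I_Ks, linear driving force for Ca2+ currents, one SR pool. Two design
constraints mattered:

* **Robust excitability under the printed sequences.** The optimization
  sequence contains inter-stimulus gaps down to 141 ms. If the model's
  refractory period is comparable, the synthetic cell sits on an
  all-or-none firing boundary and the objective acquires error cliffs of
  ~10⁶ mV² within ±5 % of the truth parameters, which defeats any
  optimizer and misrepresents the intended study (in the full guinea-pig
  model all 11 stimuli elicit action potentials). The reduced model
  therefore has fast Na+ recovery and APD90 ≈ 95 ms at a 500 ms cycle
  length, giving every printed coupling a comfortable margin; the
  objective landscape around truth is then smooth and near-quadratic.
* **Informative voltage-clamp steps.** The reduced model preserves the
  protocol's isolation logic (I_K1 ≈ 92 % at −120 mV, I_CaL largest at
  +20 mV, I_Ks largest at +40 mV).

Because targets and candidates are integrated identically, the reduced
model is its own ground truth: a candidate at the truth scalings reproduces
a noise-free target exactly, and recovery error measures the optimizer and
protocol information content, not integrator artifacts.

## Numerical integration

Fixed-step integration with Rush–Larsen exponential updates for the gating
variables (their voltage-dependent steady states and per-step decay factors
are pre-tabulated on a 0.05 mV grid over −160…90 mV and linearly
interpolated) and forward Euler for membrane potential and calcium pools.
Native steps: 0.01 ms (flagship), 0.05 ms (reduced); output grid 0.1 ms.
This choice favours throughput inside the GA loop — a full combined-objective
evaluation of the reduced model (9 pre-pacing beats + 5 s sequence + 5 s
hold + 6 s clamp) costs ≈ 20 ms — over the adaptive stiff solvers usual for
single simulations.

Accuracy is verified two ways in the test suite: against scipy's adaptive
LSODA on the same equations (max |ΔV| < 0.5 mV over a stimulated 100 ms
segment at a 0.001 ms step; convergence is first order in the step, as
expected for the Euler voltage update), and by step halving on the clamp
protocol (max |ΔI| < 0.1 A/F away from step transitions at the native
step). The voltage clamp is ideal: the command potential is substituted
instantaneously, with no series-resistance or capacitance model — matching
the treatment of the data, where capacitance transients are masked rather
than modelled.

Determinism is a contract: identical inputs give bit-identical traces, and
a whole fit ensemble is bit-reproducible from (config, seed).

## Steady state and pre-pacing

The baseline model is paced to steady state (1800 beats at a 500 ms cycle
length, 1 ms / −40 A/F pulses) and the snapshot cached per (model, scaling,
settings). Inside the GA every candidate starts from the *baseline*
snapshot and is pre-paced 9 beats at 500 ms (current clamp) or held 5 s at
−80 mV (voltage clamp) before its response is scored, damping the
transients introduced by the parameter change. Synthetic targets are
generated through this same pipeline, which is what makes the truth
scalings an exact zero of the objective.

## Genetic algorithm

Real-coded GA on the nine-gene scaling vector, linear encoding, initialized
uniformly within per-parameter bounds of 0.0001–2.99 (0.01–299 % of
baseline). Production-scale defaults: population 500, 100 generations, 10
independent runs per problem. Operators (all exposed in `GAConfig`):

* tournament selection, size 2;
* blend (BLX-α) crossover, rate 0.9, α = 0.3 — children drawn uniformly
  from the parental interval expanded by α on each side, clipped to bounds.
  Two-point gene swap is available (`crossover_kind="two_point"`) but is
  not the default: gene swapping never creates new gene values, and at
  small budgets it stalled an order of magnitude short in error;
* per-gene Gaussian mutation, rate 1/9, SD 10 % of the bound width,
  annealed geometrically (×0.95 per generation) so the search moves from
  global exploration to local refinement, clipped to bounds;
* elitism of 5 individuals (1 % of the production population), which
  measurably deepens convergence at small budgets without visible
  premature-convergence cost.

A candidate whose simulation fails (non-finite state) receives a sentinel
error of 10× the worst finite error of the first generation (or 1 if that
is zero) and the run continues. Per-individual evaluation is pure, so any
evaluation order gives identical results to serial execution.

**Iterative refinement**: the per-parameter [min, max] span of the first
ensemble's best individuals becomes the bounds for a second ensemble with
fresh seeds (seed+0 … seed+n−1 within each ensemble). A zero-width span is
widened by ±1 % of the parent bound width. This only helps when the first
ensemble spans the true solution, which is why it is applied after the
combined objective.

## In-silico validation at desk scale

The recovery study is run at a reduced scale chosen to keep the full
validation within minutes on one core: population 50, 30 generations, 3
runs per objective, reduced model, noise-free target at truth = 1. At this
scale the qualitative findings replicate robustly across seeds: the
combined stochastic-pacing + voltage-clamp objective recovers parameters
with smaller median absolute error than stochastic pacing alone; prediction
error on a novel 13-stimulus sequence orders combined < stochastic-only <
single action potential; and iterative refinement shrinks every
per-parameter SD while further lowering prediction error by roughly an
order of magnitude.

One caveat is intrinsic to the downscaled design: the "truth within
mean ± SD for ≥ 8 of 9 parameters" summary is statistically fragile with
only 3 runs. Even for an unbiased estimator whose per-run deviations are
symmetric, the probability that |mean| ≤ SD for a given parameter is
P(|t₂| < √3) ≈ 0.78, so the 8-of-9 event holds only ~40 % of the time at
n = 3 (at the production scale of 10 runs the same check is ≈ 99 %
reliable). Measured containment counts vary between 4/9 and 8/9 with the
seed. The optimizer was tuned for accuracy (median |mean − truth| of
0.05–0.25 at desk scale), not for inflating SDs, which would game this
summary while degrading the estimates.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions: printed stimulus times and
clamp steps, 9-beat pre-pacing, 5 s pre-hold, 0.1 ms sampling, standard
artifact masks, and optional additive i.i.d. Gaussian noise on either trace
(the validation default is noise-free, and a 1 mV noise SD raises the
objective at truth by exactly N_included·σ² in expectation, which is tested).
It does **not** emulate: correlated or 1/f recording noise, series-resistance
and imperfect capacitance compensation, current rundown over the protocol,
liquid-junction drift, or kinetic (as opposed to density) differences
between cell and model. Passing recovery tests therefore demonstrate that
the protocol + objective + optimizer pipeline identifies density parameters
when the model family is correct; they do not bound the error induced by
model-form mismatch on real cells.

## Experimental-data path

Recorded traces travel as two-column delimited text (`time_ms,<unit>`
header) at full printed precision; arbitrary monotone time grids are
accepted. Voltage-clamp sessions recorded in triplicate are reduced to one
trace by the shortest-time-to-peak-I_Na rule in the −40 mV step at 600 ms
(most-negative current in the step window; ties to the earliest trial). A
−3 mV liquid-junction correction is applied to command potentials for
experimental sessions only (flag-controlled); the Donnan offset is treated
as zero. Masks come from protocol metadata with the same windows as in
simulation.

## Diagnostics

* **Local sensitivity**: one parameter at a time scaled to 80–120 % of
  truth (levels 0.8, 0.9, 0.95, 1.05, 1.1, 1.2), objective recomputed
  against the baseline target, per protocol variant. The calcium variant
  substitutes the intracellular Ca2+ concentration for V/I in the same
  sums; in the reduced model it ranks the calcium-handling parameters
  (I_CaL, J_SERCA, I_pCa) at the top, as expected for a fluorescence
  objective.
* **Multi-parameter sensitivity** (documented variant; the original's
  details are not public): joint uniform perturbation of all parameters
  within ±20 %, then OLS of log₁₀(error) on the standardized absolute
  deviations |s − truth| (the error is V-shaped around truth, so raw
  scalings carry no linear signal); standardized coefficients are the
  effect sizes, significance at 0.05.
* **Progression**: squared coefficient of variation of each parameter
  across the population per generation, averaged over runs; slowly
  converging parameters are weakly determined. Uniform initial populations
  match the closed-form CV² = ((b−a)²/12)/((a+b)/2)².
* **Correlations**: Pearson correlations with significance flags over the
  pooled best 5 % of final-population individuals (documented choice);
  negative entries mark compensatory pairs.
* **Recovery report**: per-parameter mean ± SD, truth-containment flags,
  per-individual prediction errors, and unpaired two-sample t-tests (0.05)
  between objectives' prediction errors. Unpaired is a documented choice;
  the source of the convention does not state pairing.

## Known limitations

* Kinetic parameters are fixed; only densities are estimated.
* The flagship's CICR formulation is simplified (see above); quantities
  that depend on release timing details should not be read quantitatively
  from it.
* First-order integrator accuracy at the voltage upstroke; the 0.1 ms
  output grid and masking make this irrelevant to the objective, but peak
  dV/dt values carry ~1 % step dependence.
* The desk-scale containment statistic is noisy by design (see above).
* No GPU or multi-process execution; the evaluation contract is
  parallel-safe but the shipped loop is serial.
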