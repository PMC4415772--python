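# cardiofit

Cell-specific parameterization of cardiac ventricular ionic models by
genetic-algorithm fitting to dynamically rich electrophysiology protocols.

## The problem

Composite cardiac myocyte models are traditionally assembled from data
averaged over many cells and labs, then hand-tuned until a single simulated
action potential looks right. Such models routinely fail on dynamics they
were not tuned to — irregular pacing, drug block, arrhythmia — and no single
cell behaves like the average model. Under the assumption that ion-channel
*kinetics* are conserved while channel *densities* vary from cell to cell,
one can instead record a short but information-dense protocol from a single
myocyte and estimate that cell's densities directly.

`cardiofit` implements this workflow for guinea-pig ventricular myocytes.
Nine dimensionless scalings **s** = (s_Na, s_CaL, s_CaT, s_K1, s_Kr, s_Ks,
s_Kp, s_pCa, s_SERCA) multiply the baseline maximal conductances of I_Na,
I_CaL, I_CaT, I_K1, I_Kr, I_Ks, I_Kp, I_pCa and the maximal SERCA flux
J_SERCA. They are estimated by minimizing

    E2(s) = Σ_t [V_target(t) − V_model(t; s)]²  +  Σ_t [I_target(t) − I_model(t; s)]²

where V is the voltage response to a 5 s stochastic stimulation sequence
(11 stimuli, 1 ms / −40 A/F, inter-stimulus intervals uniform on
100–700 ms) and I is the total membrane current under a 6 s multi-step
voltage clamp whose holding potentials each emphasize one current
(−120 mV → I_K1, +20 mV → I_CaL, +40/−30 mV → I_Ks). A 1.3 ms window after
each stimulus and a 1.2 ms window after each potential step are excluded
(stimulus artifact / capacitance transient). The minimization uses a
real-coded genetic algorithm (population 500, 100 generations, bounds
0.01–299 % of baseline, 10 independent runs; optionally a second, local,
set of runs bounded by the span of the first — "iterative refinement").

The package contains:

* two ionic models behind one contract — a Faber–Rudy-lineage guinea-pig
  ventricular model (flagship) and a fast reduced model for validation
  studies — with numba-compiled fixed-step Rush–Larsen integration;
* the printed stimulation/clamp protocols, a seeded stochastic-sequence
  generator, and per-step current-contribution tables;
* the objective functions with artifact masks, the GA with ensembles and
  iterative refinement, and a synthetic-target generator for in-silico
  parameter-recovery validation;
* identifiability diagnostics: local and joint sensitivity, GA convergence
  progression, parameter correlations, recovery reports with t-tests;
* readers/writers for recorded traces (plain-text), triplicate trial
  selection, liquid-junction correction, and a `cardiofit` CLI.

## Worked example

Fit a synthetic cell (truth scalings = 1) with the combined objective at
the desk scale used by the in-silico validation, then score the fits on a
novel stimulation sequence:

```bash
cardiofit fit --target synthetic --objective combined --model reduced \
              --pop 50 --gens 30 --runs 3 --seed 1 --outdir fit_out
cardiofit predict --model reduced --fit-dir fit_out
```

which prints (3 runs, ~2 minutes on one core):

```
3 runs -> fit_out
  s_Na     0.956 +/- 0.029
  s_CaL    1.502 +/- 0.651
  s_CaT    1.097 +/- 0.223
  s_K1     0.953 +/- 0.035
  s_Kr     1.269 +/- 0.364
  s_Ks     1.125 +/- 0.079
  s_Kp     1.389 +/- 0.509
  s_pCa    1.030 +/- 0.057
  s_SERCA  0.908 +/- 0.159
run 0: prediction error 6653.05
run 1: prediction error 11690.2
run 2: prediction error 61654.8
mean 26666 +/- 30405.6
```

Each line is one parameter's ensemble mean ± SD across the three runs'
best individuals; at this small budget the truth (1.0) lies within one SD
for six of the nine parameters, and the widest spreads sit on I_CaL and
the plateau current I_Kp — exactly the compensatory pair the correlation
and sensitivity diagnostics flag as hardest. Prediction errors are E1
values on a 13-stimulus sequence the fits never saw; iterative refinement
(`--iterative`) lowers them by a further factor of ~4.

Inspect a protocol or the current-isolation table:

```bash
cardiofit protocol show multistep
cardiofit sensitivity --model reduced --variant combined
```

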