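"""Trace file I/O, experimental post-processing, and synthetic fitting targets.

Recorded traces travel as two-column delimited text (``time_ms,<unit>``
header; one sample per row) — diffable, lossless at full printed precision.
Experimental sessions record the multi-step voltage-clamp response in
triplicate; the trial with the shortest time to peak Na+ current during the
step to -40 mV (600 ms into the protocol) is selected for fitting.

Synthetic targets drive the in-silico validation: the simulator generates
the voltage response to the fixed stochastic sequence and the current
response to the multi-step clamp at known "truth" scalings, attaches the
standard artifact masks, and (optionally) adds i.i.d. Gaussian noise.
Targets are generated through the identical pipeline used to evaluate GA
candidates (baseline steady-state snapshot, 9-beat pre-pace, 5 s pre-hold),
so a candidate at the truth scalings reproduces a noise-free target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .models.base import IonicModel, ModelState, SimulationSettings
from .objective import (
    ObjectiveTarget,
    mask_capacitance_transients,
    mask_stimulus_artifacts,
)
from .parameters import ParameterScaling
from .protocols import (
    StimulusSequence,
    VoltageClampProtocol,
    multistep_protocol,
    optimization_sequence,
)
from .simulation import (
    pace_to_steady_state,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from .trace import Trace, VALID_UNITS

#: Single-action-potential objective: one beat, 500 ms window.
SINGLE_AP_SEQUENCE = StimulusSequence((5.0,), duration=500.0)

#: Window of the I_Na-eliciting step (-40 mV at 600 ms) used for trial selection.
INA_STEP_START = 600.0
INA_STEP_DURATION = 25.0


@dataclass
class RecordedTrace:
    """A measured (or simulated-as-measured) trace plus acquisition metadata."""

    trace: Trace
    cell_id: str = ""
    mode: str = ""  # "current-clamp" | "voltage-clamp"
    protocol_ref: str = ""

    @property
    def times(self):
        return self.trace.times

    @property
    def values(self):
        return self.trace.values

    @property
    def unit(self):
        return self.trace.unit


class TraceParseError(ValueError):
    pass


def write_trace(rec, path) -> None:
    """Write a trace as two-column delimited text with a unit header."""
    trace = rec.trace if isinstance(rec, RecordedTrace) else rec
    path = Path(path)
    lines = []
    if isinstance(rec, RecordedTrace):
        for key, val in (("cell_id", rec.cell_id), ("mode", rec.mode),
                         ("protocol", rec.protocol_ref)):
            if val:
                lines.append(f"# {key}: {val}")
    lines.append(f"time_ms,{trace.unit}")
    lines.extend(
        f"{float(t)!r},{float(v)!r}" for t, v in zip(trace.times, trace.values)
    )
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> RecordedTrace:
    """Read a two-column trace file; validates header, monotone time, row shape."""
    path = Path(path)
    meta = {}
    header = None
    times, values = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                cols = [c.strip() for c in line.split(",")]
                if len(cols) != 2 or cols[0] != "time_ms":
                    raise TraceParseError(
                        f"{path}:{lineno}: expected header 'time_ms,<unit>', got {line!r}"
                    )
                if cols[1] not in VALID_UNITS:
                    raise TraceParseError(
                        f"{path}:{lineno}: unknown unit {cols[1]!r} in header"
                    )
                header = cols
                continue
            cols = line.split(",")
            if len(cols) != 2:
                raise TraceParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            try:
                t, v = float(cols[0]), float(cols[1])
            except ValueError:
                raise TraceParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            if times and t <= times[-1]:
                raise TraceParseError(
                    f"{path}:{lineno}: time {t} not strictly increasing"
                )
            times.append(t)
            values.append(v)
    if header is None:
        raise TraceParseError(f"{path}: missing 'time_ms,<unit>' header")
    trace = Trace(np.array(times), np.array(values), header[1])
    return RecordedTrace(
        trace,
        cell_id=meta.get("cell_id", ""),
        mode=meta.get("mode", ""),
        protocol_ref=meta.get("protocol", ""),
    )


# ---------------------------------------------------------------------------
# Trial selection

@dataclass
class TrialSet:
    """Three current responses to the same voltage-clamp protocol."""

    trials: Tuple[RecordedTrace, RecordedTrace, RecordedTrace]

    def __post_init__(self):
        if len(self.trials) != 3:
            raise ValueError("a trial set holds exactly three traces")
        refs = {t.protocol_ref for t in self.trials}
        if len(refs) > 1:
            raise ValueError(f"trials reference different protocols: {refs}")


def select_best_trial(
    trials: TrialSet,
    step_start: float = INA_STEP_START,
    step_duration: float = INA_STEP_DURATION,
) -> RecordedTrace:
    """Pick the trial with the shortest time to peak inward Na+ current.

    The peak is the most-negative current within the -40 mV step window;
    ties are broken in favour of the earliest trial.
    """
    times_to_peak = []
    for k, rec in enumerate(trials.trials):
        t = rec.times
        sel = (t >= step_start) & (t < step_start + step_duration)
        if not sel.any():
            raise ValueError(
                f"trial {k}: no samples inside the step window "
                f"[{step_start}, {step_start + step_duration}) ms"
            )
        w_t = t[sel]
        w_v = rec.values[sel]
        times_to_peak.append(w_t[int(np.argmin(w_v))] - step_start)
    return trials.trials[int(np.argmin(times_to_peak))]


# ---------------------------------------------------------------------------
# Synthetic targets

@dataclass
class SyntheticTarget:
    """Simulated fitting target with known truth scalings."""

    truth: ParameterScaling
    target: ObjectiveTarget
    noise_sd: Tuple[float, float]  # (mV, A/F)
    seed: int
    base_state: ModelState


def generate_synthetic_target(
    model: IonicModel,
    truth: ParameterScaling = ParameterScaling(),
    noise_sd: Tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    settings: SimulationSettings = SimulationSettings(),
    stimuli: Optional[StimulusSequence] = None,
    protocol: Optional[VoltageClampProtocol] = None,
    include_voltage: bool = True,
    include_current: bool = True,
    steady_state_beats: Optional[int] = None,
) -> SyntheticTarget:
    """Simulate target traces at the truth scalings and attach standard masks.

    The baseline model is paced to steady state; from that snapshot the truth
    model is pre-paced 9 beats and driven by the stochastic sequence (voltage
    target) and held 5 s at -80 mV before the multi-step protocol (current
    target).  Gaussian noise with the given SDs is added when requested; the
    in-silico validation default is noise-free.
    """
    if noise_sd[0] < 0 or noise_sd[1] < 0:
        raise ValueError("noise SDs must be >= 0")
    if stimuli is None:
        stimuli = optimization_sequence()
    if protocol is None:
        protocol = multistep_protocol()
    kwargs = {} if steady_state_beats is None else {"n_beats": steady_state_beats}
    base = pace_to_steady_state(model, ParameterScaling(), settings=settings, **kwargs)
    rng = np.random.default_rng(seed)
    voltage = current = None
    if include_voltage:
        v = simulate_current_clamp(
            model, truth, base, stimuli, settings=settings, prepace=True
        )
        if noise_sd[0] > 0:
            v = Trace(v.times, v.values + rng.normal(0, noise_sd[0], v.values.shape), "mV")
        voltage = mask_stimulus_artifacts(v, stimuli)
    if include_current:
        i = simulate_voltage_clamp(model, truth, base, protocol, settings=settings)
        if noise_sd[1] > 0:
            i = Trace(i.times, i.values + rng.normal(0, noise_sd[1], i.values.shape), "A/F")
        current = mask_capacitance_transients(i, protocol)
    target = ObjectiveTarget(
        voltage=voltage, current=current, stimuli=stimuli, protocol=protocol
    )
    return SyntheticTarget(truth, target, tuple(noise_sd), seed, base)


def make_objective_target(
    synth: SyntheticTarget, variant: str
) -> ObjectiveTarget:
    """Restrict a synthetic target to one objective variant.

    Variants: 'single_ap' (one paced beat), 'stochastic' (voltage only),
    'vclamp' (current only), 'combined' (both).
    """
    t = synth.target
    if variant == "combined":
        if t.voltage is None or t.current is None:
            raise ValueError("combined variant needs both traces")
        return t
    if variant == "stochastic":
        if t.voltage is None:
            raise ValueError("no voltage trace in target")
        return ObjectiveTarget(voltage=t.voltage, stimuli=t.stimuli)
    if variant == "vclamp":
        if t.current is None:
            raise ValueError("no current trace in target")
        return ObjectiveTarget(current=t.current, protocol=t.protocol)
    raise ValueError(f"unknown variant {variant!r}")


def generate_single_ap_target(
    model: IonicModel,
    truth: ParameterScaling = ParameterScaling(),
    settings: SimulationSettings = SimulationSettings(),
    steady_state_beats: Optional[int] = None,
) -> SyntheticTarget:
    """Single-action-potential objective (one paced beat, 500 ms window)."""
    return generate_synthetic_target(
        model, truth, seed=0, settings=settings, stimuli=SINGLE_AP_SEQUENCE,
        include_current=False, steady_state_beats=steady_state_beats,
    )


# ---------------------------------------------------------------------------
# Model-state snapshots (self-describing key-value text)

def save_state(state: ModelState, path) -> None:
    lines = [f"# model: {state.model_name}"]
    lines += [f"{n} {float(v)!r}" for n, v in zip(state.names, state.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_state(path, model: IonicModel) -> ModelState:
    names, values = [], []
    model_name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "model:" in line:
                model_name = line.split("model:")[1].strip()
            continue
        n, v = line.split()
        names.append(n)
        values.append(float(v))
    if model_name != model.name:
        raise ValueError(f"snapshot is for model {model_name!r}, not {model.name!r}")
    if tuple(names) != model.state_names:
        raise ValueError("snapshot state names do not match the model")
    return model.make_state(np.array(values))
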