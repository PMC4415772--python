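"""High-level simulation operations.

Wraps the model runner kernels in protocol-aware operations: steady-state
pacing (with snapshot caching), current-clamp runs with the 9-beat pre-pacing
rule applied after every parameter change, voltage-clamp runs with the 5 s
pre-hold, and per-current decomposition.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .models.base import IonicModel, ModelState, SimulationSettings
from .parameters import ParameterScaling
from .protocols import (
    STIM_AMPLITUDE,
    STIM_WIDTH,
    StimulusSequence,
    VoltageClampProtocol,
)
from .trace import Trace

#: Pacing used to equilibrate the model and to damp transients inside the GA.
PACING_CYCLE_LENGTH = 500.0  # ms
STEADY_STATE_BEATS = 1800
PREPACE_BEATS = 9

_STEADY_STATE_CACHE: dict = {}


def clear_steady_state_cache():
    _STEADY_STATE_CACHE.clear()


def pace_to_steady_state(
    model: IonicModel,
    scaling: ParameterScaling = ParameterScaling(),
    cycle_length: float = PACING_CYCLE_LENGTH,
    n_beats: int = STEADY_STATE_BEATS,
    settings: SimulationSettings = SimulationSettings(),
    initial: Optional[ModelState] = None,
) -> ModelState:
    """Pace from rest to a period-1 steady state; snapshots are cached.

    Default: 1800 beats at a 500 ms cycle length with 1 ms, -40 A/F square
    pulses.  The returned state is the state at the end of beat ``n_beats``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if cycle_length <= STIM_WIDTH:
        raise ValueError("cycle length must exceed the stimulus pulse width")
    key = (
        model.name, scaling.key(), float(cycle_length), int(n_beats),
        settings.key(), None if initial is None else initial.values.tobytes(),
    )
    cached = _STEADY_STATE_CACHE.get(key)
    if cached is not None:
        return cached.copy()
    dt = settings.resolve_dt(model)
    state0 = model.initial_state() if initial is None else initial
    model.check_state(state0)
    onsets = cycle_length * np.arange(n_beats)
    duration = cycle_length * n_beats
    _, _, _, final = model.run_current_clamp(
        scaling.as_array(), state0.values, onsets, STIM_AMPLITUDE, STIM_WIDTH,
        duration, record_start=duration, dt=dt, out_dt=settings.out_dt,
    )
    model._check_finite(final, duration)
    result = model.make_state(final)
    _STEADY_STATE_CACHE[key] = result.copy()
    return result


def simulate_current_clamp(
    model: IonicModel,
    scaling: ParameterScaling,
    initial: ModelState,
    stimuli: StimulusSequence,
    duration: Optional[float] = None,
    settings: SimulationSettings = SimulationSettings(),
    prepace: bool = True,
    record_ca: bool = False,
) -> Trace:
    """Simulate the voltage response to a stimulus sequence.

    With ``prepace`` (the default inside the GA), 9 beats at a 500 ms interval
    are simulated first to damp transients and excluded from the returned
    trace; trace time zero is the start of the sequence proper.
    """
    model.check_state(initial)
    if duration is None:
        duration = stimuli.duration
    onsets = stimuli.onset_array()
    if onsets.size and (onsets.min() < 0 or onsets.max() >= duration):
        raise ValueError("stimulus onsets must lie in [0, duration)")
    dt = settings.resolve_dt(model)
    offset = PREPACE_BEATS * PACING_CYCLE_LENGTH if prepace else 0.0
    if prepace:
        pre = PACING_CYCLE_LENGTH * np.arange(PREPACE_BEATS)
        onsets = np.concatenate([pre, onsets + offset])
    t, v, ca, final = model.run_current_clamp(
        scaling.as_array(), initial.values, onsets, stimuli.amplitude,
        stimuli.width, duration + offset, record_start=offset, dt=dt,
        out_dt=settings.out_dt, record_ca=record_ca,
    )
    model._check_finite(final, duration + offset)
    trace = Trace(t, v, "mV")
    if record_ca:
        return trace, Trace(t, ca, "mM")
    return trace


def simulate_voltage_clamp(
    model: IonicModel,
    scaling: ParameterScaling,
    initial: ModelState,
    protocol: VoltageClampProtocol,
    settings: SimulationSettings = SimulationSettings(),
    record_ca: bool = False,
) -> Trace:
    """Simulate total membrane current under an ideal voltage clamp.

    The command potential is substituted instantaneously (the membrane
    equation is removed).  The pre-hold, if the protocol defines one, is
    simulated but excluded from the returned trace.
    """
    model.check_state(initial)
    dt = settings.resolve_dt(model)
    ph_dur, ph_v = (0.0, 0.0) if protocol.prehold is None else protocol.prehold
    t, itot, _, ca, final = model.run_voltage_clamp(
        scaling.as_array(), initial.values, protocol.durations(),
        protocol.potentials(), ph_dur, ph_v, dt=dt, out_dt=settings.out_dt,
        record_ca=record_ca,
    )
    model._check_finite(final, ph_dur + protocol.total_duration)
    trace = Trace(t, itot, "A/F")
    if record_ca:
        return trace, Trace(t, ca, "mM")
    return trace


def decompose_currents(
    model: IonicModel,
    scaling: ParameterScaling,
    initial: ModelState,
    protocol: VoltageClampProtocol,
    settings: SimulationSettings = SimulationSettings(),
) -> Dict[str, Trace]:
    """Per-current traces under voltage clamp (same grid as the total trace).

    The sum of the returned traces equals the total-current trace.
    """
    model.check_state(initial)
    dt = settings.resolve_dt(model)
    ph_dur, ph_v = (0.0, 0.0) if protocol.prehold is None else protocol.prehold
    t, itot, cur, _, final = model.run_voltage_clamp(
        scaling.as_array(), initial.values, protocol.durations(),
        protocol.potentials(), ph_dur, ph_v, dt=dt, out_dt=settings.out_dt,
        record_currents=True,
    )
    model._check_finite(final, ph_dur + protocol.total_duration)
    return {
        name: Trace(t, cur[i], "A/F")
        for i, name in enumerate(model.current_names)
    }
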