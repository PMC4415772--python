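"""Sum-of-squared-error objectives with artifact exclusion masks.

The current-clamp objective is the sum over included samples of the squared
voltage difference between target and candidate.  The combined objective adds
the analogous voltage-clamp current term; the two components, although of
different physical units, are summed unweighted into a single dimensionless
error (they are expected to be minimal over the same parameter range rather
than competitive).

Masks remove (a) a window after each stimulus onset (stimulus artifact,
default 1.3 ms) and (b) a window after each commanded-potential change
(capacitance transient, default 1.2 ms).  The protocol start counts as a
potential change.  Errors are sums, not means, over included samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .protocols import StimulusSequence, VoltageClampProtocol
from .trace import Trace

STIMULUS_MASK_WINDOW = 1.3  # ms excluded after each stimulus onset
CAPACITANCE_MASK_WINDOW = 1.2  # ms excluded after each potential change

#: Numerical slack (ms) for assigning samples to half-open mask windows.
_BOUNDARY_TOL = 1e-6


@dataclass
class ErrorValue:
    """Total objective error and its current-clamp / voltage-clamp components."""

    cc: float = 0.0
    vc: float = 0.0

    @property
    def total(self) -> float:
        return self.cc + self.vc

    def __repr__(self):
        return f"ErrorValue(total={self.total:.6g}, cc={self.cc:.6g}, vc={self.vc:.6g})"


@dataclass
class ObjectiveTarget:
    """Fitting target: voltage trace (current clamp) and/or current trace (voltage clamp).

    The associated stimulation sequence / clamp protocol travel with the
    traces so candidates can be simulated under identical drive.
    """

    voltage: Optional[Trace] = None  # mV, stochastic-pacing or single-AP response
    current: Optional[Trace] = None  # A/F, multi-step clamp response
    stimuli: Optional[StimulusSequence] = None
    protocol: Optional[VoltageClampProtocol] = None

    def __post_init__(self):
        if self.voltage is None and self.current is None:
            raise ValueError("objective target must contain at least one trace")
        if self.voltage is not None and self.voltage.unit != "mV":
            raise ValueError("current-clamp target must be in mV")
        if self.current is not None and self.current.unit != "A/F":
            raise ValueError("voltage-clamp target must be in A/F")


def _mask_windows(trace: Trace, starts: np.ndarray, window: float) -> Trace:
    if window <= 0:
        raise ValueError("mask window must be positive")
    mask = trace.mask.copy()
    for s in np.atleast_1d(starts):
        rel = trace.times - s
        mask &= ~((rel >= -_BOUNDARY_TOL) & (rel < window - _BOUNDARY_TOL))
    return trace.with_mask(mask)


def mask_stimulus_artifacts(
    trace: Trace, stimuli: StimulusSequence, window: float = STIMULUS_MASK_WINDOW
) -> Trace:
    """Exclude samples in [onset, onset+window) for every stimulus (idempotent)."""
    return _mask_windows(trace, stimuli.onset_array(), window)


def mask_capacitance_transients(
    trace: Trace,
    protocol: VoltageClampProtocol,
    window: float = CAPACITANCE_MASK_WINDOW,
) -> Trace:
    """Exclude samples in a window after every potential change, incl. protocol start."""
    return _mask_windows(trace, protocol.transition_times(), window)


def _sum_sq(target: Trace, candidate: Trace, unit: str) -> float:
    if target.unit != unit:
        raise ValueError(f"target unit {target.unit!r}; expected {unit!r}")
    if candidate.unit != unit:
        raise ValueError(f"candidate unit {candidate.unit!r}; expected {unit!r}")
    if candidate.times.shape == target.times.shape and np.array_equal(
        candidate.times, target.times
    ):
        cand = candidate.values
    else:
        cand = np.interp(target.times, candidate.times, candidate.values)
    m = target.mask
    if not m.any():
        raise ValueError("no included samples under the target mask")
    d = target.values[m] - cand[m]
    return float(np.dot(d, d))


def error_current_clamp(target: Trace, candidate: Trace) -> ErrorValue:
    """Sum of squared voltage differences (mV^2) over mask-included samples.

    The candidate is linearly interpolated onto the target's sample times if
    the grids differ.
    """
    return ErrorValue(cc=_sum_sq(target, candidate, "mV"))


def error_voltage_clamp(target: Trace, candidate: Trace) -> ErrorValue:
    """Sum of squared current differences ((A/F)^2) over mask-included samples."""
    return ErrorValue(vc=_sum_sq(target, candidate, "A/F"))


def prediction_error(
    model,
    scaling,
    novel: StimulusSequence,
    target: Trace,
    base_state,
    settings=None,
) -> ErrorValue:
    """Score a fitted model against a stimulation sequence it was not fit to.

    Simulates the voltage response to ``novel`` (with the standard 9-beat
    pre-pacing from ``base_state``) and returns the current-clamp error
    against ``target``, whose mask should already exclude stimulus artifacts.
    """
    from .models.base import SimulationSettings
    from .simulation import simulate_current_clamp

    if settings is None:
        settings = SimulationSettings()
    candidate = simulate_current_clamp(
        model, scaling, base_state, novel, settings=settings, prepace=True
    )
    return error_current_clamp(target, candidate)


def error_combined(
    target: ObjectiveTarget,
    candidate_voltage: Optional[Trace] = None,
    candidate_current: Optional[Trace] = None,
    cc_weight: float = 1.0,
    vc_weight: float = 1.0,
) -> ErrorValue:
    """Joint dimensionless error: unweighted sum of CC and VC components.

    The weight hooks default to 1 and exist only for exploratory use.
    """
    cc = vc = 0.0
    if target.voltage is not None:
        if candidate_voltage is None:
            raise ValueError("target has a voltage trace but no candidate was given")
        cc = cc_weight * _sum_sq(target.voltage, candidate_voltage, "mV")
    if target.current is not None:
        if candidate_current is None:
            raise ValueError("target has a current trace but no candidate was given")
        vc = vc_weight * _sum_sq(target.current, candidate_current, "A/F")
    return ErrorValue(cc=cc, vc=vc)
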