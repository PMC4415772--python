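"""Stimulation and voltage-clamp protocols.

Two kinds of protocol drive the fitting data:

* **Stochastic current-clamp stimulation** — 5 s sequences of brief (1 ms,
  -40 A/F) depolarizing pulses whose inter-stimulus intervals are drawn
  uniformly from 100–700 ms.  Fixed optimization and prediction sequences are
  provided as constants; new sequences can be drawn reproducibly from a seed.
* **Multi-step voltage clamp** — a fixed 6000 ms sequence of 11 holding
  potentials, each chosen to emphasize particular membrane currents, preceded
  by a 5 s hold at -80 mV so the model settles after parameter changes.

The per-step current-contribution table quantifies how well each step isolates
a current: contribution of current x in a step is
``100 * sum_t |I_x(t)| / sum_j sum_t |I_j(t)|`` over samples in the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np

from .trace import Trace

#: Default stimulus pulse: 1 ms square pulse, -40 A/F (depolarizing = negative
#: injected current).
STIM_AMPLITUDE = -40.0  # A/F
STIM_WIDTH = 1.0  # ms

#: Uniform inter-stimulus interval range for stochastic sequences (ms).
INTERVAL_RANGE = (100.0, 700.0)

_OPTIMIZATION_TIMES = (
    216.48, 623.36, 764.64, 1101.12, 1790.16, 2073.10,
    2642.28, 3183.10, 3786.07, 3959.02, 4579.72,
)

_PREDICTION_TIMES = (
    247.40, 705.30, 1020.60, 1347.90, 1462.60, 1705.60, 2038.30,
    2546.70, 3150.30, 3706.70, 3939.70, 4077.80, 4645.50,
)

_MULTISTEP_STEPS = (
    (50.0, -80.0),
    (50.0, -120.0),
    (500.0, -57.0),
    (25.0, -40.0),
    (75.0, 20.0),
    (25.0, -80.0),
    (250.0, 40.0),
    (1900.0, -30.0),
    (750.0, 40.0),
    (1725.0, -30.0),
    (650.0, -80.0),
)

#: Pre-hold before the multi-step protocol: 5 s at -80 mV.
MULTISTEP_PREHOLD = (5000.0, -80.0)


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered stimulus onset times with a common square-pulse shape."""

    onsets: Tuple[float, ...]
    amplitude: float = STIM_AMPLITUDE  # A/F
    width: float = STIM_WIDTH  # ms
    duration: float = 5000.0  # ms

    def __post_init__(self):
        onsets = tuple(float(t) for t in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.duration):
            raise ValueError("stimulus onsets must lie in [0, duration)")

    def __len__(self) -> int:
        return len(self.onsets)

    def onset_array(self) -> np.ndarray:
        return np.array(self.onsets, dtype=np.float64)


@dataclass(frozen=True)
class VoltageClampProtocol:
    """Ordered (duration ms, holding potential mV) steps with optional pre-hold."""

    steps: Tuple[Tuple[float, float], ...]
    prehold: Tuple[float, float] = None  # (duration ms, potential mV) or None

    def __post_init__(self):
        steps = tuple((float(d), float(v)) for d, v in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValueError("protocol must contain at least one step")
        if any(d <= 0 for d, _ in steps):
            raise ValueError("step durations must be positive")
        if self.prehold is not None:
            ph = (float(self.prehold[0]), float(self.prehold[1]))
            if ph[0] <= 0:
                raise ValueError("pre-hold duration must be positive")
            object.__setattr__(self, "prehold", ph)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def total_duration(self) -> float:
        """Total duration of the protocol proper (pre-hold excluded), ms."""
        return float(sum(d for d, _ in self.steps))

    def boundaries(self) -> np.ndarray:
        """Step start times (protocol-relative), including t=0, plus the end time."""
        durations = np.array([d for d, _ in self.steps])
        return np.concatenate([[0.0], np.cumsum(durations)])

    def transition_times(self) -> np.ndarray:
        """Times of commanded potential changes, including protocol start (t=0)."""
        return self.boundaries()[:-1]

    def durations(self) -> np.ndarray:
        return np.array([d for d, _ in self.steps], dtype=np.float64)

    def potentials(self) -> np.ndarray:
        return np.array([v for _, v in self.steps], dtype=np.float64)


def optimization_sequence() -> StimulusSequence:
    """The fixed 11-stimulus stochastic sequence used as the fitting objective."""
    return StimulusSequence(_OPTIMIZATION_TIMES)


def prediction_sequence() -> StimulusSequence:
    """The fixed 13-stimulus sequence used to score prediction of novel dynamics."""
    return StimulusSequence(_PREDICTION_TIMES)


def random_sequence(
    seed: int,
    duration: float = 5000.0,
    interval_range: Tuple[float, float] = INTERVAL_RANGE,
) -> StimulusSequence:
    """Draw a fresh stochastic sequence.

    Successive gaps (and the first onset, measured from time zero) are i.i.d.
    uniform on ``interval_range``; generation stops when the next onset would
    fall at or beyond ``duration``.
    """
    low, high = float(interval_range[0]), float(interval_range[1])
    if not (0 < low < high <= duration):
        raise ValueError(f"degenerate interval range {interval_range!r}")
    rng = np.random.default_rng(seed)
    onsets = []
    t = 0.0
    while True:
        t += rng.uniform(low, high)
        if t >= duration:
            break
        onsets.append(t)
    return StimulusSequence(tuple(onsets), duration=duration)


def multistep_protocol(prehold: bool = True) -> VoltageClampProtocol:
    """The fixed 11-step, 6000 ms voltage-clamp protocol (with 5 s -80 mV pre-hold)."""
    return VoltageClampProtocol(
        _MULTISTEP_STEPS, prehold=MULTISTEP_PREHOLD if prehold else None
    )


def apply_junction_correction(
    protocol: VoltageClampProtocol, offset: float = -3.0
) -> VoltageClampProtocol:
    """Shift every holding potential by ``offset`` mV (liquid junction correction).

    Applied to command potentials only when fitting experimental recordings.
    """
    steps = tuple((d, v + offset) for d, v in protocol.steps)
    prehold = None
    if protocol.prehold is not None:
        prehold = (protocol.prehold[0], protocol.prehold[1] + offset)
    return VoltageClampProtocol(steps, prehold=prehold)


@dataclass
class ContributionTable:
    """Percentage contribution of each current within each protocol step.

    ``values[i, j]`` is the contribution (%) of current ``currents[j]`` during
    step ``i``; rows sum to 100.
    """

    currents: Tuple[str, ...]
    steps: Tuple[Tuple[float, float], ...]
    values: np.ndarray  # (n_steps, n_currents), percent

    def dominant(self, step_index: int) -> str:
        """Name of the current with the largest contribution in a step."""
        return self.currents[int(np.argmax(self.values[step_index]))]

    def to_frame(self):
        import pandas as pd

        index = [f"{v:+.0f} mV ({d:.0f} ms)" for d, v in self.steps]
        return pd.DataFrame(self.values, index=index, columns=list(self.currents))


def current_contribution(
    traces: Dict[str, Trace], protocol: VoltageClampProtocol
) -> ContributionTable:
    """Per-step percentage contribution of each current (absolute-value weighted).

    Samples are assigned to steps by half-open intervals [step start, step end)
    on the protocol-relative time axis.
    """
    names = tuple(traces.keys())
    if not names:
        raise ValueError("no current traces supplied")
    t = traces[names[0]].times
    for n in names:
        if traces[n].times.shape != t.shape or not np.allclose(traces[n].times, t):
            raise ValueError("current traces must share a common time grid")
    bounds = protocol.boundaries()
    absmat = np.abs(np.stack([traces[n].values for n in names]))  # (ncur, nt)
    values = np.empty((len(protocol), len(names)))
    for i in range(len(protocol)):
        in_step = (t >= bounds[i] - 1e-9) & (t < bounds[i + 1] - 1e-9)
        sums = absmat[:, in_step].sum(axis=1)
        denom = sums.sum()
        if denom == 0:
            raise ValueError(
                f"all currents are zero within step {i} "
                f"({protocol.steps[i][1]:+.0f} mV); contribution undefined"
            )
        values[i] = 100.0 * sums / denom
    return ContributionTable(names, protocol.steps, values)


# ---------------------------------------------------------------------------
# Plain-text serialization (one row per step / stimulus)

def protocol_to_rows(obj) -> list:
    """Serialize a protocol to rows of (kind, time-or-duration, value)."""
    if isinstance(obj, StimulusSequence):
        rows = [("stimulus", t, obj.amplitude) for t in obj.onsets]
        rows.append(("meta.width_ms", obj.width, ""))
        rows.append(("meta.duration_ms", obj.duration, ""))
        return rows
    if isinstance(obj, VoltageClampProtocol):
        rows = []
        if obj.prehold is not None:
            rows.append(("prehold", obj.prehold[0], obj.prehold[1]))
        rows.extend(("step", d, v) for d, v in obj.steps)
        return rows
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def rows_to_protocol(rows: Sequence[Tuple]):
    """Inverse of :func:`protocol_to_rows`."""
    kinds = {r[0] for r in rows}
    if "step" in kinds:
        steps = tuple((float(r[1]), float(r[2])) for r in rows if r[0] == "step")
        prehold = None
        for r in rows:
            if r[0] == "prehold":
                prehold = (float(r[1]), float(r[2]))
        return VoltageClampProtocol(steps, prehold=prehold)
    if "stimulus" in kinds:
        onsets = tuple(float(r[1]) for r in rows if r[0] == "stimulus")
        amp = next(float(r[2]) for r in rows if r[0] == "stimulus")
        width = next((float(r[1]) for r in rows if r[0] == "meta.width_ms"), STIM_WIDTH)
        duration = next(
            (float(r[1]) for r in rows if r[0] == "meta.duration_ms"), 5000.0
        )
        return StimulusSequence(onsets, amplitude=amp, width=width, duration=duration)
    raise ValueError("rows contain neither steps nor stimuli")
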