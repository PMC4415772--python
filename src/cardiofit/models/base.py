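"""Ionic model contract.

The fitting machinery is model-agnostic: any model exposing this interface can
be driven by the protocols and fitted by the GA.  A model owns

* a named state vector (membrane potential, gating variables, Ca pools),
* current-clamp and voltage-clamp runners that apply the nine conductance/flux
  scalings and integrate with a fixed-step Rush–Larsen scheme (exponential
  update for gates, forward Euler for potential and concentrations),
* an instantaneous per-current evaluator used for diagnostics.

Units: time ms, potential mV, currents A/F, concentrations mmol/l.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator settings.

    dt: internal fixed step (ms); ``None`` selects the model's native step.
    out_dt: output sampling interval (ms); must be an integer multiple of dt.
    """

    dt: Optional[float] = None
    out_dt: float = 0.1

    def __post_init__(self):
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.out_dt <= 0:
            raise ValueError("out_dt must be positive")

    def resolve_dt(self, model: "IonicModel") -> float:
        dt = self.dt if self.dt is not None else model.default_dt
        stride = self.out_dt / dt
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"out_dt ({self.out_dt} ms) must be an integer multiple of dt ({dt} ms)"
            )
        return dt

    def key(self) -> tuple:
        return (self.dt, self.out_dt)


@dataclass
class ModelState:
    """Named snapshot of a model's state vector (bit-exactly restorable)."""

    model_name: str
    names: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("state vector length does not match state names")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite state variables: {bad}")

    def copy(self) -> "ModelState":
        return ModelState(self.model_name, self.names, self.values.copy())

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


class SolverError(RuntimeError):
    """Integration produced a non-finite state; names the time and variable."""

    def __init__(self, model_name: str, time: float, variable: str):
        self.time = time
        self.variable = variable
        super().__init__(
            f"{model_name}: non-finite value of {variable!r} at t = {time:.3f} ms"
        )


class IonicModel:
    """Abstract base for concrete ionic models.

    Subclasses set ``name``, ``state_names``, ``current_names``,
    ``default_dt`` and implement the three runner hooks below.  All runners
    take the nine scalings as a float64 array in canonical parameter order.
    """

    name: str = ""
    state_names: Tuple[str, ...] = ()
    current_names: Tuple[str, ...] = ()
    default_dt: float = 0.01

    # -- construction -----------------------------------------------------
    def initial_state(self) -> ModelState:
        raise NotImplementedError

    def make_state(self, values: np.ndarray) -> ModelState:
        return ModelState(self.name, self.state_names, np.asarray(values, float))

    def check_state(self, state: ModelState):
        if state.model_name != self.name:
            raise ValueError(
                f"state belongs to model {state.model_name!r}, not {self.name!r}"
            )

    # -- runner hooks (implemented by subclasses) -------------------------
    def run_current_clamp(
        self,
        scalings: np.ndarray,
        state: np.ndarray,
        onsets: np.ndarray,
        amplitude: float,
        width: float,
        duration: float,
        record_start: float,
        dt: float,
        out_dt: float,
        record_ca: bool = False,
    ):
        """Integrate under injected-current drive.

        Returns (times, V, Cai-or-None, final state).  ``times`` covers
        [record_start, duration] on the out_dt grid, reported relative to
        record_start.
        """
        raise NotImplementedError

    def run_voltage_clamp(
        self,
        scalings: np.ndarray,
        state: np.ndarray,
        durations: np.ndarray,
        potentials: np.ndarray,
        prehold_duration: float,
        prehold_potential: float,
        dt: float,
        out_dt: float,
        record_currents: bool = False,
        record_ca: bool = False,
    ):
        """Integrate with the membrane potential clamped to the commanded steps.

        Returns (times, total current, per-current matrix-or-None, Cai-or-None,
        final state).  Times cover the protocol proper (pre-hold excluded).
        """
        raise NotImplementedError

    def currents_at(self, state: np.ndarray, scalings: np.ndarray) -> Dict[str, float]:
        """Instantaneous membrane currents (A/F) at a fixed state."""
        raise NotImplementedError

    # -- helpers ----------------------------------------------------------
    def _check_finite(self, state_values: np.ndarray, time: float):
        if not np.all(np.isfinite(state_values)):
            idx = int(np.argmax(~np.isfinite(state_values)))
            raise SolverError(self.name, time, self.state_names[idx])
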