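"""The nine scalable conductance/flux parameters.

A candidate cell-specific model is the baseline ionic model with each maximal
conductance (and the maximal SERCA uptake flux) multiplied by a dimensionless
positive scaling.  A scaling of 1.0 everywhere reproduces the baseline model.
The parameter order is fixed throughout the package: I_Na, I_CaL, I_CaT, I_K1,
I_Kr, I_Ks, I_Kp, I_pCa, J_SERCA.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Canonical parameter order (index 0..8).
PARAMETER_NAMES = (
    "s_Na",
    "s_CaL",
    "s_CaT",
    "s_K1",
    "s_Kr",
    "s_Ks",
    "s_Kp",
    "s_pCa",
    "s_SERCA",
)

#: Human-readable current/flux labels in the same order.
PARAMETER_LABELS = (
    "I_Na",
    "I_CaL",
    "I_CaT",
    "I_K1",
    "I_Kr",
    "I_Ks",
    "I_Kp",
    "I_pCa",
    "J_SERCA",
)

N_PARAMETERS = len(PARAMETER_NAMES)


@dataclass(frozen=True)
class ParameterScaling:
    """Nine positive multipliers applied to the baseline maximal conductances.

    Iterating over an instance yields the nine values in canonical order.
    """

    s_Na: float = 1.0
    s_CaL: float = 1.0
    s_CaT: float = 1.0
    s_K1: float = 1.0
    s_Kr: float = 1.0
    s_Ks: float = 1.0
    s_Kp: float = 1.0
    s_pCa: float = 1.0
    s_SERCA: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"scaling {f.name} must be a positive finite number, got {v!r}"
                )

    def __iter__(self):
        return (getattr(self, name) for name in PARAMETER_NAMES)

    def as_array(self) -> np.ndarray:
        """Return the scalings as a float64 array in canonical order."""
        return np.array(list(self), dtype=np.float64)

    @classmethod
    def from_array(cls, values) -> "ParameterScaling":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (N_PARAMETERS,):
            raise ValueError(
                f"expected {N_PARAMETERS} scalings, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAMETER_NAMES, values.tolist())))

    def replace(self, **kwargs) -> "ParameterScaling":
        d = {name: getattr(self, name) for name in PARAMETER_NAMES}
        d.update(kwargs)
        return ParameterScaling(**d)

    def key(self) -> tuple:
        """Hashable identity used for steady-state caching."""
        return tuple(float(v) for v in self)
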