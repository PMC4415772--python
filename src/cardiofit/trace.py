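"""Sampled time series with exclusion masks.

Traces carry membrane potential (mV), total membrane current (A/F) or
intracellular calcium (mM) on a strictly increasing time grid, plus a boolean
inclusion mask.  Objective functions only see mask-included samples; masks are
how stimulus artifacts and capacitance transients are excised from fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = ("mV", "A/F", "mM")


@dataclass
class Trace:
    times: np.ndarray  # ms
    values: np.ndarray
    unit: str
    mask: np.ndarray = None  # True = included

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")
        if self.mask is None:
            self.mask = np.ones(self.times.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.times.shape:
                raise ValueError("mask length must equal trace length")

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "Trace":
        return Trace(self.times.copy(), self.values.copy(), self.unit, self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "Trace":
        return Trace(self.times, self.values, self.unit, mask)

    def included(self) -> np.ndarray:
        """Values at mask-included samples."""
        return self.values[self.mask]

    def resample_onto(self, times: np.ndarray) -> "Trace":
        """Linearly interpolate the trace onto a new time grid (mask reset to all-True)."""
        times = np.asarray(times, dtype=np.float64)
        vals = np.interp(times, self.times, self.values)
        return Trace(times, vals, self.unit)
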