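"""Vascular input function (VIF): plasma contrast concentration over time.

The VIF drives the Patlak forward model.  A population biexponential decay
after bolus arrival stands in for a measured superior-sagittal-sinus time
course; no hematocrit correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: default population parameters: fast and slow decay amplitudes (mM) and
#: rates (1/s), bolus arrival at 30 s.  Peak plasma concentration at arrival
#: is a1 + a2 ~ 3.3 mM, a plausible post-Gadobutrol blood level.
DEFAULT_A1 = 2.5
DEFAULT_M1 = 0.01
DEFAULT_A2 = 0.8
DEFAULT_M2 = 2.0e-4
DEFAULT_ARRIVAL_S = 30.0


@dataclass
class VascularInputFunction:
    """Plasma concentration time course C_p(t).

    Attributes
    ----------
    times : array, seconds, strictly increasing
    cp : array, plasma concentration (mM), zero before ``arrival_time``
    arrival_time : bolus arrival (seconds)
    """

    times: np.ndarray
    cp: np.ndarray
    arrival_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.ndim != 1 or self.cp.shape != self.times.shape:
            raise ValueError("times and cp must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cp < 0):
            raise ValueError("cp must be non-negative")
        if np.any(self.cp[self.times < self.arrival_time] != 0):
            raise ValueError("cp must be zero before arrival_time")


def generate_vif(
    a1: float = DEFAULT_A1,
    m1: float = DEFAULT_M1,
    a2: float = DEFAULT_A2,
    m2: float = DEFAULT_M2,
    arrival_time: float = DEFAULT_ARRIVAL_S,
    times: np.ndarray | None = None,
) -> VascularInputFunction:
    """Biexponential plasma input:
    ``cp(t) = a1*exp(-m1*(t-t0)) + a2*exp(-m2*(t-t0))`` for ``t >= t0``, else 0.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("amplitudes must be non-negative")
    if m1 <= 0 or m2 <= 0:
        raise ValueError("decay rates must be positive")
    if times is None:
        times = default_dce_times()
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1D array")
    dt = times - arrival_time
    cp = np.where(dt >= 0, a1 * np.exp(-m1 * np.maximum(dt, 0)) + a2 * np.exp(-m2 * np.maximum(dt, 0)), 0.0)
    return VascularInputFunction(times=times, cp=cp, arrival_time=float(arrival_time))


def default_dce_times(duration_s: float = 1200.0, dt_s: float = 24.0) -> np.ndarray:
    """Default DCE sampling grid: 20 min acquisition at 24 s per volume.

    The acquisition timing is a configurable convention of the synthetic
    protocol, not a measured quantity.
    """
    return np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)


def cumulative_plasma_integral(vif: VascularInputFunction) -> np.ndarray:
    """Trapezoidal cumulative integral of C_p, in mM*min (first element 0)."""
    integral_s = cumulative_trapezoid(vif.cp, vif.times, initial=0.0)
    return integral_s / 60.0
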