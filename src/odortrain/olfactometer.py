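"""First-order kinetics of delivered odor concentration.

The odor-delivery unit is characterized per odorant by two constants
measured with a photoionization detector: the rising latency ``L95``
(time after valve opening to reach 95% of the concentration plateau) and
the decay time constant ``tau_d`` (time after valve closing to fall to
1/e of the level at closing).  Each phase is modeled as a single
exponential; the rise time constant follows from the latency,

    1 - exp(-L95 / tau_r) = 0.95   =>   tau_r = L95 / ln 20.

The plateau is normalized to 1 (relative concentration); the fraction of
saturated vapor in the carrier air is carried as metadata only.  Traces
are exactly repeatable across valve cycles -- no adaptation or residual
term is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OdorKinetics",
    "ODOR_LIBRARY",
    "calibrate_kinetics",
    "concentration_trace",
    "time_to_fraction",
]

_LN20 = math.log(20.0)


@dataclass(frozen=True)
class OdorKinetics:
    """Calibrated delivery kinetics of one odorant.

    Attributes
    ----------
    name : str
    relative_volume_ratio : float
        Percentage of saturated vapor in the carrier air (metadata).
    rise_latency_ms : float
        Time to reach 95% of plateau after valve opening (L95).
    decay_tau_ms : float
        Exponential time constant of the fall after valve closing.
    rise_tau_ms : float
        Derived rise time constant, ``L95 / ln 20``.
    """

    name: str
    relative_volume_ratio: float
    rise_latency_ms: float
    decay_tau_ms: float
    rise_tau_ms: float


def calibrate_kinetics(
    name: str,
    relative_volume_ratio: float,
    rise_latency_ms: float,
    decay_tau_ms: float,
) -> OdorKinetics:
    """Build :class:`OdorKinetics` from the measured constants.

    ``rise_latency_ms`` and ``decay_tau_ms`` must be positive; the rise
    time constant is derived as ``rise_latency_ms / ln 20`` so the rising
    exponential reaches exactly 95% at the stated latency.
    """
    if rise_latency_ms <= 0:
        raise ValueError("rise_latency_ms must be positive")
    if decay_tau_ms <= 0:
        raise ValueError("decay_tau_ms must be positive")
    return OdorKinetics(
        name=name,
        relative_volume_ratio=relative_volume_ratio,
        rise_latency_ms=float(rise_latency_ms),
        decay_tau_ms=float(decay_tau_ms),
        rise_tau_ms=rise_latency_ms / _LN20,
    )


#: Measured delivery kinetics of the four odorants used in the tasks
#: (ratio % of saturated vapor, rising latency to 95% in ms, decay time
#: constant in ms).
ODOR_LIBRARY: dict[str, OdorKinetics] = {
    k.name: k
    for k in (
        calibrate_kinetics("1-Butanol", 10.0, 18.0, 20.0),
        calibrate_kinetics("Methyl butyrate", 2.5, 17.0, 22.0),
        calibrate_kinetics("Hexanoic acid", 15.0, 31.0, 41.0),
        calibrate_kinetics("Octane", 5.0, 71.0, 31.0),
    )
}


def concentration_trace(
    kinetics: OdorKinetics,
    valve_open_ms: float,
    valve_close_ms: float,
    t_grid_ms: Sequence[float],
) -> np.ndarray:
    """Relative concentration over a time grid for one valve cycle.

    ``c(t) = 0`` before the valve opens, ``1 - exp(-(t - open)/tau_r)``
    while open, and ``c(close) * exp(-(t - close)/tau_d)`` after closing.
    The grid must be sorted ascending.
    """
    if valve_open_ms >= valve_close_ms:
        raise ValueError("valve_open_ms must precede valve_close_ms")
    t = np.asarray(t_grid_ms, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid_ms must be sorted ascending")
    c = np.zeros_like(t)
    rising = (t >= valve_open_ms) & (t < valve_close_ms)
    c[rising] = 1.0 - np.exp(-(t[rising] - valve_open_ms) / kinetics.rise_tau_ms)
    c_close = 1.0 - math.exp(-(valve_close_ms - valve_open_ms) / kinetics.rise_tau_ms)
    falling = t >= valve_close_ms
    c[falling] = c_close * np.exp(-(t[falling] - valve_close_ms) / kinetics.decay_tau_ms)
    return c


def time_to_fraction(kinetics: OdorKinetics, fraction: float, phase: str) -> float:
    """Invert one phase's exponential: time (ms) to reach ``fraction``.

    For ``phase="rise"``, the time after valve opening at which the trace
    reaches ``fraction`` of plateau: ``-tau_r * ln(1 - fraction)``.  For
    ``phase="decay"``, the time after valve closing to fall to
    ``fraction`` of the level at closing: ``-tau_d * ln(fraction)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if phase == "rise":
        return -kinetics.rise_tau_ms * math.log(1.0 - fraction)
    if phase == "decay":
        return -kinetics.decay_tau_ms * math.log(fraction)
    raise ValueError(f"phase must be 'rise' or 'decay', got {phase!r}")
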