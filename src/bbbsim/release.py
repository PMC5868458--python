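"""Linear release/uptake kinetics of encapsulated delphinidin.

Nanoparticle-borne compound taken up by the p-gp transporter (pool
``C_u_star``) converts to released compound in the brain (pool ``C_star``)
at the uptake rate ``k_2``; the released pool clears at the release rate
``k_1``.  This is the classic two-compartment linear cascade whose
released-pool time course is the Bateman function

    C*(t) = C_u*(0) · k_2/(k_2 − k_1) · (exp(−k_1·t) − exp(−k_2·t))

peaking at ``t_peak = ln(k_2/k_1)/(k_2 − k_1)`` — about 50.1 min at the
default rates (k_1 = 0.01/min, k_2 = 0.035/min).  At equal rates the
Bateman form degenerates to ``C_u*(0)·k·t·exp(−k·t)`` with peak ``1/k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReleaseParameters",
    "ReleaseState",
    "release_rhs",
    "bateman",
    "peak_time",
    "peak_value",
]

# relative rate difference below which the equal-rates limit is used,
# avoiding catastrophic cancellation in (exp(-k1 t) - exp(-k2 t))/(k2 - k1)
_EQUAL_RATE_RTOL = 1e-9


class ReleaseParameterError(ValueError):
    """Invalid release-kinetics parameter or state."""


@dataclass(frozen=True)
class ReleaseParameters:
    """First-order rate constants (1/min).

    ``k_1`` — release (clearance) rate of delphinidin from the endothelial
    cytoplasm; ``k_2`` — p-gp uptake rate feeding the released pool.
    """

    k_1: float = 0.01
    k_2: float = 0.035

    def __post_init__(self) -> None:
        if not (self.k_1 > 0):
            raise ReleaseParameterError(f"k_1 must be positive, got {self.k_1}")
        if self.k_2 < 0:
            raise ReleaseParameterError(f"k_2 must be non-negative, got {self.k_2}")


@dataclass(frozen=True)
class ReleaseState:
    """Concentrations of the uptaken (``C_u_star``) and released
    (``C_star``) pools, µM."""

    C_u_star: float = 1.0
    C_star: float = 0.0

    def __post_init__(self) -> None:
        if self.C_u_star < 0 or self.C_star < 0:
            raise ReleaseParameterError(
                f"pool concentrations must be non-negative, got "
                f"C_u_star={self.C_u_star}, C_star={self.C_star}"
            )


def release_rhs(state: ReleaseState, params: ReleaseParameters) -> tuple[float, float]:
    """Time derivatives ``(dC_u_star/dt, dC_star/dt)`` of the cascade."""
    dCu = -params.k_2 * state.C_u_star
    dC = params.k_2 * state.C_u_star - params.k_1 * state.C_star
    return dCu, dC


def _rates_equal(k_1: float, k_2: float) -> bool:
    return abs(k_2 - k_1) < _EQUAL_RATE_RTOL * max(k_1, k_2)


def bateman(
    t: np.ndarray | float,
    params: ReleaseParameters,
    init: ReleaseState = ReleaseState(),
) -> np.ndarray | float:
    """Closed-form released-pool concentration ``C_star(t)``.

    Handles a nonzero initial released pool (which decays at ``k_1``) and
    switches to the degenerate equal-rates branch near ``k_1 = k_2``.
    """
    t = np.asarray(t, dtype=float)
    k1, k2 = params.k_1, params.k_2
    decay_init = init.C_star * np.exp(-k1 * t)
    if _rates_equal(k1, k2):
        k = 0.5 * (k1 + k2)
        pulse = init.C_u_star * k * t * np.exp(-k * t)
    else:
        pulse = (
            init.C_u_star
            * k2
            / (k2 - k1)
            * (np.exp(-k1 * t) - np.exp(-k2 * t))
        )
    out = decay_init + pulse
    return out if out.ndim else float(out)


def peak_time(params: ReleaseParameters) -> float:
    """Time of the released-pool maximum for the pulse initial condition
    (all compound uptaken, none yet released).

    ``ln(k_2/k_1)/(k_2 − k_1)``, with the limit ``1/k`` at equal rates;
    symmetric under swapping the two rates.
    """
    k1, k2 = params.k_1, params.k_2
    if not (k2 > 0):
        raise ReleaseParameterError(
            f"peak time requires k_2 > 0 (nothing enters the released pool), got {k2}"
        )
    if _rates_equal(k1, k2):
        return 2.0 / (k1 + k2)
    return math.log(k2 / k1) / (k2 - k1)


def peak_value(params: ReleaseParameters, init: ReleaseState = ReleaseState()) -> float:
    """Released-pool concentration at :func:`peak_time` (pulse initial
    condition; an initial released pool shifts the true peak slightly and
    is evaluated numerically by the simulator instead)."""
    return float(bateman(peak_time(params), params, init))
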