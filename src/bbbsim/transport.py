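"""Four-compartment transport model of the blood–brain barrier.

Free (mode 1) or nanoparticle-encapsulated (mode 2) delphinidin exchanges
between the capillary lumen (concentration ``C_L``) and the endothelial
cytoplasm (``C_E``) across the luminal membrane, and between the
endothelium and a constant brain-tissue bath ``C_M`` across the abluminal
membrane.  Membrane transport is linear in the concentration difference
with permeability coefficients ``D_LE`` (mode-dependent) and ``D_EM``
(velocity units, flux = area · permeability · ΔC).  The p-glycoprotein
pump returns compound from the endothelium to the lumen with saturable
Michaelis–Menten kinetics:

    J_pgp(C_E) = J_max · C_E / (K_M + C_E)

``J_max`` is a flux per unit capillary length (amol/(min·µm) canonically),
so the pump's total rate is ``J_pgp · l``; divided by a compartment volume
it becomes a concentration rate.  The brain bath ``C_M`` is held constant:
no mass balance is enforced across the outer membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .geometry import CapillaryGeometry
from .units import CANONICAL, UnitSystem

__all__ = [
    "TransportParameters",
    "TransportState",
    "Mode",
    "pgp_flux",
    "transport_rhs",
    "ParameterError",
]

Mode = Literal["free", "encapsulated"]


class ParameterError(ValueError):
    """Invalid model parameter or state."""


@dataclass(frozen=True)
class TransportParameters:
    """Rate constants and boundary values in canonical units.

    Defaults are the model's published parameter set: permeabilities in
    µm/min, ``J_max`` in amol/(min·µm) (2.42 pmol/(min·dm)), concentrations
    in µM, times in min.  ``D_LE_1`` (free compound) is an order-of-magnitude
    estimate rather than a measured value; see the config schema's
    provenance labels.
    """

    D_LE_1: float = 0.5
    D_LE_2: float = 34.8
    D_EM: float = 1.89
    J_max: float = 24.2
    K_M: float = 1.5
    C_M: float = 1.0
    t_start: float = 0.0
    t_stop: float = 20.0

    def __post_init__(self) -> None:
        for name in ("D_LE_1", "D_LE_2", "D_EM", "J_max", "C_M"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not (self.K_M > 0):
            raise ParameterError(f"K_M must be positive, got {self.K_M}")
        if not (self.t_stop > self.t_start):
            raise ParameterError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )

    def D_LE(self, mode: Mode) -> float:
        if mode == "free":
            return self.D_LE_1
        if mode == "encapsulated":
            return self.D_LE_2
        raise ParameterError(f"unknown mode {mode!r}")

    def with_overrides(self, **kwargs: float) -> "TransportParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TransportState:
    """Instantaneous compartment concentrations (µM) and transport mode."""

    C_L: float
    C_E: float
    mode: Mode = "free"

    def __post_init__(self) -> None:
        if self.C_L < 0 or self.C_E < 0:
            raise ParameterError(
                f"concentrations must be non-negative, got C_L={self.C_L}, C_E={self.C_E}"
            )
        if self.mode not in ("free", "encapsulated"):
            raise ParameterError(f"mode must be 'free' or 'encapsulated', got {self.mode!r}")


def pgp_flux(C_E: float, J_max: float, K_M: float) -> float:
    """Saturable p-gp efflux flux per unit capillary length.

    Returns ``J_max·C_E/(K_M + C_E)``: zero at ``C_E = 0``, half-maximal at
    ``C_E = K_M``, bounded in ``[0, J_max)`` and monotone in ``C_E``.
    """
    if C_E < 0:
        raise ParameterError(f"C_E must be non-negative, got {C_E}")
    if not (K_M > 0):
        raise ParameterError(f"K_M must be positive, got {K_M}")
    if J_max < 0:
        raise ParameterError(f"J_max must be non-negative, got {J_max}")
    return J_max * C_E / (K_M + C_E)


def transport_rhs(
    state: TransportState,
    params: TransportParameters,
    geom: CapillaryGeometry,
    units: UnitSystem = CANONICAL,
) -> tuple[float, float]:
    """Time derivatives ``(dC_L/dt, dC_E/dt)`` in concentration/time units.

    The membrane terms ``A·D·ΔC/V`` are already concentration rates when
    concentrations are in the system's concentration unit; the pump term
    ``J_pgp·l/V`` is an amount density rate and is scaled by the unit
    system's amount-density→concentration factor before summation.  Efflux
    adds to the lumen and subtracts from the endothelium.
    """
    D_LE = params.D_LE(state.mode)
    efflux = pgp_flux(state.C_E, params.J_max, params.K_M) * geom.l
    efflux_conc = efflux * units.conc_per_amount_density  # conc·volume/time
    dC_L = (geom.A_LE * D_LE * (state.C_E - state.C_L) + efflux_conc) / geom.V_L
    dC_E = (
        geom.A_LE * D_LE * (state.C_L - state.C_E)
        + geom.A_EM * params.D_EM * (params.C_M - state.C_E)
        - efflux_conc
    ) / geom.V_E
    return dC_L, dC_E
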