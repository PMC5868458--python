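"""Unit handling for the capillary transport model.

The model's published parameters mix units (µm, km, min, µM, pmol/(min·dm)),
so every quantity is converted into one canonical system before any
right-hand side is evaluated.  The canonical system is

* length      µm   (permeabilities are already quoted in µm/min)
* time        min
* amount      amol
* concentration µM

Concentrations are kept in µM rather than amol/µm³; the single place the
two meet — dividing an amount flux by a compartment volume — goes through
:attr:`UnitSystem.conc_per_amount_density`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UnitSystem",
    "CANONICAL",
    "to_canonical",
    "from_canonical",
    "supported_units",
    "UnitError",
]


class UnitError(ValueError):
    """Raised for unknown unit strings or dimension mismatches."""


# SI factors for the base dimensions used by the model.
_LENGTH_M = {
    "um": 1e-6,
    "mm": 1e-3,
    "cm": 1e-2,
    "dm": 1e-1,
    "m": 1.0,
    "km": 1e3,
}
_TIME_S = {"s": 1.0, "min": 60.0, "h": 3600.0}
_AMOUNT_MOL = {
    "amol": 1e-18,
    "fmol": 1e-15,
    "pmol": 1e-12,
    "nmol": 1e-9,
    "umol": 1e-6,
    "mmol": 1e-3,
    "mol": 1.0,
}
_CONC_M = {"nM": 1e-9, "uM": 1e-6, "mM": 1e-3, "M": 1.0}


def _norm(unit: str) -> str:
    # accept the Greek micro sign as an alias for "u"
    return unit.replace("µ", "u").replace("μ", "u").strip()


@dataclass(frozen=True)
class UnitSystem:
    """A choice of base units; defines conversion factors for every
    dimension the model uses.

    Two different systems give numerically different parameter values but —
    by construction — identical physics; ``convert_value`` between systems
    is exact rescaling.
    """

    length: str = "um"
    time: str = "min"
    amount: str = "amol"
    concentration: str = "uM"

    def __post_init__(self) -> None:
        for table, name in (
            (_LENGTH_M, self.length),
            (_TIME_S, self.time),
            (_AMOUNT_MOL, self.amount),
            (_CONC_M, self.concentration),
        ):
            if _norm(name) not in table:
                raise UnitError(f"unsupported base unit {name!r}")

    # -- factors of this system's derived units, expressed in SI ----------
    def _si(self, kind: str) -> float:
        L = _LENGTH_M[_norm(self.length)]
        T = _TIME_S[_norm(self.time)]
        N = _AMOUNT_MOL[_norm(self.amount)]
        C = _CONC_M[_norm(self.concentration)]
        return {
            "length": L,
            "time": T,
            "amount": N,
            "concentration": C,
            "area": L**2,
            "volume": L**3,
            "permeability": L / T,  # membrane permeability, velocity units
            "rate": 1.0 / T,
            "linear_flux": N / (T * L),  # amount per time per capillary length
            "amount_flux": N / T,
        }[kind]

    @property
    def conc_per_amount_density(self) -> float:
        """Concentration units per (amount unit / length unit³).

        Canonical: 1 amol/µm³ = 1e3 µM, so the factor is 1000.
        """
        n = _AMOUNT_MOL[_norm(self.amount)]
        v = _LENGTH_M[_norm(self.length)] ** 3 * 1e3  # m³ -> L
        molar = n / v
        return molar / _CONC_M[_norm(self.concentration)]

    def convert_value(self, value: float, kind: str, other: "UnitSystem") -> float:
        """Re-express ``value`` of dimension ``kind`` from this system in
        ``other``'s units."""
        return value * self._si(kind) / other._si(kind)


CANONICAL = UnitSystem()


def _build_registry(system: UnitSystem) -> dict[str, tuple[str, float]]:
    """Printed-unit string -> (dimension kind, factor into ``system``)."""
    reg: dict[str, tuple[str, float]] = {}
    for u, f in _LENGTH_M.items():
        reg[u] = ("length", f / system._si("length"))
    for u, f in _TIME_S.items():
        reg[u] = ("time", f / system._si("time"))
    for u, f in _AMOUNT_MOL.items():
        reg[u] = ("amount", f / system._si("amount"))
    for u, f in _CONC_M.items():
        reg[u] = ("concentration", f / system._si("concentration"))
    # derived units printed in the parameter table
    for lu, lf in _LENGTH_M.items():
        for tu, tf in _TIME_S.items():
            reg[f"{lu}/{tu}"] = ("permeability", (lf / tf) / system._si("permeability"))
    for tu, tf in _TIME_S.items():
        reg[f"1/{tu}"] = ("rate", (1.0 / tf) / system._si("rate"))
        reg[f"/{tu}"] = ("rate", (1.0 / tf) / system._si("rate"))
    for nu, nf in _AMOUNT_MOL.items():
        for tu, tf in _TIME_S.items():
            reg[f"{nu}/{tu}"] = ("amount_flux", (nf / tf) / system._si("amount_flux"))
            for lu, lf in _LENGTH_M.items():
                key = f"{nu}/({tu}.{lu})"
                reg[key] = ("linear_flux", (nf / (tf * lf)) / system._si("linear_flux"))
    return reg


_REGISTRY = _build_registry(CANONICAL)


def supported_units() -> list[str]:
    """All printed-unit strings accepted by :func:`to_canonical`."""
    return sorted(_REGISTRY)


def _lookup(unit: str) -> tuple[str, float]:
    key = _norm(unit)
    if key not in _REGISTRY:
        raise UnitError(
            f"unknown unit {unit!r}; supported units: {', '.join(supported_units())}"
        )
    return _REGISTRY[key]


def to_canonical(value: float, unit: str) -> float:
    """Convert ``value`` expressed in a printed ``unit`` into the canonical
    system (µm / min / amol / µM)."""
    _, factor = _lookup(unit)
    return value * factor


def from_canonical(value: float, unit: str) -> float:
    """Inverse of :func:`to_canonical`; round-trips to 1 part in 1e12."""
    _, factor = _lookup(unit)
    return value / factor
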