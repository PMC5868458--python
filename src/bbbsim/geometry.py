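"""Idealised single-tube capillary geometry.

The brain's capillary bed is collapsed into one right circular cylinder:
a lumen of radius ``r_L`` wrapped by an endothelial shell out to ``r_E``,
with total length ``l`` (the aggregate length of all brain capillaries,
~600 km, treated as a single tube).  Compartment volumes and membrane
exchange areas follow the cylinder closed forms.  Every derived quantity
is linear in ``l``, so totals over the full length and per-unit-length
values give identical concentration dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CapillaryGeometry", "derive_geometry", "GeometryError"]


class GeometryError(ValueError):
    """Invalid capillary dimensions."""


@dataclass(frozen=True)
class CapillaryGeometry:
    """Capillary dimensions and derived volumes/areas (canonical units, µm).

    Attributes
    ----------
    r_L, r_E, l
        Luminal radius, endothelial outer radius, total length.
    V_L, V_E
        Luminal volume and endothelial shell volume (µm³).
    A_LE, A_EM
        Lumen–endothelium and endothelium–tissue exchange areas (µm²).
    """

    r_L: float
    r_E: float
    l: float
    V_L: float
    V_E: float
    A_LE: float
    A_EM: float


def derive_geometry(r_L: float, r_E: float, l: float) -> CapillaryGeometry:
    """Build a :class:`CapillaryGeometry` from the three lengths.

    Parameters are in canonical length units (µm).  Raises
    :class:`GeometryError` naming the offending field for non-positive or
    inverted radii.
    """
    if not (r_L > 0):
        raise GeometryError(f"r_L must be positive, got {r_L}")
    if not (r_E > r_L):
        raise GeometryError(f"r_E must exceed r_L, got r_E={r_E}, r_L={r_L}")
    if not (l > 0):
        raise GeometryError(f"l must be positive, got {l}")
    return CapillaryGeometry(
        r_L=r_L,
        r_E=r_E,
        l=l,
        V_L=math.pi * r_L**2 * l,
        V_E=math.pi * (r_E**2 - r_L**2) * l,
        A_LE=2.0 * math.pi * r_L * l,
        A_EM=2.0 * math.pi * r_E * l,
    )
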