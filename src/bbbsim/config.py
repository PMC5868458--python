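"""Parameter schema, defaults and configuration resolution.

The schema keys are the model's published parameter symbols verbatim
(``D_LE_1`` … ``t_stop``).  Values in config files and CLI overrides are
given in each parameter's printed unit (µm/min, µm, km, pmol/(min·dm), µM,
1/min, min — see :data:`SCHEMA`); they are converted to the canonical
system on resolution.  Precedence is CLI > file > defaults, and the
resolved provenance of every key is recorded and logged.

``k`` (a maximum p-gp pumping rate, 0.21 µmol/min) is part of the published
parameter table but appears in none of the model equations; it is carried
in the schema for completeness and unused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .geometry import CapillaryGeometry, derive_geometry
from .release import ReleaseParameters
from .transport import TransportParameters
from .units import to_canonical

__all__ = ["SCHEMA", "RunConfig", "resolve_config", "ConfigError", "load_config_file"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key, bad type or invalid value in a configuration source."""


@dataclass(frozen=True)
class ParamSpec:
    """One schema entry: printed default, printed unit, meaning, source tag."""

    default: float
    unit: str
    meaning: str
    source: str


#: the published parameter table, in its printed units
SCHEMA: dict[str, ParamSpec] = {
    "D_LE_1": ParamSpec(0.5, "um/min",
                        "lumen-endothelium permeability, free delphinidin",
                        "reasonable prediction (estimated)"),
    "D_LE_2": ParamSpec(34.8, "um/min",
                        "lumen-endothelium permeability, encapsulated delphinidin",
                        "literature"),
    "D_EM": ParamSpec(1.89, "um/min",
                      "endothelium-tissue permeability", "literature"),
    "r_L": ParamSpec(1.2, "um", "luminal radius", "estimated from histology"),
    "r_E": ParamSpec(3.9, "um", "endothelial outer radius", "estimated from histology"),
    "l": ParamSpec(600.0, "km", "aggregate capillary length", "literature"),
    "J_max": ParamSpec(2.42, "pmol/(min.dm)",
                       "maximum p-gp efflux flux per unit capillary length",
                       "literature"),
    "K_M": ParamSpec(1.50, "uM", "Michaelis constant of p-gp efflux", "literature"),
    "C_M": ParamSpec(1.0, "uM", "brain-tissue (bath) concentration, held constant",
                     "literature"),
    "k_1": ParamSpec(0.01, "1/min",
                     "release rate of delphinidin from endothelial cytoplasm",
                     "literature"),
    "k_2": ParamSpec(0.035, "1/min", "p-gp uptake rate", "literature"),
    "k": ParamSpec(0.21, "umol/min",
                   "maximum transport rate due to p-gp pumping (unused: appears "
                   "in no model equation)", "literature"),
    "t_start": ParamSpec(0.0, "min", "integration start time", "nominal"),
    "t_stop": ParamSpec(20.0, "min", "integration stop time (transport model)",
                        "nominal"),
}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved parameter set in canonical units.

    ``provenance`` maps each key to ``default``/``file``/``cli``.
    ``deterministic`` asserts the run involves no randomness (the model has
    no stochastic component).
    """

    values: dict[str, float]
    provenance: dict[str, str]
    deterministic: bool = True

    @property
    def geometry(self) -> CapillaryGeometry:
        return derive_geometry(self.values["r_L"], self.values["r_E"], self.values["l"])

    @property
    def transport(self) -> TransportParameters:
        v = self.values
        return TransportParameters(
            D_LE_1=v["D_LE_1"], D_LE_2=v["D_LE_2"], D_EM=v["D_EM"],
            J_max=v["J_max"], K_M=v["K_M"], C_M=v["C_M"],
            t_start=v["t_start"], t_stop=v["t_stop"],
        )

    @property
    def release(self) -> ReleaseParameters:
        return ReleaseParameters(k_1=self.values["k_1"], k_2=self.values["k_2"])

    def printed(self) -> dict[str, float]:
        """Values converted back to their printed units (for display)."""
        from .units import from_canonical

        return {k: from_canonical(v, SCHEMA[k].unit) for k, v in self.values.items()}

    def metadata(self) -> dict[str, Any]:
        """Embeddable provenance block for output files."""
        return {
            "parameters_canonical": dict(self.values),
            "units": "um/min/amol/uM",
            "provenance": dict(self.provenance),
            "deterministic": self.deterministic,
        }


def _check_overrides(overrides: Mapping[str, Any], origin: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for key, value in overrides.items():
        if key not in SCHEMA:
            raise ConfigError(
                f"unknown parameter {key!r} in {origin}; valid keys: "
                f"{', '.join(SCHEMA)}"
            )
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(
                f"parameter {key!r} in {origin} must be a number in "
                f"{SCHEMA[key].unit}, got {value!r}"
            )
        out[key] = float(value)
    return out


def resolve_config(
    file_overrides: Mapping[str, Any] | None = None,
    cli_overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Merge defaults, file overrides and CLI overrides (CLI wins).

    Override values are interpreted in each parameter's printed unit and
    converted to canonical units here.  The resolved configuration is
    logged before any computation uses it.
    """
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    file_ov = _check_overrides(file_overrides or {}, "config file")
    cli_ov = _check_overrides(cli_overrides or {}, "command line")
    for key, spec in SCHEMA.items():
        if key in cli_ov:
            printed, origin = cli_ov[key], "cli"
        elif key in file_ov:
            printed, origin = file_ov[key], "file"
        else:
            printed, origin = spec.default, "default"
        values[key] = to_canonical(printed, spec.unit)
        provenance[key] = origin
    cfg = RunConfig(values=values, provenance=provenance)
    log.info(
        "resolved configuration: %s",
        ", ".join(
            f"{k}={cfg.printed()[k]:g} {SCHEMA[k].unit} ({provenance[k]})"
            for k in SCHEMA
        ),
    )
    return cfg


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON override file into a flat key→number mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping of parameters")
    return data
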