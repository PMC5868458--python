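"""Deterministic writers for trajectories, metrics and annotated graphs.

CSV columns are written in a fixed order with full-precision decimal text;
JSON is written with sorted keys.  Two runs with the same configuration
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np

from .config import RunConfig
from .simulate import SimulationResult

__all__ = ["write_result", "write_metrics_json", "write_annotated_graph", "read_trajectory"]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_result(
    result: SimulationResult,
    csv_path: str | Path | None = None,
    metrics_path: str | Path | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write the trajectory CSV and/or the metrics JSON.

    The metrics document embeds the resolved configuration provenance
    block when a :class:`~bbbsim.config.RunConfig` is supplied.
    """
    if csv_path is not None:
        frame = result.to_frame()
        cols = ["t_min"] + list(result.series)
        # repr-roundtrip float text: full precision, deterministic
        frame.to_csv(csv_path, index=False, columns=cols)
    if metrics_path is not None:
        write_metrics_json(result, metrics_path, config=config)


def write_metrics_json(
    result: SimulationResult,
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    doc: dict[str, Any] = {
        "mode": result.mode,
        "metrics": _jsonable(result.metrics),
    }
    if config is not None:
        doc["config"] = _jsonable(config.metadata())
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_annotated_graph(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def read_trajectory(path: str | Path):
    """Read back a trajectory CSV into a DataFrame (full precision)."""
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")
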