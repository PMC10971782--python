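"""File I/O: edge lists, GraphML, and result serialisation.

Edge-list format: one edge per line, two whitespace-separated 0-based
integer node ids; blank lines and ``#`` comments allowed.  Parse errors
carry the offending line number.  All stochastic results are written with
their resolved configuration and seed embedded, so a run can be
reproduced from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import validate_graph

__all__ = [
    "read_graph",
    "write_graph",
    "read_edgelist",
    "write_edgelist",
    "write_json",
    "read_json",
    "trajectories_to_csv",
]


def read_edgelist(path) -> nx.Graph:
    path = Path(path)
    g = nx.Graph()
    seen = set()
    max_node = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids, got {raw.strip()!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: node ids must be integers") from None
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: node ids must be non-negative")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate edge {key}")
            seen.add(key)
            g.add_edge(u, v)
            max_node = max(max_node, u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    # make ids contiguous (isolated intermediate ids are not representable
    # in an edge list anyway)
    g.add_nodes_from(range(max_node + 1))
    if set(g.nodes) != set(range(g.number_of_nodes())):
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    return validate_graph(g)


def write_edgelist(g: nx.Graph, path, comment: str | None = None) -> None:
    validate_graph(g)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges):
            fh.write(f"{u} {v}\n")


def read_graph(path, fmt: str | None = None) -> nx.Graph:
    """Read a graph, inferring the format from the suffix unless given."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edgelist")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {u: int(u) for u in g.nodes})
        if set(g.nodes) != set(range(g.number_of_nodes())):
            g = nx.convert_node_labels_to_integers(g, ordering="sorted")
        return validate_graph(nx.Graph(g))
    if fmt == "edgelist":
        return read_edgelist(path)
    raise ValueError("format must be 'edgelist' or 'graphml'")


def write_graph(g: nx.Graph, path, fmt: str | None = None, comment: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "edgelist")
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        write_edgelist(g, path, comment=comment)
    else:
        raise ValueError("format must be 'edgelist' or 'graphml'")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    return obj


def write_json(result, path, config: dict | None = None, seed=None) -> None:
    """Write a result (dataclass or dict) as JSON with config and seed embedded."""
    payload = {"result": _jsonable(result)}
    if config is not None:
        payload["config"] = _jsonable(config)
    if seed is not None:
        payload["seed"] = int(seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def trajectories_to_csv(trajectories, path) -> None:
    """Frequency or optimization trajectories as tidy CSV."""
    frames = []
    for i, traj in enumerate(trajectories):
        if hasattr(traj, "p_a"):  # Moran TrajectoryRecord
            frames.append(pd.DataFrame({
                "replicate": i,
                "time": traj.times,
                "p_a": traj.p_a,
                "p_Aa": traj.p_Aa,
                "p_AA": traj.p_AA,
                "p_aa": traj.p_aa,
            }))
        else:  # OptTrajectory
            frames.append(pd.DataFrame({
                "replicate": getattr(traj, "replicate", i),
                "events": traj.times,
                "mean_value": traj.mean_values,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
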