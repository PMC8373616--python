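"""File round-tripping: graphs (DOT, GraphML), model specs (YAML/JSON),
trajectories (CSV + JSON sidecar), groupings (CSV) and reports (JSON).

All formats are plain text and versioned so a run can be reconstructed from
its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graph import DependencyGraph, StateNode

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Trajectory

SPEC_SCHEMA = "neuroblankets-model-spec/1"
REPORT_SCHEMA = "neuroblankets-report/1"

_ID_RE = r'"((?:[^"\\]|\\.)*)"'
_ATTR_RE = re.compile(r'(\w+)\s*=\s*"((?:[^"\\]|\\.)*)"')
_NODE_RE = re.compile(rf"^\s*{_ID_RE}\s*(?:\[(.*)\])?\s*;\s*$")
_EDGE_RE = re.compile(rf"^\s*{_ID_RE}\s*->\s*{_ID_RE}\s*(?:\[(.*)\])?\s*;\s*$")


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _dot_unescape(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def write_dot(graph: DependencyGraph, path: str | Path) -> None:
    """Write the graph as GraphViz DOT with role/scale/group/sign attributes."""
    lines = ["digraph dependency {"]
    for node_id in sorted(graph.node_ids):
        node = graph.nodes[node_id]
        attrs = [f'role="{node.role}"', f'scale="{node.scale}"']
        if node.group is not None:
            attrs.append(f'group="{_dot_escape(node.group)}"')
        lines.append(f'  "{_dot_escape(node_id)}" [{", ".join(attrs)}];')
    for u, v in sorted(graph.edges):
        sign = graph.signs.get((u, v), "unsigned")
        lines.append(f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}" [sign="{sign}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dot(path: str | Path) -> DependencyGraph:
    """Read a DOT file produced by :func:`write_dot` (covers that subset)."""
    graph = DependencyGraph()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("digraph", "}")):
            continue
        m = _EDGE_RE.match(line)
        if m:
            u, v, attr_str = m.group(1), m.group(2), m.group(3) or ""
            attrs = {k: _dot_unescape(val) for k, val in _ATTR_RE.findall(attr_str)}
            graph.add_edge(_dot_unescape(u), _dot_unescape(v),
                           sign=attrs.get("sign", "unsigned"))
            continue
        m = _NODE_RE.match(line)
        if m:
            node_id, attr_str = m.group(1), m.group(2) or ""
            attrs = {k: _dot_unescape(val) for k, val in _ATTR_RE.findall(attr_str)}
            graph.add_node(
                StateNode(
                    _dot_unescape(node_id),
                    role=attrs.get("role", "unassigned"),
                    scale=int(attrs.get("scale", 0)),
                    group=attrs.get("group"),
                )
            )
            continue
        raise ValueError(f"unparseable DOT line: {raw!r}")
    return graph


def write_graphml(graph: DependencyGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def read_graphml(path: str | Path) -> DependencyGraph:
    return DependencyGraph.from_networkx(nx.read_graphml(str(path)))


# -- model specs -----------------------------------------------------------

def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def model_spec_hash(spec: Mapping) -> str:
    """Stable content hash of a model spec (sha256 of canonical JSON)."""
    return hashlib.sha256(_canonical(spec).encode()).hexdigest()


def write_model_spec(spec: Mapping, path: str | Path) -> None:
    path = Path(path)
    spec = dict(spec)
    spec.setdefault("spec_schema", SPEC_SCHEMA)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(spec, sort_keys=True))


def read_model_spec(path: str | Path):
    path = Path(path)
    text = path.read_text()
    spec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(spec, dict) or "type" not in spec:
        raise ValueError(f"{path} is not a model spec (missing 'type')")
    return spec


# -- trajectories ----------------------------------------------------------

def write_trajectory(traj: "Trajectory", path: str | Path) -> None:
    """CSV (time column + one column per state) plus a JSON sidecar with
    seed, dt, integrator and model hash for bit-identical regeneration."""
    path = Path(path)
    frame = traj.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "seed": traj.seed,
        "dt": traj.dt,
        "integrator": traj.integrator,
        "model": traj.model_name,
        "model_hash": traj.model_hash,
        "state_labels": list(traj.state_labels),
        "input_labels": list(traj.input_labels),
        "n_steps": int(len(traj.times) - 1),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_trajectory_frame(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return frame, meta


# -- groupings -------------------------------------------------------------

def write_grouping(mapping: Mapping[str, str], path: str | Path) -> None:
    """Two-column CSV: micro node id, macro unit label."""
    frame = pd.DataFrame(
        sorted(mapping.items()), columns=["micro_id", "macro_label"]
    )
    frame.to_csv(path, index=False)


def read_grouping(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    if list(frame.columns) != ["micro_id", "macro_label"]:
        raise ValueError(
            f"grouping file {path} must have columns micro_id,macro_label"
        )
    return dict(zip(frame["micro_id"], frame["macro_label"]))


# -- reports ---------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    report = dict(_jsonable(report))
    report.setdefault("report_schema", REPORT_SCHEMA)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
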