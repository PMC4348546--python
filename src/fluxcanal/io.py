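"""File exchange: orientations (GraphML/DOT), states, trajectories, reports.

Formats are deliberately boring: GraphML (via networkx) and DOT for graphs,
tidy CSV for trajectories, JSON for states, reports and manifests.  Node
attribute ``a`` carries steady auxin; edge attributes ``p`` and ``J`` carry
membrane PIN and flux.
"""

from __future__ import annotations

import hashlib
import json
import platform
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import SimulationResult
from .model import ConfigurationError, State, TissueGraph
from .steady_state import ChainSolution, OrientedSubgraph, TopologyReport

__all__ = [
    "export_orientation",
    "import_orientation",
    "write_state",
    "read_state",
    "write_trajectory",
    "report",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Orientation graphs
# ---------------------------------------------------------------------------

def export_orientation(g: OrientedSubgraph, path: str | Path,
                       format: str = "graphml") -> Path:
    """Write an orientation with its a/p/J attributes; returns the path."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g.to_networkx(), path)
    elif format == "dot":
        path.write_text(_to_dot(g))
    else:
        raise ConfigurationError(f"unsupported orientation format {format!r}")
    return path


def import_orientation(path: str | Path, format: str = "graphml") -> OrientedSubgraph:
    """Read an orientation written by :func:`export_orientation`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        dg = nx.DiGraph()
        dg.add_nodes_from((int(v), data) for v, data in g.nodes(data=True))
        dg.add_edges_from((int(u), int(v), data) for u, v, data in g.edges(data=True))
        return OrientedSubgraph.from_networkx(dg)
    if format == "dot":
        return _from_dot(path.read_text())
    raise ConfigurationError(f"unsupported orientation format {format!r}")


def _to_dot(g: OrientedSubgraph) -> str:
    lines = ["digraph orientation {"]
    for i in range(g.n_cells):
        attrs = f' [a="{float(g.a[i])!r}"]' if g.a is not None else ""
        lines.append(f"  {i}{attrs};")
    for (i, j) in g.edges:
        parts = []
        if (i, j) in g.p:
            parts.append(f'p="{float(g.p[(i, j)])!r}"')
        if (i, j) in g.J:
            parts.append(f'J="{float(g.J[(i, j)])!r}"')
        attr = f" [{', '.join(parts)}]" if parts else ""
        lines.append(f"  {i} -> {j}{attr};")
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_NODE = re.compile(r"^\s*(\d+)\s*(?:\[a=\"([^\"]*)\"\])?\s*;")
_DOT_EDGE = re.compile(
    r"^\s*(\d+)\s*->\s*(\d+)\s*(?:\[p=\"([^\"]*)\"(?:,\s*J=\"([^\"]*)\")?\])?\s*;")


def _from_dot(text: str) -> OrientedSubgraph:
    nodes, a_vals, edges, p, J = [], {}, [], {}, {}
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            edges.append((i, j))
            if m.group(3) is not None:
                p[(i, j)] = float(m.group(3))
            if m.group(4) is not None:
                J[(i, j)] = float(m.group(4))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.append(int(m.group(1)))
            if m.group(2) is not None:
                a_vals[int(m.group(1))] = float(m.group(2))
    n = max(nodes) + 1 if nodes else 0
    a = None
    if len(a_vals) == n and n:
        a = np.array([a_vals[i] for i in range(n)])
    return OrientedSubgraph(n, edges, a=a, p=p, J=J)


# ---------------------------------------------------------------------------
# States and trajectories
# ---------------------------------------------------------------------------

def write_state(state: State, path: str | Path) -> Path:
    path = Path(path)
    doc = {"a": state.a.tolist(), "p": state.p.tolist()}
    if state.P is not None:
        doc["P"] = state.P.tolist()
    path.write_text(json.dumps(doc))
    return path


def read_state(path: str | Path) -> State:
    doc = json.loads(Path(path).read_text())
    return State(np.asarray(doc["a"]), np.asarray(doc["p"]),
                 np.asarray(doc["P"]) if "P" in doc else None)


def write_trajectory(result: SimulationResult, path: str | Path) -> Path:
    """Tidy CSV (time, variable, value) of the stored trajectory."""
    path = Path(path)
    result.trajectory_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Reports and manifests
# ---------------------------------------------------------------------------

def report(result: SimulationResult, topology: TopologyReport | None = None,
           chain: ChainSolution | None = None) -> tuple[str, dict]:
    """Human-readable summary plus its machine twin."""
    fs = result.final_state
    doc = {
        "variant": result.variant,
        "status": result.status,
        "t_end": float(result.times[-1]),
        "rhs_norm_final": result.diagnostics.get("rhs_norm_final"),
        "auxin_min": float(fs.a.min()),
        "auxin_max": float(fs.a.max()),
        "membrane_pin_max": float(fs.p.max(initial=0.0)),
    }
    if result.escape_time is not None:
        doc["escape_time"] = float(result.escape_time)
    if topology is not None:
        doc["topology"] = {
            "sinks": list(topology.sinks),
            "sources": list(topology.sources),
            "has_cycle": topology.has_cycle,
            "is_sink_rooted_forest": topology.is_sink_rooted_forest,
            "verdict": topology.verdict,
        }
    if chain is not None:
        doc["regime"] = chain.regime
        doc["chain"] = chain.to_dict()

    lines = [
        f"variant: {doc['variant']}",
        f"status:  {doc['status']} (t_end = {doc['t_end']:g}, "
        f"||rhs||_inf = {doc['rhs_norm_final']:.3g})",
        f"auxin:   min {doc['auxin_min']:.6g}, max {doc['auxin_max']:.6g}",
        f"PIN:     max membrane concentration {doc['membrane_pin_max']:.6g}",
    ]
    if "escape_time" in doc:
        lines.append(f"escape:  finite-time divergence, delta ~ {doc['escape_time']:.6g}")
    if topology is not None:
        t = doc["topology"]
        lines.append(
            f"orientation: {len(t['sinks'])} sink(s), {len(t['sources'])} source(s), "
            f"cycle={t['has_cycle']}, sink-rooted forest={t['is_sink_rooted_forest']}, "
            f"verdict={t['verdict']}")
    if chain is not None:
        lines.append(f"vein regime: {chain.regime}"
                     + (" (degenerate)" if chain.degenerate else ""))
    return "\n".join(lines) + "\n", doc


def write_manifest(path: str | Path, config_doc: dict, seed: int | None) -> Path:
    """Reproducibility manifest: config hash, seed and library versions."""
    import scipy

    canonical = json.dumps(config_doc, sort_keys=True)
    doc = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "networkx": nx.__version__,
        "pandas": pd.__version__,
    }
    from . import __version__
    doc["fluxcanal"] = __version__
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path
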