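"""Programmatic construction of tissues, parameter sets and study scenarios.

Every scenario studied with this package is built here from printed
parameters — no external data.  The three named scenarios correspond to the
canonical numerical experiments for the flux model:

* ``scenario_grid_patches`` — a regular 8 x 11 grid (88 cells) with uniform
  auxin production 0.1 except two 3-cell patches producing at 2.1;
  ``beta_a = 5``, ``lam = 5``, ``mu = 0.1``, quadratic response.  Converged
  states are sink-rooted forests.  A diffusive variant adds a small
  normalized diffusion rate (0.001) on a non-regular (jittered) grid.
* ``scenario_sink_line`` — a 20-cell line in which only cell index 9 degrades
  auxin (rate 0.1); all cells produce at 0.1.  The production rate and the
  PIN-cycling rates are not printed for this experiment and are recorded as
  assumptions in the scenario metadata.  Trajectories oscillate around the
  in-tree equilibrium rather than converging.
* ``scenario_source_line`` — a 20-cell open line with a source at cell 0:
  ``alpha = beta = 0.1`` everywhere, ``lam = mu = 0.01`` (so ``c = 1``), and
  source production 0.9 (``"low_source"`` — canal above background, regime A)
  or 3.1 (``"high_source"`` — canal below background, regime B).

Initial conditions: auxin starts at its uncoupled fixed point
``alpha_a/beta_a`` (0 where ``beta_a = 0``) and membrane PIN at a small
homogeneous load with 1% seeded jitter.  The zero-PIN configuration is
asymptotically stable for the quadratic response, so a strictly zero (or
infinitesimally jittered) initial PIN can never canalize: the load is sized
from the nucleation threshold ``p > 1/(c a^2)`` of membranes adjacent to the
auxin source so that those membranes — and only those — can escape the basin
of the all-isolated state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import ModelParams, ResponseFunction, State, StructuralError, TissueGraph
from .steady_state import OrientedSubgraph

__all__ = [
    "Scenario",
    "make_grid",
    "make_line",
    "scenario_grid_patches",
    "scenario_sink_line",
    "scenario_source_line",
    "random_in_tree",
    "tissue_from_orientation",
    "random_state",
]


@dataclass
class Scenario:
    """A named, self-contained study condition."""

    name: str
    variant: str
    tissue: TissueGraph
    params: ModelParams
    phi: ResponseFunction
    pin_init: float = 0.1            # homogeneous initial membrane PIN load
    jitter: float = 0.01             # relative seeded jitter on that load
    init_kind: str = "uncoupled"     # or "near_tree_equilibrium"
    expected: str = ""               # qualitative outcome tag used by tests
    metadata: dict = field(default_factory=dict)

    def initial_state(self, seed: int | None = None) -> State:
        """Seeded initial state.

        ``init_kind="uncoupled"`` (default): auxin at its uncoupled fixed
        point ``alpha_a/beta_a`` (0 where degradation vanishes), membrane PIN
        at the homogeneous load ``pin_init`` with 1% uniform jitter (symmetry
        breaking).  ``init_kind="near_tree_equilibrium"``: the exact
        sink-rooted in-tree steady state (requires ``metadata["sink"]``)
        jittered by 1% — used where the object of study is the fate of that
        equilibrium.
        """
        rng = np.random.default_rng(seed)
        if self.init_kind == "near_tree_equilibrium":
            from .steady_state import sink_tree_state
            base = sink_tree_state(
                self._sink_tree(), self.tissue,
                self.params.cell_rates(self.tissue)[0], self.params.c,
                float(np.max(self.params.cell_rates(self.tissue)[1])))
            a = base.a * (1.0 + self.jitter * rng.uniform(-1.0, 1.0, base.a.size))
            p = base.p * (1.0 + self.jitter * rng.uniform(-1.0, 1.0, base.p.size))
            return State(np.maximum(a, 0.0), np.maximum(p, 0.0))
        alpha, beta = self.params.cell_rates(self.tissue)
        a = np.where(beta > 0, alpha / np.where(beta > 0, beta, 1.0), 0.0)
        p = self.pin_init * (1.0 + self.jitter * rng.uniform(-1.0, 1.0, 2 * self.tissue.n_edges))
        P = None
        if self.variant == "extended":
            P = np.full(self.tissue.n_cells, self.params.pin_pool)
        return State(a, np.maximum(p, 0.0), P)

    def _sink_tree(self):
        """BFS in-tree of the tissue oriented toward ``metadata['sink']``."""
        import networkx as nx

        from .steady_state import OrientedSubgraph
        sink = self.metadata["sink"]
        g = self.tissue.to_networkx()
        parent = dict(nx.bfs_predecessors(g, sink))
        return OrientedSubgraph(self.tissue.n_cells,
                                [(int(c), int(p)) for c, p in parent.items()])

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "variant": self.variant,
            "tissue": self.tissue.to_dict(),
            "params": self.params.to_dict(),
            "response": self.phi.to_dict(),
            "pin_init": self.pin_init,
            "jitter": self.jitter,
            "init_kind": self.init_kind,
            "expected": self.expected,
            "metadata": self.metadata,
        }

    @classmethod
    def from_config(cls, doc: dict) -> "Scenario":
        return cls(
            name=doc["name"],
            variant=doc["variant"],
            tissue=TissueGraph.from_dict(doc["tissue"]),
            params=ModelParams.from_dict(doc["params"]),
            phi=ResponseFunction.from_dict(doc["response"]),
            pin_init=doc.get("pin_init", 0.1),
            jitter=doc.get("jitter", 0.01),
            init_kind=doc.get("init_kind", "uncoupled"),
            expected=doc.get("expected", ""),
            metadata=doc.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# Tissues
# ---------------------------------------------------------------------------

def make_grid(rows: int, cols: int, regular: bool = True,
              seed: int | None = None) -> TissueGraph:
    """Four-neighbour lattice of ``rows x cols`` cells, no periodic wrap.

    ``regular=False`` jitters volumes and membrane areas by +-10% (seeded),
    producing a grid of non-regular cells.
    """
    if rows < 1 or cols < 1:
        raise StructuralError("grid needs at least one row and one column")
    n = rows * cols

    def idx(r, c):
        return r * cols + c

    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((idx(r, c), idx(r, c + 1)))
            if r + 1 < rows:
                edges.append((idx(r, c), idx(r + 1, c)))
    volumes = areas = None
    if not regular:
        rng = np.random.default_rng(seed)
        volumes = 1.0 + 0.1 * rng.uniform(-1.0, 1.0, n)
        areas = 1.0 + 0.1 * rng.uniform(-1.0, 1.0, len(edges))
    return TissueGraph(n, edges, volumes, areas)


def make_line(L: int, periodic: bool = False) -> TissueGraph:
    """Path graph of L cells; ``periodic=True`` closes it into a ring."""
    if L < 2:
        raise StructuralError("a line needs at least two cells")
    edges = [(i, i + 1) for i in range(L - 1)]
    if periodic:
        edges.append((0, L - 1))
    return TissueGraph(L, edges)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

def scenario_grid_patches(diffusive: bool = False, seed: int | None = 0,
                          patch_rows: tuple[int, int] = (2, 5),
                          patch_cols: tuple[int, int, int] = (3, 4, 5)) -> Scenario:
    """Heterogeneous-production grid: 8 x 11 cells, two 3-cell patches.

    Background production 0.1, patch production 2.1, ``beta_a = 5``,
    ``lam = 5``, ``mu = 0.1`` in every cell; quadratic response;
    cytosolic PIN pool normalized to 1 (so ``c = lam/mu = 50``).  Patch
    placement is not uniquely determined by the printed description ("two
    groups of 3 cells"); the default places two horizontal 3-cell runs and is
    configurable — downstream assertions should be topological, not
    position-sensitive.

    ``diffusive=True`` switches to the full model on a non-regular grid with
    normalized diffusion 0.001 (the robustness variant of the experiment).
    """
    rows, cols = 8, 11
    tissue = make_grid(rows, cols, regular=not diffusive, seed=seed)
    alpha = np.full(rows * cols, 0.1)
    patches = [r * cols + c for r in patch_rows for c in patch_cols]
    alpha[patches] = 2.1
    lam, mu = 5.0, 0.1
    if diffusive:
        params = ModelParams(alpha_a=alpha, beta_a=5.0, gamma_D=0.001, gamma_A=1.0,
                             rho0=0.0, mu=mu, lam=lam, alpha_p=1.0, beta_p=1.0)
        variant = "full"
        # full-model insertion h(J) matches the slow limit's lam*(alpha_p/beta_p)*Phi
        phi = ResponseFunction.quadratic(kappa=lam)
    else:
        params = ModelParams(alpha_a=alpha, beta_a=5.0, gamma_D=0.0, gamma_A=1.0,
                             mu=mu, lam=lam, alpha_p=1.0, beta_p=1.0)
        variant = "slow"
        phi = ResponseFunction.quadratic()
    return Scenario(
        name="grid_patches" + ("_diffusive" if diffusive else ""),
        variant=variant, tissue=tissue, params=params, phi=phi,
        pin_init=0.3, jitter=0.01,
        expected="sink_rooted_forest",
        metadata={
            "patch_cells": patches,
            "assumptions": [
                "patch placement: two horizontal 3-cell runs (configurable)",
                "cytosolic PIN pool alpha_p/beta_p = 1",
                "initial membrane PIN load 0.3 (above the patch-membrane "
                "nucleation threshold 1/(c a_patch^2) ~ 0.11)",
            ],
        },
    )


def scenario_sink_line(L: int = 20, sink: int = 9) -> Scenario:
    """Sink-driven line: only the sink cell degrades auxin.

    ``beta_a = 0.1`` at the sink, 0 elsewhere; uniform production 0.1
    (assumption — not printed); quadratic response; ``lam = mu = 0.02`` so
    ``c = 1`` (assumption).  The run starts at the exact spanning in-tree
    steady state with 1% jitter: that equilibrium is linearly unstable here
    with a complex leading eigenvalue, so the trajectory develops sustained
    auxin oscillations around it instead of converging.
    """
    tissue = make_line(L)
    beta = np.zeros(L)
    beta[sink] = 0.1
    params = ModelParams(alpha_a=0.1, beta_a=beta, mu=0.02, lam=0.02,
                         alpha_p=1.0, beta_p=1.0)
    return Scenario(
        name="sink_line", variant="slow", tissue=tissue, params=params,
        phi=ResponseFunction.quadratic(), pin_init=0.1, jitter=0.01,
        init_kind="near_tree_equilibrium",
        expected="oscillating",
        metadata={
            "sink": sink,
            "assumptions": [
                "uniform alpha_a = 0.1 (not printed)",
                "lam = mu = 0.02, cytosolic pool 1 (c = 1; not printed): "
                "chosen so the in-tree equilibrium loses stability through a "
                "complex (oscillatory) mode",
            ],
        },
    )


def scenario_source_line(kind: str = "low_source", L: int = 20) -> Scenario:
    """Source-driven open line of L cells with the source at cell 0.

    ``alpha = beta = 0.1`` in every cell, ``lam = mu = 0.01`` (``c = 1``),
    quadratic response.  ``kind`` selects the source production rate:
    ``"low_source"`` -> 0.9 (regime A: canal above background, flux with the
    auxin gradient), ``"high_source"`` -> 3.1 (regime B: canal below
    background, flux against the gradient), ``"background"`` -> 0.1 (control:
    homogeneous production, relaxes to the all-isolated state).
    """
    rates = {"low_source": 0.9, "high_source": 3.1, "background": 0.1}
    if kind not in rates:
        raise StructuralError(f"unknown source-line kind {kind!r}")
    tissue = make_line(L)
    alpha = np.full(L, 0.1)
    alpha[0] = rates[kind]
    params = ModelParams(alpha_a=alpha, beta_a=0.1, mu=0.01, lam=0.01,
                         alpha_p=1.0, beta_p=1.0)
    expected = {"low_source": "regime_A", "high_source": "regime_B",
                "background": "all_isolated"}[kind]
    return Scenario(
        name=f"source_line_{kind}", variant="slow", tissue=tissue,
        params=params, phi=ResponseFunction.quadratic(),
        pin_init=0.1, jitter=0.01, expected=expected,
        metadata={"source": 0, "alpha0": rates[kind], "background": 1.0},
    )


# ---------------------------------------------------------------------------
# Random generators for property tests
# ---------------------------------------------------------------------------

def random_in_tree(n_nodes: int, seed: int | None = None) -> OrientedSubgraph:
    """Uniformly random rooted in-tree on ``n_nodes`` labelled nodes.

    Sampled via a random Pruefer sequence (uniform over labelled trees) with
    a uniformly chosen root; every non-root node has out-degree exactly one
    along its path to the root.  Deterministic for a given seed.
    """
    if n_nodes < 1:
        raise StructuralError("need at least one node")
    rng = np.random.default_rng(seed)
    if n_nodes == 1:
        return OrientedSubgraph(1, [])
    if n_nodes == 2:
        und = [(0, 1)]
    else:
        prufer = rng.integers(0, n_nodes, size=n_nodes - 2)
        degree = np.ones(n_nodes, dtype=int)
        for v in prufer:
            degree[v] += 1
        und = []
        import heapq
        leaves = [i for i in range(n_nodes) if degree[i] == 1]
        heapq.heapify(leaves)
        for v in prufer:
            leaf = heapq.heappop(leaves)
            und.append((leaf, int(v)))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, int(v))
        u, w = heapq.heappop(leaves), heapq.heappop(leaves)
        und.append((u, w))
    root = int(rng.integers(0, n_nodes))
    # orient every undirected tree edge toward the root
    import networkx as nx
    g = nx.Graph(und)
    directed = []
    parent = dict(nx.bfs_predecessors(g, root))
    for child, par in parent.items():
        directed.append((int(child), int(par)))
    return OrientedSubgraph(n_nodes, directed)


def tissue_from_orientation(g: OrientedSubgraph) -> TissueGraph:
    """Regular tissue whose adjacency is the undirected support of ``g``."""
    return TissueGraph(g.n_cells, [(min(i, j), max(i, j)) for i, j in g.edges])


def random_state(tissue: TissueGraph, seed: int | None = None,
                 scale: float = 1.0, with_cytosol: bool = False) -> State:
    """Nonnegative uniform random state, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return State(
        a=scale * rng.uniform(0.0, 1.0, tissue.n_cells),
        p=scale * rng.uniform(0.0, 1.0, 2 * tissue.n_edges),
        P=scale * rng.uniform(0.0, 1.0, tissue.n_cells) if with_cytosol else None,
    )
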