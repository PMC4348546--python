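"""Steady-state structure of the flux model: orientations, stability, veins.

Because the response function is rectified, any equilibrium of the slow model
satisfies a *complementarity* condition on every membrane: at least one of
``p*_ij, p*_ji`` vanishes.  Reading off the nonzero directions turns each
steady state into an oriented subgraph G* of the tissue, whose topology
carries the stability information:

* an equilibrium whose orientation has **no sink**, **a directed cycle** or a
  cell of **out-degree > 1** is linearly unstable (quadratic response);
* every stable equilibrium therefore sits on a forest of trees directed from
  leaves to roots (sink-rooted forest).

The necessary-condition check never certifies stability; spectral claims are
made only from the numerically computed Jacobian.

Closed forms are provided for the two biologically distinguished regimes:

* **sink-driven** (a single degrading cell): the orientation is a spanning
  in-tree rooted at the sink and ``a_i = 1 / (c * alpha_a(i))`` for non-root
  cells, where ``alpha_a(i)`` is the total production of the subtree draining
  through ``i`` — auxin *decreases* along every path into the sink;
* **source-driven** (a single over-producing cell): the vein is a linear
  chain; auxin along it is either everywhere above background and increasing
  (regime A, weak sources) or below background and decreasing (regime B,
  strong sources), the terminal sink cell excepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import eigvals
from scipy.optimize import root

from .model import (
    FluxModelError,
    ModelParams,
    ResponseFunction,
    State,
    StructuralError,
    TissueGraph,
    make_rhs,
    rhs_slow,
)

__all__ = [
    "ComplementarityError",
    "OrientedSubgraph",
    "TopologyReport",
    "ChainSolution",
    "extract_orientation",
    "classify_topology",
    "jacobian_stability",
    "construct_equilibrium",
    "solve_sink_tree",
    "solve_source_chain",
    "classify_regime",
    "regime_map",
]


class ComplementarityError(FluxModelError):
    """Both membrane directions carry PIN: not a valid slow-model equilibrium."""

    def __init__(self, offending):
        self.offending = offending
        super().__init__(
            "not a valid slow-model equilibrium orientation; membranes with "
            f"PIN in both directions: {offending}")


# ---------------------------------------------------------------------------
# Orientation graphs
# ---------------------------------------------------------------------------

@dataclass
class OrientedSubgraph:
    """Directed subgraph read off a steady state (i -> j iff p*_ij > tol)."""

    n_cells: int
    edges: list[tuple[int, int]]
    isolated: set[int] = field(default_factory=set)
    a: np.ndarray | None = None              # steady auxin per cell, if known
    p: dict[tuple[int, int], float] = field(default_factory=dict)
    J: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        seen_und = set()
        for i, j in self.edges:
            if i == j:
                raise StructuralError("self edge in orientation")
            und = (min(i, j), max(i, j))
            if und in seen_und:
                raise StructuralError(f"both directions present on membrane {und}")
            seen_und.add(und)
        connected = {v for e in self.edges for v in e}
        self.isolated = set(range(self.n_cells)) - connected

    @property
    def retained(self) -> set[int]:
        """V* = V minus the isolated cells."""
        return set(range(self.n_cells)) - self.isolated

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_cells))
        if self.a is not None:
            for i in range(self.n_cells):
                g.nodes[i]["a"] = float(self.a[i])
        for e in self.edges:
            attrs = {}
            if e in self.p:
                attrs["p"] = float(self.p[e])
            if e in self.J:
                attrs["J"] = float(self.J[e])
            g.add_edge(*e, **attrs)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "OrientedSubgraph":
        n = g.number_of_nodes()
        edges = [(int(i), int(j)) for i, j in g.edges]
        a = None
        if all("a" in g.nodes[i] for i in g.nodes) and n:
            a = np.array([float(g.nodes[i]["a"]) for i in sorted(g.nodes)])
        p = {e: float(g.edges[e]["p"]) for e in g.edges if "p" in g.edges[e]}
        J = {e: float(g.edges[e]["J"]) for e in g.edges if "J" in g.edges[e]}
        return cls(n, edges, a=a, p=p, J=J)


@dataclass(frozen=True)
class TopologyReport:
    """Degree structure of an orientation and its necessary-condition verdict.

    ``verdict`` is ``"certified_unstable"`` when the orientation has no sink,
    a directed cycle, or a cell with out-degree > 1 — each of which rules out
    linear stability for the quadratic response.  Otherwise the verdict is
    ``"necessary_conditions_met"``, which is *not* a stability certificate.
    """

    in_degree: tuple[int, ...]
    out_degree: tuple[int, ...]
    sinks: tuple[int, ...]
    sources: tuple[int, ...]
    has_cycle: bool
    is_sink_rooted_forest: bool
    verdict: str


def extract_orientation(state: State, tissue: TissueGraph,
                        tol: float | None = None) -> OrientedSubgraph:
    """Orientation of an (approximate) slow-model equilibrium.

    ``tol`` defaults to ``1e-6 * max(1, max p)`` — relative, so the extraction
    survives unit rescaling.  Membranes with PIN above tolerance in both
    directions violate equilibrium complementarity and raise
    :class:`ComplementarityError`.
    """
    state.check(tissue, "slow", nonnegative=False)
    p = state.p
    if tol is None:
        tol = 1e-6 * max(1.0, float(p.max(initial=0.0)))
    edges, pmap, Jmap, offending = [], {}, {}, []
    for e in range(tissue.n_edges):
        i, j = (int(v) for v in tissue.edges[e])
        pij, pji = float(p[2 * e]), float(p[2 * e + 1])
        if pij > tol and pji > tol:
            offending.append((i, j))
        elif pij > tol:
            edges.append((i, j))
            pmap[(i, j)] = pij
            Jmap[(i, j)] = float(state.a[i] * pij - state.a[j] * pji)
        elif pji > tol:
            edges.append((j, i))
            pmap[(j, i)] = pji
            Jmap[(j, i)] = float(state.a[j] * pji - state.a[i] * pij)
    if offending:
        raise ComplementarityError(offending)
    return OrientedSubgraph(tissue.n_cells, edges, a=state.a.copy(), p=pmap, J=Jmap)


def classify_topology(g: OrientedSubgraph) -> TopologyReport:
    """Degrees, sinks/sources, cycles and the instability verdict of G*."""
    dg = g.to_networkx()
    indeg = tuple(dg.in_degree(i) for i in range(g.n_cells))
    outdeg = tuple(dg.out_degree(i) for i in range(g.n_cells))
    sinks = tuple(i for i in range(g.n_cells) if outdeg[i] == 0 and indeg[i] > 0)
    sources = tuple(i for i in range(g.n_cells) if indeg[i] == 0 and outdeg[i] > 0)
    has_cycle = not nx.is_directed_acyclic_graph(dg)
    forest = (not has_cycle) and all(d <= 1 for d in outdeg)
    nonempty = len(g.edges) > 0
    if nonempty and (len(sinks) == 0 or has_cycle or any(d > 1 for d in outdeg)):
        verdict = "certified_unstable"
    else:
        verdict = "necessary_conditions_met"
    return TopologyReport(indeg, outdeg, sinks, sources, has_cycle, forest, verdict)


# ---------------------------------------------------------------------------
# Spectral stability
# ---------------------------------------------------------------------------

def _fd_jacobian(fun, y, rel_step=1e-7):
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    f0 = np.asarray(fun(0.0, y))
    for k in range(n):
        h = rel_step * max(1.0, abs(y[k]))
        yp = y.copy(); yp[k] += h
        ym = y.copy(); ym[k] -= h
        J[:, k] = (np.asarray(fun(0.0, yp)) - np.asarray(fun(0.0, ym))) / (2 * h)
    return J, f0


def jacobian_stability(variant: str, tissue: TissueGraph, params: ModelParams,
                       phi: ResponseFunction, equilibrium: State,
                       tol_eig: float = 1e-6, tol_eq: float = 1e-6):
    """Classify an equilibrium by the spectrum of the finite-difference Jacobian.

    Returns ``(label, spectrum)`` with label ``"stable"`` when all eigenvalue
    real parts are below ``-tol_eig``, ``"unstable"`` when some exceed
    ``+tol_eig``, and ``"marginal"`` otherwise.  Raises when the supplied
    state is not an equilibrium to within ``tol_eq``.
    """
    fun, pack, _, _ = make_rhs(variant, tissue, params, phi)
    y = pack(equilibrium)
    J, f0 = _fd_jacobian(fun, y)
    res = float(np.max(np.abs(f0)))
    if res > tol_eq:
        raise FluxModelError(f"state is not an equilibrium (||rhs||_inf = {res:.3g})")
    spec = eigvals(J)
    mre = float(np.max(spec.real))
    if mre < -tol_eig:
        label = "stable"
    elif mre > tol_eig:
        label = "unstable"
    else:
        label = "marginal"
    return label, spec


def construct_equilibrium(tissue: TissueGraph, orientation: Iterable[tuple[int, int]],
                          params: ModelParams, a_guess: np.ndarray | None = None,
                          tol: float = 1e-12) -> State:
    """Slow-model equilibrium (quadratic response) with a prescribed orientation.

    On every active membrane ``i -> j`` the fixed point of the PIN equation
    forces ``p_ij = 1/(c a_i^2)`` and flux ``J = 1/(c a_i)``; the remaining
    unknowns are the cell auxin levels, solved by Newton iteration on the cell
    balance equations.  Raises when no positive solution is found.
    """
    c = params.c
    alpha, beta = params.cell_rates(tissue)
    edges = [(int(i), int(j)) for i, j in orientation]
    for i, j in edges:
        tissue.pair_index(i, j)  # validates adjacency
    out_count = np.zeros(tissue.n_cells)
    for i, _ in edges:
        out_count[i] += 1

    def residual(a):
        r = alpha - beta * a
        r -= out_count / (c * a)
        for i, j in edges:
            r[j] += 1.0 / (c * a[i])
        return r

    a0 = a_guess if a_guess is not None else np.where(beta > 0, alpha / np.maximum(beta, 1e-12), 1.0)
    a0 = np.maximum(np.asarray(a0, dtype=float), 1e-6)
    sol = root(residual, a0, method="hybr", tol=1e-13)
    a = sol.x
    if not sol.success or np.any(a <= 0) or np.max(np.abs(residual(a))) > 1e-8:
        raise FluxModelError("no positive equilibrium found for this orientation")
    p = np.zeros(2 * tissue.n_edges)
    for i, j in edges:
        p[tissue.pair_index(i, j)] = 1.0 / (c * a[i] ** 2)
    state = State(a, p)
    check = rhs_slow(state, tissue, params, ResponseFunction.quadratic())
    res = max(np.max(np.abs(check.a)), np.max(np.abs(check.p), initial=0.0))
    if res > 1e-8:
        raise FluxModelError(f"constructed state fails the residual check ({res:.3g})")
    return state


# ---------------------------------------------------------------------------
# Sink-driven closed form
# ---------------------------------------------------------------------------

def solve_sink_tree(tree: OrientedSubgraph | nx.DiGraph, alpha_a: Sequence[float],
                    c: float, beta_root: float) -> tuple[np.ndarray, State | None]:
    """Exact steady state of the sink-driven slow model on a spanning in-tree.

    Every non-root cell has out-degree one and zero degradation; the root
    (the unique sink) degrades at ``beta_root > 0``.  With ``alpha_a(i)`` the
    total production of the subtree draining through ``i``::

        a_i    = 1 / (c * alpha_a(i))       (i != root)
        a_root = alpha_a(root) / beta_root

    so auxin strictly decreases along every directed path while it stays away
    from the root, and the flux out of ``i`` equals ``alpha_a(i)``.

    Returns ``(a, state)`` where ``state`` carries the membrane PIN pattern
    ``p_i->parent = c * alpha_a(i)**2`` (None when the tree is not backed by a
    tissue-sized orientation).
    """
    if isinstance(tree, OrientedSubgraph):
        dg = tree.to_networkx()
        n = tree.n_cells
    else:
        dg = tree
        n = dg.number_of_nodes()
    if c <= 0:
        raise FluxModelError("c must be positive")
    if beta_root <= 0:
        raise FluxModelError("no steady state: the sink must degrade auxin (beta_root > 0)")
    alpha_a = np.asarray(alpha_a, dtype=float)
    if alpha_a.shape != (n,):
        raise StructuralError(f"alpha_a must have length {n}")

    roots = [i for i in dg.nodes if dg.out_degree(i) == 0]
    if len(roots) != 1 or not nx.is_directed_acyclic_graph(dg) or \
            any(dg.out_degree(i) > 1 for i in dg.nodes) or \
            dg.number_of_edges() != n - 1:
        raise StructuralError("orientation is not a spanning in-tree")
    root_cell = roots[0]

    # one bottom-up pass accumulates subtree production sums
    subtree = alpha_a.astype(float).copy()
    for i in nx.topological_sort(dg):          # leaves before the root
        for _, parent in dg.out_edges(i):
            subtree[parent] += subtree[i]

    a = 1.0 / (c * subtree)
    a[root_cell] = subtree[root_cell] / beta_root

    state = None
    if isinstance(tree, OrientedSubgraph):
        p = {}
        J = {}
        for i, parent in dg.edges:
            p[(i, parent)] = c * subtree[i] ** 2
            J[(i, parent)] = subtree[i]
        state = OrientedSubgraph(n, list(dg.edges), a=a, p=p, J=J)
    return a, state


def sink_tree_state(tree: OrientedSubgraph, tissue: TissueGraph,
                    alpha_a: Sequence[float], c: float, beta_root: float) -> State:
    """Full :class:`State` of the sink-driven equilibrium on a tissue."""
    a, oriented = solve_sink_tree(tree, alpha_a, c, beta_root)
    p = np.zeros(2 * tissue.n_edges)
    for (i, j), val in oriented.p.items():
        p[tissue.pair_index(i, j)] = val
    return State(a, p)


# ---------------------------------------------------------------------------
# Source-driven chain
# ---------------------------------------------------------------------------

@dataclass
class ChainSolution:
    """Steady state of a source-driven linear vein ``i0 -> i1 -> ... -> in``.

    ``a`` holds the chain auxin levels (length n+1), ``p`` and ``J`` the
    membrane PIN and fluxes on the n chain edges.  ``regime`` is ``"A"``
    (auxin above background, nondecreasing), ``"B"`` (below background,
    nonincreasing — terminal sink cell excepted) or ``"other"``;
    ``status`` is ``"ok"`` or ``"no_solution"``.
    """

    n: int
    a: np.ndarray
    p: np.ndarray
    J: np.ndarray
    background: float
    regime: str = "other"
    degenerate: bool = False
    status: str = "ok"

    def to_dict(self) -> dict:
        return {"n": self.n, "a": self.a.tolist(), "p": self.p.tolist(),
                "J": self.J.tolist(), "background": self.background,
                "regime": self.regime, "degenerate": self.degenerate,
                "status": self.status}


def solve_source_chain(n: int, alpha: float, alpha0: float, beta: float,
                       c: float, lam: float = 1.0, mu: float = 1.0,
                       prefer: str = "high-flux") -> ChainSolution:
    """Solve the slow-model steady state on a source-driven chain of n edges.

    All cells share degradation ``beta`` and production ``alpha`` except the
    source ``i0`` with ``alpha0``.  On every chain edge the quadratic response
    pins ``p_k = 1/(c a_k^2)`` and ``J_k = 1/(c a_k)``; the cell balances then
    reduce to one scalar quadratic per cell, solved by continuation along the
    chain with backtracking over the two roots.  ``prefer="high-flux"`` takes
    the smaller-auxin (larger-flux) root first, which is the branch selected
    by forward integration in both source-driven regimes.

    Returns a :class:`ChainSolution`; failure to find a real positive branch
    is reported as ``status="no_solution"``, not an exception.
    """
    if beta <= 0 or c <= 0:
        raise FluxModelError("beta and c must be positive")
    bg = alpha / beta
    if n == 0:  # isolated source cell, no vein
        a = np.array([alpha0 / beta])
        return ChainSolution(0, a, np.empty(0), np.empty(0), bg,
                             regime="A" if a[0] >= bg else "other")

    order = (0, 1) if prefer == "high-flux" else (1, 0)

    def cell_roots(inflow_plus_alpha: float) -> list[float]:
        # beta*c*a^2 - c*(inflow+alpha)*a + 1 = 0
        disc = (c * inflow_plus_alpha) ** 2 - 4.0 * beta * c
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        roots = [(c * inflow_plus_alpha - sq) / (2 * beta * c),
                 (c * inflow_plus_alpha + sq) / (2 * beta * c)]
        return [roots[k] for k in order if roots[k] > 0]

    a = np.full(n + 1, np.nan)
    J = np.full(n, np.nan)

    def extend(k: int, inflow: float) -> bool:
        """Place cell k given the flux flowing into it; recurse down the chain."""
        drive = inflow + (alpha0 if k == 0 else alpha)
        if k == n:                      # terminal sink cell: no outgoing flux
            a[k] = drive / beta
            return True
        for ak in cell_roots(drive):
            a[k] = ak
            J[k] = 1.0 / (c * ak)
            if extend(k + 1, J[k]):
                return True
        return False

    if not extend(0, 0.0):
        return ChainSolution(n, a, np.empty(0), np.empty(0), bg, status="no_solution")

    p = 1.0 / (c * a[:-1] ** 2)
    sol = ChainSolution(n, a, p, J, bg)
    sol.regime, sol.degenerate = classify_regime(sol)
    return sol


def classify_regime(chain: ChainSolution, tol: float = 1e-9) -> tuple[str, bool]:
    """Label a chain solution as regime A, B or other.

    A: auxin at or above background ``alpha/beta`` and nondecreasing along the
    whole vein.  B: auxin at or below background and nonincreasing along the
    vein, *excluding the terminal sink cell* — its balance forces it above
    background in either regime, and the canal proper is the preceding cells.
    The degenerate constant profile satisfies both chains of inequalities and
    is reported as A with ``degenerate=True``.
    """
    if chain.status != "ok":
        return "other", False
    a, bg = chain.a, chain.background
    scale = max(1.0, float(np.max(np.abs(a))))
    eps = tol * scale
    inc = bool(np.all(np.diff(a) >= -eps)) and bool(np.all(a >= bg - eps))
    body = a[:-1] if a.size > 1 else a
    dec = bool(np.all(np.diff(body) <= eps)) and bool(np.all(body <= bg + eps))
    if inc and dec:
        return "A", True
    if inc:
        return "A", False
    if dec:
        return "B", False
    return "other", False


def regime_map(alpha_grid: Sequence[float], alpha0_grid: Sequence[float],
               c: float, lam: float, mu: float, beta: float, n: int):
    """Regime label on an (alpha, alpha0) grid for a chain of n edges.

    Points with ``alpha0 <= alpha`` have no source-driven premise and are
    labelled ``"other"``; per-point solver failures propagate as ``"other"``.
    Returns a pandas DataFrame indexed by alpha with alpha0 columns.
    """
    import pandas as pd

    labels = np.empty((len(alpha_grid), len(alpha0_grid)), dtype=object)
    for r, alpha in enumerate(alpha_grid):
        for s, alpha0 in enumerate(alpha0_grid):
            if alpha0 <= alpha:
                labels[r, s] = "other"
                continue
            sol = solve_source_chain(n, alpha, alpha0, beta, c, lam, mu)
            labels[r, s] = sol.regime if sol.status == "ok" else "other"
    return pd.DataFrame(labels, index=list(alpha_grid), columns=list(alpha0_grid))
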