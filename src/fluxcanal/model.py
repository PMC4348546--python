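"""Core definitions of the flux-based auxin transport model on a cell graph.

The tissue is an undirected graph of cells.  Each cell ``i`` carries an auxin
concentration ``a_i`` (mol m^-3) and, in the extended model, a cytosolic PIN
pool ``P_i``.  Each *ordered* adjacent pair ``(i, j)`` carries a membrane PIN
concentration ``p_ij`` (mol m^-2): the PIN sitting in the membrane of cell
``i`` that faces cell ``j`` and pumps auxin from ``i`` into ``j``.

Three model variants are provided:

``full``
    The original flux model.  Auxin moves by Fickian diffusion
    ``J^D = gamma_D (a_i - a_j)`` and by PIN-mediated active transport
    ``J^A = gamma_A (a_i p_ij - a_j p_ji)``; membrane PIN responds to the net
    flux through a rectified, nondecreasing response function ``h`` plus a
    basal insertion rate ``rho_0`` and linear removal ``mu``.

``extended``
    Adds the cytosolic PIN pool ``P_i``: insertion into a membrane consumes
    cytosolic PIN at rate ``lambda P_i h(J)`` and removal returns it.  When
    PIN production and degradation are switched off the per-cell total
    ``P_i + (1/V_i) sum_j S_ij p_ij`` is exactly conserved.

``slow``
    The singular limit of the extended model when PIN cycling is fast and
    diffusion negligible (regular tissue, transport rate normalized to 1):
    ``da_i/dt = alpha_ai - beta_ai a_i + sum_k (a_k p_ki - a_i p_ik)`` and
    ``dp_ij/dt = lambda (alpha_p/beta_p) Phi(J_ij) - mu p_ij`` with
    ``J_ij = a_i p_ij - a_j p_ji``.

All response functions are *rectified*: they vanish for nonpositive flux, so
PIN is only inserted into membranes that carry outgoing auxin flux.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "FluxModelError",
    "StructuralError",
    "UnsupportedVariantError",
    "ConfigurationError",
    "TissueGraph",
    "ModelParams",
    "ResponseFunction",
    "State",
    "VARIANTS",
    "diffusive_flux",
    "active_flux",
    "eval_response",
    "rhs_full",
    "rhs_extended",
    "rhs_slow",
    "make_rhs",
    "normalize_params",
    "apply_eps_scaling",
    "total_cell_pin",
    "pin_conservation_rate",
    "source_condition",
]


class FluxModelError(Exception):
    """Base class for all errors raised by fluxcanal."""


class StructuralError(FluxModelError):
    """Dimension mismatch or malformed graph structure."""


class UnsupportedVariantError(FluxModelError):
    """A model variant was requested on a tissue it does not support."""


class ConfigurationError(FluxModelError):
    """Invalid parameter or response-function specification."""


VARIANTS = ("full", "extended", "slow")


# ---------------------------------------------------------------------------
# Tissue graph
# ---------------------------------------------------------------------------

class TissueGraph:
    """Undirected cell-adjacency graph with volumes and membrane areas.

    Parameters
    ----------
    n_cells:
        Number of cells ``M``; cells are identified by ``0 .. M-1``.
    edges:
        Iterable of undirected adjacency pairs ``(i, j)``.  Stored sorted with
        ``i < j``; self edges and duplicates are rejected.
    volumes:
        Cell volumes ``V_i`` (default 1 for every cell).
    areas:
        Membrane surface areas ``S_ij``, one per undirected edge, aligned with
        ``edges`` (default 1).  ``S_ij = S_ji`` by construction.

    Membrane PIN lives on *ordered* pairs.  Edge ``e = (i, j)`` owns the two
    ordered pairs ``2e = i->j`` and ``2e + 1 = j->i``; the reverse of ordered
    pair ``k`` is ``k ^ 1``.
    """

    def __init__(
        self,
        n_cells: int,
        edges: Iterable[tuple[int, int]],
        volumes: Sequence[float] | None = None,
        areas: Sequence[float] | None = None,
    ):
        if n_cells < 1:
            raise StructuralError("tissue needs at least one cell")
        self.n_cells = int(n_cells)

        edge_arr = np.asarray(sorted({(min(i, j), max(i, j)) for i, j in edges}), dtype=int)
        if edge_arr.size == 0:
            edge_arr = np.empty((0, 2), dtype=int)
        if edge_arr.size:
            if edge_arr.min() < 0 or edge_arr.max() >= n_cells:
                raise StructuralError("edge endpoint out of range")
            if np.any(edge_arr[:, 0] == edge_arr[:, 1]):
                raise StructuralError("self edges are not allowed")
        self.edges = edge_arr
        self.n_edges = len(edge_arr)

        self.volumes = self._positive_vector(volumes, self.n_cells, "volumes")
        self.areas = self._positive_vector(areas, self.n_edges, "areas")

        # ordered-pair index arrays
        m = self.n_edges
        self.pair_src = np.empty(2 * m, dtype=int)
        self.pair_dst = np.empty(2 * m, dtype=int)
        self.pair_src[0::2] = edge_arr[:, 0] if m else []
        self.pair_src[1::2] = edge_arr[:, 1] if m else []
        self.pair_dst[0::2] = edge_arr[:, 1] if m else []
        self.pair_dst[1::2] = edge_arr[:, 0] if m else []
        self.pair_rev = np.arange(2 * m) ^ 1
        self.pair_area = np.repeat(self.areas, 2)
        self.degrees = np.bincount(self.pair_src, minlength=self.n_cells)
        self._pair_index = {
            (int(s), int(d)): k for k, (s, d) in enumerate(zip(self.pair_src, self.pair_dst))
        }

    @staticmethod
    def _positive_vector(values, n, name):
        if values is None:
            return np.ones(n)
        out = np.asarray(values, dtype=float)
        if out.shape != (n,):
            raise StructuralError(f"{name} must have length {n}")
        if n and out.min() <= 0:
            raise StructuralError(f"{name} must be strictly positive")
        return out

    # -- derived structure --------------------------------------------------

    def pair_index(self, i: int, j: int) -> int:
        """Index of the ordered pair ``i -> j`` in the membrane-PIN layout."""
        try:
            return self._pair_index[(i, j)]
        except KeyError:
            raise StructuralError(f"cells {i} and {j} are not adjacent") from None

    def neighbors(self, i: int) -> list[int]:
        return [int(d) for s, d in zip(self.pair_src, self.pair_dst) if s == i]

    @property
    def regular(self) -> bool:
        """True when all volumes and all membrane areas are equal."""
        vol_ok = np.allclose(self.volumes, self.volumes[0]) if self.n_cells else True
        area_ok = np.allclose(self.areas, self.areas[0]) if self.n_edges else True
        return bool(vol_ok and area_ok)

    @property
    def W(self) -> float:
        """Surface-to-volume ratio ``S_ij / V_i`` of a regular tissue."""
        if not self.regular:
            raise UnsupportedVariantError("W is only defined for regular tissues")
        if self.n_edges == 0:
            return 1.0 / float(self.volumes[0])
        return float(self.areas[0] / self.volumes[0])

    # -- interchange ---------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_cells):
            g.add_node(i, volume=float(self.volumes[i]))
        for e, (i, j) in enumerate(self.edges):
            g.add_edge(int(i), int(j), area=float(self.areas[e]))
        return g

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "edges": [[int(i), int(j)] for i, j in self.edges],
            "volumes": self.volumes.tolist(),
            "areas": self.areas.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TissueGraph":
        return cls(doc["n_cells"], [tuple(e) for e in doc["edges"]],
                   doc.get("volumes"), doc.get("areas"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "TissueGraph":
        return cls.from_dict(json.loads(text))

    def __eq__(self, other):
        return (
            isinstance(other, TissueGraph)
            and self.n_cells == other.n_cells
            and np.array_equal(self.edges, other.edges)
            and np.allclose(self.volumes, other.volumes)
            and np.allclose(self.areas, other.areas)
        )

    def __repr__(self):
        return f"TissueGraph(M={self.n_cells}, m={self.n_edges}, regular={self.regular})"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _as_cell_vector(value, n_cells) -> np.ndarray:
    out = np.asarray(value, dtype=float)
    if out.ndim == 0:
        out = np.full(n_cells, float(out))
    if out.shape != (n_cells,):
        raise StructuralError(f"per-cell rate must be scalar or length {n_cells}")
    return out


@dataclass
class ModelParams:
    """Rate constants of the transport model.

    ``alpha_a``/``beta_a`` are auxin synthesis (mol m^-3 s^-1) and degradation
    (s^-1) rates, scalar or per cell.  ``gamma_D`` (m s^-1) and ``gamma_A``
    (m^3 mol^-1 s^-1) are the diffusive and active transport coefficients.
    ``rho0`` is the basal membrane insertion rate (full model only), ``mu`` the
    membrane removal rate, ``lam`` the insertion rate and ``alpha_p``/``beta_p``
    the cytosolic PIN production/degradation.  Units are consistent
    user-supplied working units; no conversion is attempted.
    """

    alpha_a: float | np.ndarray = 1.0
    beta_a: float | np.ndarray = 1.0
    gamma_D: float = 0.0
    gamma_A: float = 1.0
    rho0: float = 0.0
    mu: float = 1.0
    lam: float = 1.0
    alpha_p: float = 1.0
    beta_p: float = 1.0
    eps: float = 1.0

    def __post_init__(self):
        for name in ("gamma_D", "gamma_A", "rho0", "mu", "lam", "alpha_p", "beta_p"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if np.any(np.asarray(self.alpha_a) < 0) or np.any(np.asarray(self.beta_a) < 0):
            raise ConfigurationError("alpha_a and beta_a must be nonnegative")

    @property
    def c(self) -> float:
        """Composite steady-state constant ``c = lam * alpha_p / (mu * beta_p)``."""
        if self.mu <= 0 or self.beta_p <= 0:
            raise ConfigurationError("c requires mu > 0 and beta_p > 0")
        return self.lam * self.alpha_p / (self.mu * self.beta_p)

    @property
    def pin_pool(self) -> float:
        """Quasi-steady cytosolic PIN level ``alpha_p / beta_p``."""
        if self.beta_p <= 0:
            raise ConfigurationError("pin_pool requires beta_p > 0")
        return self.alpha_p / self.beta_p

    def cell_rates(self, tissue: TissueGraph) -> tuple[np.ndarray, np.ndarray]:
        return (_as_cell_vector(self.alpha_a, tissue.n_cells),
                _as_cell_vector(self.beta_a, tissue.n_cells))

    def to_dict(self) -> dict:
        d = {}
        for name in ("alpha_a", "beta_a", "gamma_D", "gamma_A", "rho0", "mu",
                     "lam", "alpha_p", "beta_p", "eps"):
            v = getattr(self, name)
            d[name] = v.tolist() if isinstance(v, np.ndarray) else float(v)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParams":
        kw = dict(doc)
        for key in ("alpha_a", "beta_a"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


def apply_eps_scaling(params: ModelParams, eps: float, D0: float | None = None) -> ModelParams:
    """Scale PIN cycling rates into the fast regime used by the slow limit.

    Returns a copy with ``alpha_p -> alpha_p/eps``, ``beta_p -> beta_p/eps``
    and, when ``D0`` is given, a diffusion constant ``gamma_D`` such that the
    normalized diffusion rate is ``D0 * eps``.  The composite constant ``c``
    is invariant under this scaling.
    """
    if eps <= 0:
        raise ConfigurationError("eps must be positive")
    gamma_D = params.gamma_D if D0 is None else D0 * eps
    return replace(params, alpha_p=params.alpha_p / eps,
                   beta_p=params.beta_p / eps, gamma_D=gamma_D, eps=eps)


# ---------------------------------------------------------------------------
# Response functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseFunction:
    """Rectified flux-response nonlinearity ``h`` (or its normalized form).

    All kinds evaluate to zero for arguments <= 0 and are nondecreasing and
    nonnegative for positive arguments:

    - ``linear``:    kappa * x / j_ref
    - ``quadratic``: kappa * (x / j_ref)**2
    - ``hill``:      rho * x**n / (theta**n + x**n)   (bounded by rho)
    - ``power``:     rho * x**n
    - ``custom``:    user callable (rectification enforced); ``bounded`` must
      be declared by the caller.
    """

    kind: str = "quadratic"
    kappa: float = 1.0
    j_ref: float = 1.0
    rho: float = 1.0
    theta: float = 1.0
    n: float = 2.0
    fn: Callable[[np.ndarray], np.ndarray] | None = None
    custom_bounded: bool = False

    def __post_init__(self):
        if self.kind not in ("linear", "quadratic", "hill", "power", "custom"):
            raise ConfigurationError(f"unknown response kind {self.kind!r}")
        for name in ("kappa", "j_ref", "rho", "theta", "n"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"response parameter {name} must be >= 0")
        if self.kind in ("linear", "quadratic") and self.j_ref == 0:
            raise ConfigurationError("j_ref must be positive")
        if self.kind == "custom" and self.fn is None:
            raise ConfigurationError("custom response needs a callable")

    # convenience constructors
    @classmethod
    def linear(cls, kappa=1.0, j_ref=1.0):
        return cls("linear", kappa=kappa, j_ref=j_ref)

    @classmethod
    def quadratic(cls, kappa=1.0, j_ref=1.0):
        return cls("quadratic", kappa=kappa, j_ref=j_ref)

    @classmethod
    def hill(cls, rho=1.0, theta=1.0, n=2.0):
        return cls("hill", rho=rho, theta=theta, n=n)

    @classmethod
    def power(cls, rho=1.0, n=2.0):
        return cls("power", rho=rho, n=n)

    @property
    def bounded(self) -> bool:
        """True iff sup_{x>0} h(x) is finite."""
        if self.kind == "hill":
            return True
        if self.kind == "custom":
            return self.custom_bounded
        return False

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        pos = np.maximum(x, 0.0)
        if self.kind == "linear":
            out = self.kappa * pos / self.j_ref
        elif self.kind == "quadratic":
            out = self.kappa * (pos / self.j_ref) ** 2
        elif self.kind == "hill":
            xn = pos ** self.n
            out = np.where(pos > 0, self.rho * xn / (self.theta ** self.n + xn), 0.0)
        elif self.kind == "power":
            out = self.rho * pos ** self.n
        else:
            out = np.where(x > 0, np.asarray(self.fn(pos), dtype=float), 0.0)
        return out if out.ndim else float(out)

    def derivative(self, x):
        """One-sided (rectified) derivative; 0 for x <= 0.

        The rectified quadratic is C^1 with derivative 0 at the kink, which is
        what makes finite-difference Jacobians of the slow model well posed.
        """
        x = np.asarray(x, dtype=float)
        pos = np.maximum(x, 0.0)
        if self.kind == "linear":
            out = np.where(x > 0, self.kappa / self.j_ref, 0.0)
        elif self.kind == "quadratic":
            out = 2.0 * self.kappa * pos / self.j_ref ** 2
        elif self.kind == "hill":
            tn = self.theta ** self.n
            out = np.where(
                x > 0,
                self.rho * self.n * tn * pos ** (self.n - 1) / (tn + pos ** self.n) ** 2,
                0.0,
            )
        elif self.kind == "power":
            out = np.where(x > 0, self.rho * self.n * pos ** (self.n - 1), 0.0)
        else:
            step = 1e-7 * np.maximum(1.0, np.abs(x))
            out = np.where(x > 0, (np.asarray(self(x + step)) - np.asarray(self(x))) / step, 0.0)
        return out if out.ndim else float(out)

    def scaled_input(self, W: float) -> "ResponseFunction":
        """Return ``Phi`` with ``Phi(x) = h(x / W)`` within the same family."""
        if W <= 0:
            raise ConfigurationError("W must be positive")
        if self.kind in ("linear", "quadratic"):
            return replace(self, j_ref=self.j_ref * W)
        if self.kind == "hill":
            return replace(self, theta=self.theta * W)
        if self.kind == "power":
            return replace(self, rho=self.rho / W ** self.n)
        fn = self.fn
        return replace(self, fn=lambda x, _f=fn, _w=W: _f(np.asarray(x) / _w))

    def to_dict(self) -> dict:
        if self.kind == "custom":
            raise ConfigurationError("custom response functions are not serializable")
        return {"kind": self.kind, "kappa": self.kappa, "j_ref": self.j_ref,
                "rho": self.rho, "theta": self.theta, "n": self.n}

    @classmethod
    def from_dict(cls, doc: dict) -> "ResponseFunction":
        return cls(**doc)


def eval_response(phi: ResponseFunction, x):
    """Evaluate a response function (rectified: 0 for x <= 0)."""
    return phi(x)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class State:
    """Model state: per-cell auxin ``a``, membrane PIN ``p`` per ordered pair,
    and (extended model only) cytosolic PIN ``P``."""

    a: np.ndarray
    p: np.ndarray
    P: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.P is not None:
            self.P = np.asarray(self.P, dtype=float)

    @classmethod
    def zeros(cls, tissue: TissueGraph, with_cytosol: bool = False) -> "State":
        return cls(
            a=np.zeros(tissue.n_cells),
            p=np.zeros(2 * tissue.n_edges),
            P=np.zeros(tissue.n_cells) if with_cytosol else None,
        )

    def check(self, tissue: TissueGraph, variant: str = "slow", nonnegative: bool = True):
        if self.a.shape != (tissue.n_cells,):
            raise StructuralError("auxin vector has wrong length")
        if self.p.shape != (2 * tissue.n_edges,):
            raise StructuralError("membrane PIN vector must have one entry per ordered pair")
        if variant == "extended":
            if self.P is None or self.P.shape != (tissue.n_cells,):
                raise StructuralError("extended model needs a cytosolic PIN vector")
        if nonnegative:
            low = min(self.a.min(initial=0.0), self.p.min(initial=0.0))
            if self.P is not None:
                low = min(low, self.P.min(initial=0.0))
            if low < 0:
                raise StructuralError("state entries must be nonnegative")
        return self

    def copy(self) -> "State":
        return State(self.a.copy(), self.p.copy(),
                     None if self.P is None else self.P.copy())

    def p_at(self, tissue: TissueGraph, i: int, j: int) -> float:
        return float(self.p[tissue.pair_index(i, j)])


# ---------------------------------------------------------------------------
# Fluxes and right-hand sides
# ---------------------------------------------------------------------------

def diffusive_flux(a_i, a_j, gamma_D):
    """Fickian flux ``gamma_D (a_i - a_j)`` through membrane i|j (mol m^-2 s^-1)."""
    return gamma_D * (a_i - a_j)


def active_flux(a_i, a_j, p_ij, p_ji, gamma_A):
    """PIN-mediated flux ``gamma_A (a_i p_ij - a_j p_ji)`` (mol m^-2 s^-1)."""
    return gamma_A * (a_i * p_ij - a_j * p_ji)


def _pair_flux(tissue, a, p, gamma_D, gamma_A):
    src, dst = tissue.pair_src, tissue.pair_dst
    J = gamma_A * (a[src] * p - a[dst] * p[tissue.pair_rev])
    if gamma_D != 0.0:
        J = gamma_D * (a[src] - a[dst]) + J
    return J


def _scatter(tissue, pair_values):
    out = np.zeros(tissue.n_cells)
    np.add.at(out, tissue.pair_src, pair_values)
    return out


def rhs_full(state: State, tissue: TissueGraph, params: ModelParams,
             phi: ResponseFunction) -> State:
    """Time derivative of the full model (diffusion + active transport,
    flux-responsive membrane PIN with basal insertion ``rho0``)."""
    state.check(tissue, "full", nonnegative=False)
    alpha, beta = params.cell_rates(tissue)
    J = _pair_flux(tissue, state.a, state.p, params.gamma_D, params.gamma_A)
    da = alpha - beta * state.a - _scatter(tissue, tissue.pair_area * J) / tissue.volumes
    dp = phi(J) + params.rho0 - params.mu * state.p
    return State(da, np.asarray(dp, dtype=float))


def rhs_extended(state: State, tissue: TissueGraph, params: ModelParams,
                 phi: ResponseFunction) -> State:
    """Time derivative of the extended model with explicit cytosolic PIN.

    Membrane insertion draws on the cytosolic pool (rate ``lam P_i h(J)``);
    removal at rate ``mu`` returns PIN to the pool, so with
    ``alpha_p = beta_p = 0`` the per-cell total PIN is conserved exactly.
    """
    state.check(tissue, "extended", nonnegative=False)
    alpha, beta = params.cell_rates(tissue)
    J = _pair_flux(tissue, state.a, state.p, params.gamma_D, params.gamma_A)
    da = alpha - beta * state.a - _scatter(tissue, tissue.pair_area * J) / tissue.volumes
    h = phi(J)
    insertion = params.lam * state.P[tissue.pair_src] * h
    removal = params.mu * state.p
    dp = insertion - removal
    dP = (params.alpha_p - params.beta_p * state.P
          + _scatter(tissue, tissue.pair_area * (removal - insertion)) / tissue.volumes)
    return State(da, dp, dP)


def rhs_slow(state: State, tissue: TissueGraph, params: ModelParams,
             phi: ResponseFunction) -> State:
    """Time derivative of the slow (fast PIN-cycling, zero diffusion) limit.

    Requires a regular tissue; the cytosolic pool is frozen at
    ``alpha_p / beta_p`` and the active transport rate is normalized to 1.
    """
    if not tissue.regular:
        raise UnsupportedVariantError("the slow model requires a regular tissue")
    state.check(tissue, "slow", nonnegative=False)
    alpha, beta = params.cell_rates(tissue)
    src, dst = tissue.pair_src, tissue.pair_dst
    J = state.a[src] * state.p - state.a[dst] * state.p[tissue.pair_rev]
    da = alpha - beta * state.a - _scatter(tissue, J)
    dp = params.lam * params.pin_pool * phi(J) - params.mu * state.p
    return State(da, np.asarray(dp, dtype=float))


_RHS = {"full": rhs_full, "extended": rhs_extended, "slow": rhs_slow}


def make_rhs(variant: str, tissue: TissueGraph, params: ModelParams,
             phi: ResponseFunction):
    """Return ``(fun, pack, unpack, dim)`` for ODE integration.

    ``fun(t, y)`` evaluates the packed right-hand side; ``pack(state)`` and
    ``unpack(y)`` convert between :class:`State` and the flat vector layout
    ``[a, p]`` (full/slow) or ``[a, P, p]`` (extended).
    """
    if variant not in _RHS:
        raise UnsupportedVariantError(f"unknown variant {variant!r}")
    if variant == "slow" and not tissue.regular:
        raise UnsupportedVariantError("the slow model requires a regular tissue")
    rhs = _RHS[variant]
    M, mp = tissue.n_cells, 2 * tissue.n_edges

    if variant == "extended":
        dim = 2 * M + mp

        def pack(state: State) -> np.ndarray:
            return np.concatenate([state.a, state.P, state.p])

        def unpack(y: np.ndarray) -> State:
            return State(y[:M], y[2 * M:], y[M:2 * M])
    else:
        dim = M + mp

        def pack(state: State) -> np.ndarray:
            return np.concatenate([state.a, state.p])

        def unpack(y: np.ndarray) -> State:
            return State(y[:M], y[M:])

    def fun(t, y):
        d = rhs(unpack(y), tissue, params, phi)
        return pack(d)

    return fun, pack, unpack, dim


# ---------------------------------------------------------------------------
# Normalization and conserved quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedModel:
    """Normalized rates of a regular tissue: ``D = gamma_D W``,
    ``T = gamma_A W``, ``Phi(x) = h(x / W)`` and ``c = lam alpha_p/(mu beta_p)``."""

    D: float
    T: float
    phi: ResponseFunction
    c: float
    params: ModelParams


def normalize_params(tissue: TissueGraph, params: ModelParams,
                     h: ResponseFunction, eps: float | None = None,
                     D0: float | None = None) -> NormalizedModel:
    """Normalize rates for a regular tissue; optionally apply the fast
    PIN-cycling scaling (``eps``) under which ``c`` is invariant."""
    if not tissue.regular:
        raise UnsupportedVariantError("normalization requires a regular tissue")
    W = tissue.W
    scaled = params if eps is None else apply_eps_scaling(params, eps, D0)
    return NormalizedModel(
        D=scaled.gamma_D * W,
        T=scaled.gamma_A * W,
        phi=h.scaled_input(W),
        c=scaled.c,
        params=scaled,
    )


def total_cell_pin(state: State, tissue: TissueGraph, i: int | None = None):
    """Per-cell total PIN ``P_i + (1/V_i) sum_j S_ij p_ij`` (extended model).

    Returns the scalar for cell ``i`` or the full vector when ``i`` is None.
    This quantity is exactly conserved along trajectories when
    ``alpha_p = beta_p = 0``.
    """
    state.check(tissue, "extended", nonnegative=False)
    total = state.P + _scatter(tissue, tissue.pair_area * state.p) / tissue.volumes
    return total if i is None else float(total[i])


def pin_conservation_rate(state: State, tissue: TissueGraph, params: ModelParams,
                          phi: ResponseFunction) -> np.ndarray:
    """Rate of change of the per-cell total PIN under the extended model:
    ``dP_i/dt + (1/V_i) sum_j S_ij dp_ij/dt``.

    Evaluates to ``alpha_p - beta_p P_i``; identically zero (to the last bit,
    by construction of :func:`rhs_extended`) when production and degradation
    are switched off.
    """
    d = rhs_extended(state, tissue, params, phi)
    return d.P + _scatter(tissue, tissue.pair_area * d.p) / tissue.volumes


def source_condition(alpha0: float, alpha: float, beta: float, c: float,
                     reading: str = "2*beta/c") -> bool:
    """Predicate for the source-driven premise ``alpha0 >= <middle> > alpha``.

    The middle term of the printed condition is typographically ambiguous;
    ``reading`` selects ``"2*beta/c"`` (default), ``"2*beta*c"`` or
    ``"2*sqrt(beta/c)"`` (the existence threshold of the source-cell steady
    state, ``alpha0**2 >= 4 beta / c``).  The solver itself never uses this
    predicate; it reports no-solution directly when the chain equations have
    no real positive root.
    """
    middle = {
        "2*beta/c": 2 * beta / c,
        "2*beta*c": 2 * beta * c,
        "2*sqrt(beta/c)": 2 * math.sqrt(beta / c),
    }
    try:
        mid = middle[reading]
    except KeyError:
        raise ConfigurationError(f"unknown reading {reading!r}") from None
    return alpha0 >= mid > alpha
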