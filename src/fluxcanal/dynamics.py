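"""Time integration of the transport models with outcome classification.

The quadratic flux feedback makes trajectories stiff near canalization and
genuinely divergent (finite escape time) for unbounded response functions, so
integration uses SciPy's stiff-capable adaptive solvers with event-style
termination:

* **converged** — the sup-norm of the right-hand side fell below a tolerance;
* **diverged** — membrane PIN crossed a large threshold while accelerating;
  the escape time ``delta`` is estimated by first-order extrapolation of the
  fastest-growing component (for the quadratic feedback ``p ~ 1/(delta - t)``,
  so ``delta ~ t + p/ṗ``);
* **oscillating** — the trajectory tail keeps a finite amplitude around a
  stationary mean;
* **reached_t_max** — none of the above fired.

A legacy *cut-off* mode clamps membrane PIN at ``p_max``, reproducing the
bounded behaviour of earlier simulation studies rather than the model's
intrinsic dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    FluxModelError,
    ModelParams,
    ResponseFunction,
    State,
    StructuralError,
    TissueGraph,
    apply_eps_scaling,
    make_rhs,
)

__all__ = [
    "IntegratorOptions",
    "SimulationResult",
    "integrate",
    "run_with_cutoff",
    "detect_convergence",
    "detect_oscillation",
    "detect_blowup",
    "compare_slow_fast",
]


@dataclass(frozen=True)
class IntegratorOptions:
    """Integration controls.

    ``conv_tol`` is the convergence tolerance on the sup-norm of the
    right-hand side; ``blowup_threshold`` is the membrane-PIN level treated as
    a divergence signature; ``oscillation_window`` is the trailing fraction of
    the run inspected for sustained oscillation.  ``p_max`` activates the
    legacy cut-off mode (mutually exclusive with blow-up detection).
    """

    t_max: float = 1e4
    rtol: float = 1e-8
    atol: float = 1e-10
    conv_tol: float = 1e-8
    blowup_threshold: float = 1e6
    oscillation_window: float = 0.2
    osc_amp_tol: float = 1e-4
    osc_drift_frac: float = 0.25
    p_max: float | None = None
    method: str | None = None       # None: LSODA, or BDF+sparsity for large systems
    max_step: float = np.inf
    n_eval: int | None = None       # optional uniform output grid
    seed: int | None = None         # recorded for provenance only

    def __post_init__(self):
        if self.t_max <= 0 or self.conv_tol <= 0 or self.blowup_threshold <= 0:
            raise FluxModelError("thresholds and t_max must be positive")
        if self.p_max is not None and self.p_max < 0:
            raise FluxModelError("p_max must be nonnegative")


@dataclass
class SimulationResult:
    """Outcome of one integration run."""

    variant: str
    status: str                      # converged | diverged | oscillating | reached_t_max | failed
    times: np.ndarray
    trajectory: np.ndarray           # (dim, n_times) packed states
    final_state: State
    escape_time: float | None = None
    diagnostics: dict = field(default_factory=dict)
    options: IntegratorOptions | None = None

    def state_at(self, k: int) -> State:
        return self._unpack(self.trajectory[:, k])

    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table of the stored trajectory."""
        dim, nt = self.trajectory.shape
        names = self.diagnostics.get("variable_names")
        if names is None:
            names = [f"y{k}" for k in range(dim)]
        return pd.DataFrame({
            "time": np.repeat(self.times, dim),
            "variable": np.tile(names, nt),
            "value": self.trajectory.T.ravel(),
        })


def _variable_names(variant: str, tissue: TissueGraph) -> list[str]:
    a = [f"a[{i}]" for i in range(tissue.n_cells)]
    p = [f"p[{int(s)}->{int(d)}]" for s, d in zip(tissue.pair_src, tissue.pair_dst)]
    if variant == "extended":
        P = [f"P[{i}]" for i in range(tissue.n_cells)]
        return a + P + p
    return a + p


def _pick_method(options: IntegratorOptions, dim: int) -> str:
    if options.method is not None:
        return options.method
    return "BDF" if dim > 150 else "LSODA"


def _jac_sparsity(variant: str, tissue: TissueGraph, dim: int):
    """Structural sparsity of the Jacobian, used to speed up BDF on large tissues."""
    from scipy.sparse import lil_matrix

    M = tissue.n_cells
    offset = 2 * M if variant == "extended" else M
    S = lil_matrix((dim, dim), dtype=float)
    S[:offset, :offset] = 1  # cell blocks are dense enough to keep simple
    for k, (s, d) in enumerate(zip(tissue.pair_src, tissue.pair_dst)):
        r = offset + k
        cols = [s, d, r, offset + int(tissue.pair_rev[k])]
        if variant == "extended":
            cols += [M + s, M + d]
        for cl in cols:
            S[r, cl] = 1
            S[cl, r] = 1
    return S.tocsr()


def integrate(variant: str, tissue: TissueGraph, params: ModelParams,
              phi: ResponseFunction, init: State,
              options: IntegratorOptions = IntegratorOptions()) -> SimulationResult:
    """Integrate a model variant from ``init`` and classify the outcome.

    Deterministic: identical inputs and options produce identical output (the
    solvers hold no hidden random state).
    """
    init.check(tissue, variant)
    fun, pack, unpack, dim = make_rhs(variant, tissue, params, phi)
    y0 = pack(init)
    if not np.all(np.isfinite(y0)):
        raise FluxModelError("initial state contains non-finite entries")
    f0 = fun(0.0, y0)
    if not np.all(np.isfinite(f0)):
        raise FluxModelError("right-hand side is not finite at the initial state")
    p_slice = slice(2 * tissue.n_cells, None) if variant == "extended" \
        else slice(tissue.n_cells, None)
    cutoff = options.p_max is not None

    if cutoff:
        base_fun = fun

        def fun(t, y, _f=base_fun):  # clamp insertion at the cap
            d = _f(t, y)
            at_cap = y[p_slice] >= options.p_max
            dp = d[p_slice]
            dp[at_cap & (dp > 0)] = 0.0
            return d

    def conv_event(t, y):
        return float(np.max(np.abs(fun(t, y)))) - options.conv_tol
    conv_event.terminal = True
    conv_event.direction = -1

    events = [conv_event]
    if not cutoff:
        def blow_event(t, y):
            return float(np.max(y[p_slice], initial=0.0)) - options.blowup_threshold
        blow_event.terminal = True
        blow_event.direction = 1
        events.append(blow_event)

    method = _pick_method(options, dim)
    kwargs = dict(method=method, rtol=options.rtol, atol=options.atol,
                  max_step=options.max_step, events=events, dense_output=False)
    if method == "BDF":
        kwargs["jac_sparsity"] = _jac_sparsity(variant, tissue, dim)
    if options.n_eval:
        kwargs["t_eval"] = np.linspace(0.0, options.t_max, options.n_eval)

    sol = solve_ivp(fun, (0.0, options.t_max), y0, **kwargs)

    times = sol.t
    traj = sol.y
    # make sure the terminal event state is part of the stored trajectory
    if sol.status == 1:
        for te, ye in zip(sol.t_events, sol.y_events):
            if te.size and (times.size == 0 or te[-1] > times[-1]):
                times = np.append(times, te[-1])
                traj = np.hstack([traj, ye[-1][:, None]])

    if times.size == 0:
        times = np.array([0.0])
        traj = y0[:, None]

    y_end = traj[:, -1]
    f_end = fun(times[-1], y_end)
    rhs_norm = float(np.max(np.abs(f_end)))
    diagnostics = {
        "rhs_norm_final": rhs_norm,
        "n_steps": int(times.size),
        "solver_status": int(sol.status),
        "solver_message": sol.message,
        "method": method,
        "max_p": float(np.max(y_end[p_slice], initial=0.0)),
        "variable_names": _variable_names(variant, tissue),
    }

    escape = None
    if sol.status == 1 and not cutoff and len(sol.t_events) > 1 and sol.t_events[1].size:
        status = "diverged"
        escape = _escape_estimate(times[-1], y_end, f_end, p_slice)
        diagnostics["escape_time"] = escape
    elif sol.status == 1 and sol.t_events[0].size:
        status = "converged"
    elif sol.status == 0:
        if rhs_norm < options.conv_tol:
            status = "converged"
        elif times.size >= 8 and detect_oscillation(
                times, traj, options.oscillation_window,
                options.osc_amp_tol, options.osc_drift_frac):
            status = "oscillating"
        else:
            status = "reached_t_max"
    else:  # solver breakdown
        growing = float(np.max(np.abs(y_end))) > 10.0 * max(1.0, float(np.max(np.abs(y0))))
        if not cutoff and growing:
            status = "diverged"
            escape = _escape_estimate(times[-1], y_end, f_end, p_slice)
        else:
            status = "failed"

    if cutoff:  # projection step: the cap is enforced on the stored trajectory
        traj = traj.copy()
        traj[p_slice] = np.minimum(traj[p_slice], options.p_max)
        y_end = traj[:, -1]

    return SimulationResult(
        variant=variant, status=status, times=times, trajectory=traj,
        final_state=unpack(y_end), escape_time=escape,
        diagnostics=diagnostics, options=options,
    )


# give SimulationResult access to the right unpacker without holding closures
def _result_unpack(self, y):
    names = self.diagnostics.get("variable_names", [])
    M = sum(1 for s in names if s.startswith("a["))
    has_P = any(s.startswith("P[") for s in names)
    if has_P:
        return State(y[:M], y[2 * M:], y[M:2 * M])
    return State(y[:M], y[M:])


SimulationResult._unpack = _result_unpack


def _escape_estimate(t: float, y: np.ndarray, f: np.ndarray, p_slice: slice) -> float:
    """Extrapolated escape time from the fastest-growing membrane component.

    For the quadratic feedback ``ṗ ≈ K p**2`` near blow-up, ``delta - t =
    p / ṗ`` exactly, so the estimate is threshold-robust.
    """
    p = y[p_slice]
    dp = f[p_slice]
    if p.size == 0:
        return float(t)
    k = int(np.argmax(p))
    if dp[k] > 0:
        return float(t + p[k] / dp[k])
    return float(t)


def detect_convergence(times: np.ndarray, trajectory: np.ndarray,
                       rhs_fun, tol: float) -> bool:
    """True iff the right-hand side sup-norm at the final state is below tol."""
    if times.size == 0:
        raise FluxModelError("empty trajectory")
    f = rhs_fun(times[-1], trajectory[:, -1])
    return bool(np.max(np.abs(f)) < tol)


def detect_oscillation(times: np.ndarray, trajectory: np.ndarray,
                       window: float = 0.2, amp_tol: float = 1e-4,
                       drift_frac: float = 0.25) -> bool:
    """Detect sustained oscillation in the trailing ``window`` fraction.

    A variable oscillates when its tail amplitude exceeds ``amp_tol`` (relative
    to its scale) while the difference between the means of the two halves of
    the tail stays below ``drift_frac`` times that amplitude — i.e. the signal
    keeps swinging around a stationary level instead of drifting or decaying.
    """
    if not 0 < window <= 1:
        raise FluxModelError("window must lie in (0, 1]")
    if times.size < 8:
        raise FluxModelError("trajectory shorter than the oscillation window")
    t_end = times[-1]
    mask = times >= t_end - window * (t_end - times[0])
    if mask.sum() < 8:
        mask = np.zeros_like(mask)
        mask[-8:] = True
    tail = trajectory[:, mask]
    n = tail.shape[1]
    half = n // 2
    amp = tail.max(axis=1) - tail.min(axis=1)
    scale = np.maximum(1.0, np.abs(tail.mean(axis=1)))
    drift = np.abs(tail[:, :half].mean(axis=1) - tail[:, half:].mean(axis=1))
    swinging = (amp > amp_tol * scale) & (drift < drift_frac * amp)
    return bool(np.any(swinging))


def detect_blowup(times: np.ndarray, p_norm: np.ndarray,
                  threshold: float = 1e6) -> float | None:
    """Scan a sampled trajectory of membrane-PIN sup-norms for a blow-up
    signature: the norm crosses ``threshold`` while its growth accelerates.

    Returns the extrapolated escape time, or None when no signature is found
    (e.g. for linear growth, which never accelerates past the threshold with
    a collapsing time-to-double).
    """
    times = np.asarray(times, dtype=float)
    p_norm = np.asarray(p_norm, dtype=float)
    if times.shape != p_norm.shape or times.size < 3:
        raise FluxModelError("need matching time and norm samples (>= 3)")
    above = np.nonzero(p_norm >= threshold)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k < 2:
        return None
    # superlinear growth check: log-slope increasing toward the crossing
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(p_norm[: k + 1], 1e-300))
    dt = np.diff(times[: k + 1])
    rate = np.diff(lp) / np.where(dt > 0, dt, np.inf)
    if rate.size < 2 or not rate[-1] > 1.5 * max(rate[0], 1e-12):
        return None
    # p ~ 1/(delta - t)  =>  delta ≈ t_k + 1 / d(log p)/dt
    return float(times[k] + 1.0 / rate[-1])


def run_with_cutoff(variant: str, tissue: TissueGraph, params: ModelParams,
                    phi: ResponseFunction, init: State, p_max: float,
                    options: IntegratorOptions = IntegratorOptions()) -> SimulationResult:
    """Integrate with membrane PIN clamped at ``p_max``.

    This reproduces the bounded behaviour of earlier simulation studies that
    imposed a cut-off on PIN concentrations; it never reports divergence and
    does not reflect the model's intrinsic (possibly finite-time divergent)
    dynamics.
    """
    if p_max < 0:
        raise FluxModelError("p_max must be nonnegative")
    opts = replace(options, p_max=p_max)
    init_clamped = init.copy()
    init_clamped.p = np.minimum(init_clamped.p, p_max)
    return integrate(variant, tissue, params, phi, init_clamped, opts)


def compare_slow_fast(tissue: TissueGraph, params: ModelParams,
                      phi: ResponseFunction, init: State,
                      eps_list: Sequence[float], t_max: float,
                      options: IntegratorOptions | None = None,
                      D0: float = 0.0, n_eval: int = 200) -> pd.DataFrame:
    """Deviation of the fast PIN-cycling (extended) model from its slow limit.

    For each ``eps`` the extended model is run with ``alpha_p/eps``,
    ``beta_p/eps`` and diffusion ``D0*eps`` from the matched initial condition
    (cytosolic pool at ``alpha_p/beta_p``), and compared with the slow-limit
    trajectory on a common time grid.  Returns a table of sup-norm deviations
    over (auxin, membrane PIN); the deviations shrink as ``eps`` does.

    Raises when the slow run itself does not converge within ``t_max``.
    """
    base = options or IntegratorOptions()
    grid_opts = replace(base, t_max=t_max, n_eval=n_eval, p_max=None)
    slow = integrate("slow", tissue, params, phi, init, grid_opts)
    if slow.status not in ("converged",) and slow.diagnostics["rhs_norm_final"] > base.conv_tol:
        raise FluxModelError(
            f"slow-limit run did not converge (status={slow.status}); "
            "cannot anchor the comparison")

    rows = []
    for eps in eps_list:
        fast_params = apply_eps_scaling(params, eps, D0=D0)
        fast_init = State(init.a.copy(), init.p.copy(),
                          np.full(tissue.n_cells, fast_params.pin_pool))
        fast = integrate("extended", tissue, fast_params, phi, fast_init, grid_opts)
        nt = min(slow.times.size, fast.times.size)
        M = tissue.n_cells
        slow_ap = slow.trajectory[:, :nt]                      # [a, p]
        fast_a = fast.trajectory[:M, :nt]
        fast_p = fast.trajectory[2 * M:, :nt]
        dev = float(np.max(np.abs(np.vstack([fast_a, fast_p]) - slow_ap)))
        rows.append({"eps": float(eps), "deviation": dev,
                     "fast_status": fast.status, "n_common": int(nt)})
    return pd.DataFrame(rows)
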