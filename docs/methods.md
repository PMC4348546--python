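# Methods

## The model

`fluxcanal` simulates flux-based auxin canalization on a tissue represented
as an undirected graph G = (V, E) of M cells.  Cell i holds an auxin
concentration a_i (mol m⁻³); each *ordered* adjacent pair (i, j) holds a
membrane PIN concentration p_ij (mol m⁻²) — the efflux carriers in the
membrane of cell i facing cell j.  p_ij and p_ji are independent state
variables (2m values for m membranes).

Auxin crosses the membrane between i and j with net flux

    J_{i→j} = γ_D (a_i − a_j) + γ_A (a_i p_ij − a_j p_ji),

a Fickian term plus PIN-mediated active transport.  Both terms are exactly
antisymmetric, so transport conserves total auxin Σ V_i a_i whenever
production and degradation are off (asserted to machine precision in the
tests).

Three variants share this flux law:

* **full** — `da_i/dt = α_ai − β_ai a_i − (1/V_i) Σ_j S_ij J_{i→j}`,
  `dp_ij/dt = h(J_{i→j}) + ρ₀ − μ p_ij`.  The response function h is
  *rectified* (h(J) = 0 for J ≤ 0) and nondecreasing: membranes gain PIN in
  proportion to the outgoing flux they carry.  This positive feedback is the
  canalization mechanism.
* **extended** — adds a cytosolic PIN pool P_i.  Insertion consumes the pool
  at rate λ P_i h(J); removal (rate μ) returns it.  With α_p = β_p = 0 the
  per-cell total P_i + (1/V_i) Σ_j S_ij p_ij is conserved *identically*: the
  implementation computes the insertion/removal terms once and reuses them
  with opposite signs, so the conservation rate evaluates to exactly 0.0 in
  floating point, not merely below a tolerance.
* **slow** — the fast-PIN-cycling, zero-diffusion limit on a regular tissue
  (all V_i and S_ij equal; transport rate normalized to 1):
  `da_i/dt = α_ai − β_ai a_i + Σ_k (a_k p_ki − a_i p_ik)`,
  `dp_ij/dt = λ (α_p/β_p) Φ(J_{i→j}) − μ p_ij`.
  Basal insertion ρ₀ is deliberately absent here: steady-state orientation
  analysis relies on membranes being able to empty completely.

Response families: linear κx/J_ref, quadratic κ(x/J_ref)², Hill
ρxⁿ/(θⁿ + xⁿ) (bounded), power ρxⁿ.  Defaults κ = J_ref = 1 (dimensionless
working units); all inputs are treated as consistent user units with no
conversion layer.  For a regular tissue, `normalize_params` returns
D = γ_D W, T = γ_A W and Φ(x) = h(x/W) with W = S/V; the composite constant

    c = λ α_p / (μ β_p)

is the single parameter controlling steady-state PIN levels (p* = c Φ(J*))
and is invariant under the fast-cycling scaling α_p → α_p/ε, β_p → β_p/ε,
D → D₀ε.

## Integration and outcome classification

Trajectories are integrated with SciPy's stiff-capable solvers (LSODA;
BDF with a structural Jacobian sparsity pattern for systems above 150
variables, e.g. the 402-variable 8×11 grid).  Termination is event-driven:

* **converged** when ‖rhs‖∞ < 10⁻⁸ (default; tightened to 10⁻¹¹ where a
  closed form is being verified);
* **diverged** when any membrane PIN crosses 10⁶ (default) while growing.
  For the quadratic feedback ṗ ≈ K p² near blow-up, so the escape time is
  extrapolated as δ ≈ t_event + p/ṗ; because p grows like 1/(δ − t), the
  estimate moves by only ~10⁻⁶ relative when the threshold is raised from
  10⁶ to 10⁷ — the 5% robustness asserted in the tests is conservative.
  Blow-up is *detected*, never proven; the model's dichotomy (solutions are
  global for bounded Φ, otherwise global or finite-time divergent) justifies
  reading the signature as divergence for unbounded Φ.
* **oscillating** when, over the trailing 20% of the run, some variable's
  amplitude exceeds 10⁻⁴ of its scale while the means of the two halves of
  that window differ by less than a quarter of the amplitude (swing without
  drift).  A decaying transient fails the drift test; a constant fails the
  amplitude test.
* **reached_t_max** otherwise.

The legacy cut-off mode clamps p at p_max (insertion zeroed at the cap,
projection onto [0, p_max] on the stored trajectory).  It reproduces the
bounded behaviour of earlier simulation practice and never reports
divergence; it is not the model's intrinsic dynamics.  On the two-cell
blow-up benchmark the clamped flow actually settles on an interior
equilibrium *below* the cap — the cap only needs to catch the transient.

Determinism: all randomness enters through explicit seeds in scenario
construction; the integrator itself is deterministic, and identical inputs
reproduce trajectories bitwise.

## Steady states and their topology

Because Φ is rectified, any slow-model equilibrium satisfies
min(p*_ij, p*_ji) = 0 on every membrane (complementarity).  Reading the
nonzero directions yields an oriented subgraph G*; cells with no oriented
membrane form the isolated set I*.  Orientation extraction uses a relative
threshold 10⁻⁶ · max(1, max p) so it survives unit rescaling, and raises an
error (listing the offending membranes) if both directions carry PIN.

For the quadratic response the topology of G* constrains stability: an
equilibrium is linearly unstable if G* has no sink, contains a directed
cycle, or gives any cell out-degree > 1.  `classify_topology` applies these
as a *falsifier* — verdict `certified_unstable` — and otherwise reports
`necessary_conditions_met`, which is never a stability certificate; stability
claims always come from the spectrum of the (central finite-difference)
Jacobian.  The rectified quadratic is C¹ with Φ′(0) = 0, so the Jacobian is
well defined at the kink.  The all-isolated state E₀ (a_i = α_ai/β_ai,
p ≡ 0) is an equilibrium for any parameters and is spectrally stable in
every random draw tested.  With a bounded (Hill) response the constraint
disappears: the package constructs a rotationally symmetric directed
4-cycle on a 2×2 grid that is spectrally stable and is reached by forward
integration from a perturbed start — loops are possible exactly where the
quadratic response forbids them.

`construct_equilibrium` builds equilibria with a prescribed orientation by
exploiting the membrane fixed point: on an active membrane p = c Φ(a_i p)
with Φ(x) = x² forces p = 1/(c a_i²) and flux J = 1/(c a_i), leaving only
the cell balances, solved by Newton iteration.

### Sink-driven systems

With a single degrading cell i₀ (β = 0 elsewhere) the steady orientation is
a spanning in-tree rooted at i₀.  Writing A(i) for the total production of
the subtree draining through i, flux balance gives J_out(i) = A(i), hence

    a_i = 1 / (c · A(i))   (i ≠ i₀),    a_{i₀} = A(i₀) / β_{i₀},

with membrane PIN p = c A(i)² on the edge out of i.  Subtree sums are
accumulated in one bottom-up pass.  Auxin therefore *decreases* along every
path into the sink (the sums grow), producing the depletion zone around it,
while the sink cell itself holds the whole tree's production over its
degradation rate.

Spectral analysis of these equilibria produced a finding worth recording:
they are only locally stable when PIN turnover is slow.  At μ = λ = 0.1,
8 of 20 random in-trees (≤ 12 nodes, c = 1) are unstable; at μ = λ = 0.01
all 20 are stable with leading eigenvalue −μ.  The exactness check therefore
runs the ensemble at μ = λ = 0.01 (the same cycling rates as the
source-driven line scenario), perturbs the closed-form state by 1% and
integrates to ‖rhs‖∞ < 10⁻¹¹; agreement is ~10⁻⁹ relative, far inside the
10⁻⁶ tolerance asserted.  The sink-driven *line* scenario (20 cells, sink at
cell index 9, uniform production 0.1 — both assumptions, as the original
experiment prints neither production nor cycling rates) sits on the other
side of this boundary: at μ = λ = 0.02 the in-tree equilibrium has a complex
unstable eigenvalue pair, and a run started at the equilibrium with 1%
jitter develops large sustained auxin oscillations around it instead of
converging.  The fate is seed-dependent — other jitter directions lose the
drainage pattern and accumulate auxin linearly — so the oscillation test is
a documented seeded demonstration (seed 2), and with an unbounded response
the oscillatory run eventually ends in finite-time PIN divergence.

### Source-driven systems

With uniform α, β and one over-producing cell (α₀ > α), the vein is a
directed chain i₀ → … → i_n.  On each chain edge p_k = 1/(c a_k²) and
J_k = 1/(c a_k), so each cell balance is a scalar quadratic in a_k given the
inflow from upstream: the solver is an exact recursion along the chain with
backtracking over the two roots (continuation in chain length), preferring
the smaller-auxin / larger-flux root — the branch forward integration
selects in both regimes.  Failure to find a real positive branch is returned
as a `no_solution` status, not an exception; for weak sources the full-span
chain indeed has no steady state and the emergent vein is short.

Regimes: **A** — auxin at or above background α/β and nondecreasing along
the vein (weak sources); **B** — at or below background and nonincreasing
(strong sources), *excluding the terminal sink cell*: its balance
a_n = (α + J_in)/β ≥ α/β forces it above background in either regime, so the
canal proper is the preceding cells.  The degenerate constant profile
satisfies both chains of inequalities and is reported as A with a
degeneracy flag.  `regime_map` sweeps (α, α₀) grids; steady states depend on
λ, μ only through c, so jointly rescaling λ and μ leaves the map unchanged
(asserted).  The printed premise "α₀ ≥ 2βc > α" is typographically ambiguous
in its middle term; `source_condition` exposes the candidate readings
(2β/c, 2βc, 2√(β/c) — the last is the existence threshold of the
source-cell quadratic) as a documented predicate instead of hard-coding one
into the solver.

## Scenarios and initial conditions

All study conditions are built programmatically (`scenarios` module); there
is no external data.  Printed parameters are used verbatim: the 8×11 grid
(88 cells) with two 3-cell patches producing 2.1 against a 0.1 background,
β = 5, λ = 5, μ = 0.1; the 20-cell source line with α = β = 0.1,
λ = μ = 0.01 and α₀ ∈ {0.9, 3.1}.  Values the sources leave open were fixed
once: cytosolic pool α_p/β_p = 1 everywhere (hence c = λ/μ, giving the
stated c = 1 on the line and c = 50 on the grid); patch placement (only
"two groups of 3 cells" is printed) defaults to two horizontal runs and is
configurable, so grid assertions are topological, never position-sensitive.

Initial conditions need care because E₀ is asymptotically stable: a zero
(or multiplicatively jittered zero) membrane-PIN state can never canalize.
A membrane out of cell i nucleates only above the threshold p > 1/(c a_i²)
of the scalar PIN dynamics.  Scenarios therefore start auxin at its
uncoupled fixed point α_a/β_a and membrane PIN at a small homogeneous load
with 1% seeded jitter for symmetry breaking; the load (0.1 on the line,
0.3 on the grid) is sized from that threshold so that source-adjacent
membranes (thresholds ~0.012 and ~0.11 respectively) escape E₀'s basin
deterministically for every seed, while background membranes (thresholds
≥ 0.2 and ~50) decay.  On the grid, membrane decay outruns the nucleation
wave, so converged canals are short (each patch cell exports through one
membrane, peak PIN ≈ 210); the forest topology — the claim under test — is
unaffected.

What the generator does *not* emulate: real cell geometry or growth, influx
carriers, stochastic gene expression, or measurement noise.  Passing tests
show the transport model's mathematical behaviour under its own assumptions,
not agreement with imaging data.

## Problem sizes and numerical settings

Chosen so the whole suite runs comfortably on one CPU: grids up to 8×11
(402 ODE variables), lines of 20 cells, random in-trees ≤ 12 nodes,
20-member ensembles, 100-state conservation sweeps; t_max 2·10⁵ for the
source line (the canalization wave is sequential and slow at μ = 0.01),
5·10³ for the grid, 3·10⁴ for sink trees.  Solver tolerances default to
rtol 10⁻⁸ / atol 10⁻¹⁰ (10⁻¹⁰/10⁻¹² for closed-form verification).  The
ε-reduction check runs the extended model at ε ∈ {0.1, 0.01, 0.001} against
the slow limit on a shared 200-point grid; deviations fall linearly with ε
(≈ 4·10⁻³ → 4·10⁻⁵).

## Known limitations

* Stability verdicts are numerical (finite-difference spectra at tolerance
  10⁻⁶ on eigenvalue real parts); no symbolic certificates.
* Blow-up detection is a signature, not a proof, and the escape-time
  estimate assumes the quadratic local growth law.
* The oscillation detector is a heuristic on sampled trajectories; phase
  drift slower than the window length reads as stationary.
* `solve_source_chain` follows the forward-integration branch; other
  (unstable) chain branches exist and are not enumerated.
* The slow variant requires a regular tissue by construction; non-regular
  tissues must use the full or extended variants.
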