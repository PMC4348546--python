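"""Unit tests for the core model: fluxes, response functions, right-hand sides."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxcanal import (
    ConfigurationError,
    ModelParams,
    ResponseFunction,
    State,
    StructuralError,
    TissueGraph,
    UnsupportedVariantError,
    active_flux,
    apply_eps_scaling,
    diffusive_flux,
    eval_response,
    make_grid,
    normalize_params,
    pin_conservation_rate,
    rhs_extended,
    rhs_full,
    rhs_slow,
    total_cell_pin,
)

finite = st.floats(-1e6, 1e6, allow_nan=False)
nonneg = st.floats(0, 1e3, allow_nan=False)


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def test_diffusive_flux_values():
    assert diffusive_flux(2, 2, 5) == 0
    assert diffusive_flux(3, 1, 0.5) == 1.0


@given(finite, finite, st.floats(0, 100, allow_nan=False))
def test_diffusive_flux_antisymmetric(ai, aj, gd):
    assert diffusive_flux(ai, aj, gd) == -diffusive_flux(aj, ai, gd)


def test_active_flux_values():
    assert active_flux(1, 1, 1, 1, 1) == 0
    assert active_flux(2, 1, 3, 0, 1) == 6
    # an empty cell can only import
    assert active_flux(0, 2.0, 5.0, 1.5, 1.0) == -3.0 <= 0


@given(nonneg, nonneg, nonneg, nonneg, st.floats(0, 100, allow_nan=False))
def test_active_flux_antisymmetric(ai, aj, pij, pji, ga):
    assert active_flux(ai, aj, pij, pji, ga) == -active_flux(aj, ai, pji, pij, ga)


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

ALL_KINDS = [
    ResponseFunction.linear(kappa=2.0, j_ref=0.5),
    ResponseFunction.quadratic(),
    ResponseFunction.hill(rho=1.0, theta=1.0, n=2.0),
    ResponseFunction.power(rho=0.7, n=3.0),
]


@pytest.mark.parametrize("phi", ALL_KINDS, ids=lambda p: p.kind)
def test_response_rectified_and_monotone(phi):
    xs = np.linspace(-5.0, 5.0, 101)
    vals = phi(xs)
    assert np.all(vals[xs <= 0] == 0.0)
    assert np.all(np.diff(vals) >= -1e-15)
    assert np.all(vals >= 0)


def test_response_examples():
    quad = ResponseFunction.quadratic()
    assert eval_response(quad, -3.0) == 0.0
    assert eval_response(quad, 2.0) == 4.0
    hill = ResponseFunction.hill(rho=1.0, theta=1.0, n=2.0)
    assert eval_response(hill, 1e9) == pytest.approx(1.0, abs=1e-12)


def test_boundedness_flags():
    assert ResponseFunction.hill().bounded
    assert not ResponseFunction.linear().bounded
    assert not ResponseFunction.quadratic().bounded
    assert not ResponseFunction.power(n=1.0).bounded


def test_response_derivative_matches_finite_difference():
    xs = np.array([0.3, 1.0, 2.7])
    h = 1e-7
    for phi in ALL_KINDS:
        fd = (phi(xs + h) - phi(xs - h)) / (2 * h)
        assert np.allclose(phi.derivative(xs), fd, rtol=1e-5)
        assert phi.derivative(-1.0) == 0.0


def test_response_bad_config_rejected():
    with pytest.raises(ConfigurationError):
        ResponseFunction(kind="cubic")
    with pytest.raises(ConfigurationError):
        ResponseFunction.quadratic(kappa=-1.0)


# ---------------------------------------------------------------------------
# tissue graph
# ---------------------------------------------------------------------------

def test_tissue_structure_and_roundtrip():
    t = TissueGraph(3, [(0, 1), (1, 2)], volumes=[1.0, 2.0, 1.0], areas=[0.5, 0.25])
    assert t.n_edges == 2
    assert t.pair_index(0, 1) ^ 1 == t.pair_index(1, 0)
    assert sorted(t.neighbors(1)) == [0, 2]
    assert not t.regular
    t2 = TissueGraph.from_json(t.to_json())
    assert t2 == t
    g = t.to_networkx()
    assert g.number_of_edges() == 2 and g.edges[0, 1]["area"] == 0.5


def test_tissue_invariants_enforced():
    with pytest.raises(StructuralError):
        TissueGraph(2, [(0, 0)])
    with pytest.raises(StructuralError):
        TissueGraph(2, [(0, 3)])
    with pytest.raises(StructuralError):
        TissueGraph(2, [(0, 1)], volumes=[1.0, -1.0])
    with pytest.raises(UnsupportedVariantError):
        TissueGraph(2, [(0, 1)], volumes=[1.0, 2.0]).W


def test_regular_tissue_W():
    t = TissueGraph(2, [(0, 1)], volumes=[2.0, 2.0], areas=[0.5])
    assert t.regular and t.W == 0.25


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def test_full_rhs_matches_hand_computation(two_cell):
    """Independent scalar evaluation of the full model on two cells."""
    params = ModelParams(alpha_a=np.array([1.0, 0.3]), beta_a=np.array([0.2, 0.1]),
                         gamma_D=0.5, gamma_A=2.0, rho0=0.05, mu=0.3)
    phi = ResponseFunction.quadratic(kappa=1.5)
    a = np.array([3.0, 1.0])
    p = np.array([0.5, 0.2])   # p[0] = p_01, p[1] = p_10
    d = rhs_full(State(a, p), two_cell, params, phi)

    J01 = 0.5 * (3.0 - 1.0) + 2.0 * (3.0 * 0.5 - 1.0 * 0.2)
    J10 = -J01
    da0 = 1.0 - 0.2 * 3.0 - J01
    da1 = 0.3 - 0.1 * 1.0 - J10
    dp01 = 1.5 * J01 ** 2 + 0.05 - 0.3 * 0.5
    dp10 = 0.0 + 0.05 - 0.3 * 0.2
    assert np.allclose(d.a, [da0, da1], rtol=1e-14)
    assert np.allclose(d.p, [dp01, dp10], rtol=1e-14)


def test_full_homogeneous_zero_pin_is_equilibrium(grid3, quad):
    params = ModelParams(alpha_a=0.6, beta_a=0.3, gamma_D=0.2, rho0=0.0, mu=1.0)
    state = State(np.full(9, 2.0), np.zeros(2 * grid3.n_edges))
    d = rhs_full(state, grid3, params, quad)
    assert np.all(d.a == 0.0) and np.all(d.p == 0.0)


@pytest.mark.parametrize("variant", ["full", "extended", "slow"])
def test_transport_conserves_total_auxin(grid3, quad, variant):
    """With production and degradation off, sum_i V_i da_i/dt vanishes."""
    rng = np.random.default_rng(42)
    tissue = grid3 if variant == "slow" else make_grid(3, 3, regular=False, seed=1)
    params = ModelParams(alpha_a=0.0, beta_a=0.0, gamma_D=0.3, mu=0.5, lam=0.7,
                         alpha_p=0.0, beta_p=1.0)
    for _ in range(5):
        a = rng.uniform(0, 2, 9)
        p = rng.uniform(0, 2, 2 * tissue.n_edges)
        if variant == "full":
            d = rhs_full(State(a, p), tissue, params, quad)
        elif variant == "extended":
            d = rhs_extended(State(a, p, rng.uniform(0, 1, 9)), tissue, params, quad)
        else:
            d = rhs_slow(State(a, p), tissue, params, quad)
        total = float(np.dot(tissue.volumes, d.a))
        assert abs(total) < 1e-12 * max(1.0, np.abs(d.a).max())


def test_extended_matches_independent_evaluator(grid3):
    """Term-by-term loop evaluation of the extended model, coded separately."""
    rng = np.random.default_rng(7)
    tissue = make_grid(3, 3, regular=False, seed=3)
    params = ModelParams(alpha_a=0.4, beta_a=0.2, gamma_D=0.1, gamma_A=1.3,
                         mu=0.6, lam=0.9, alpha_p=0.3, beta_p=0.5)
    phi = ResponseFunction.quadratic(kappa=0.8)
    a = rng.uniform(0, 2, 9)
    P = rng.uniform(0, 2, 9)
    p = rng.uniform(0, 2, 2 * tissue.n_edges)
    d = rhs_extended(State(a, p, P), tissue, params, phi)

    def h(x):
        return 0.8 * x * x if x > 0 else 0.0

    pair = {(int(s), int(e)): k for k, (s, e) in
            enumerate(zip(tissue.pair_src, tissue.pair_dst))}
    area = {tuple(sorted(e)): tissue.areas[k] for k, e in enumerate(map(tuple, tissue.edges))}
    for i in range(9):
        da = 0.4 - 0.2 * a[i]
        dP = 0.3 - 0.5 * P[i]
        for j in tissue.neighbors(i):
            S = area[tuple(sorted((i, j)))]
            J = 0.1 * (a[i] - a[j]) + 1.3 * (a[i] * p[pair[(i, j)]] - a[j] * p[pair[(j, i)]])
            da -= S * J / tissue.volumes[i]
            dP += S * (0.6 * p[pair[(i, j)]] - 0.9 * P[i] * h(J)) / tissue.volumes[i]
        assert d.a[i] == pytest.approx(da, rel=1e-12, abs=1e-12)
        assert d.P[i] == pytest.approx(dP, rel=1e-12, abs=1e-12)
    for (i, j), k in pair.items():
        J = 0.1 * (a[i] - a[j]) + 1.3 * (a[i] * p[k] - a[j] * p[pair[(j, i)]])
        assert d.p[k] == pytest.approx(0.9 * P[i] * h(J) - 0.6 * p[k], rel=1e-12, abs=1e-12)


def test_slow_zero_pin_state_is_exact_equilibrium(grid3, quad):
    alpha = np.linspace(0.2, 1.0, 9)
    beta = np.linspace(0.5, 1.3, 9)
    params = ModelParams(alpha_a=alpha, beta_a=beta, mu=0.4, lam=0.7)
    e0 = State(alpha / beta, np.zeros(2 * grid3.n_edges))
    d = rhs_slow(e0, grid3, params, quad)
    assert np.all(d.a == 0.0) and np.all(d.p == 0.0)


def test_slow_isolated_cell_decouples(quad):
    t = TissueGraph(3, [(0, 1), (1, 2)])
    params = ModelParams(alpha_a=0.8, beta_a=0.4, mu=1.0, lam=1.0)
    a = np.array([1.5, 2.0, 0.3])
    p = np.zeros(4)
    p[t.pair_index(1, 2)] = 0.7   # cell 0 keeps all incident membranes empty
    d = rhs_slow(State(a, p), t, params, quad)
    assert d.a[0] == pytest.approx(0.8 - 0.4 * 1.5, rel=1e-14)


def test_slow_rejects_non_regular_tissue(quad):
    t = TissueGraph(2, [(0, 1)], volumes=[1.0, 2.0])
    with pytest.raises(UnsupportedVariantError):
        rhs_slow(State(np.ones(2), np.zeros(2)), t, ModelParams(), quad)


def test_flux_antisymmetry_in_rhs_is_exact(grid3, quad):
    """J_{i->j} = -J_{j->i} bit-for-bit, both flux components."""
    from fluxcanal.model import _pair_flux
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 3, 9)
    p = rng.uniform(0, 3, 2 * grid3.n_edges)
    J = _pair_flux(grid3, a, p, 0.37, 1.21)
    assert np.all(J == -J[grid3.pair_rev])


# ---------------------------------------------------------------------------
# conservation and normalization
# ---------------------------------------------------------------------------

def test_pin_conservation_identity_is_exact(grid3, quad):
    """dP_i/dt + (1/V_i) sum_j S_ij dp_ij/dt == 0 when alpha_p = beta_p = 0."""
    params = ModelParams(alpha_a=0.5, beta_a=0.2, mu=0.8, lam=1.1,
                         alpha_p=0.0, beta_p=0.0)
    rng = np.random.default_rng(11)
    for _ in range(20):
        state = State(rng.uniform(0, 3, 9), rng.uniform(0, 3, 2 * grid3.n_edges),
                      rng.uniform(0, 3, 9))
        rate = pin_conservation_rate(state, grid3, params, quad)
        assert np.max(np.abs(rate)) < 1e-12


def test_total_cell_pin_values(two_cell):
    state = State(np.ones(2), np.zeros(2), np.array([1.0, 0.5]))
    assert total_cell_pin(state, two_cell, 0) == 1.0
    state2 = State(np.ones(2), np.array([2.0, 0.0]), np.array([1.0, 0.5]))
    assert total_cell_pin(state2, two_cell, 0) == 3.0   # P + S*p/V with S=V=1


def test_normalization():
    t = TissueGraph(2, [(0, 1)], volumes=[2.0, 2.0], areas=[1.0])  # W = 0.5
    h = ResponseFunction.quadratic(kappa=1.0, j_ref=1.0)
    params = ModelParams(gamma_D=2.0, gamma_A=3.0, mu=0.5, lam=1.0,
                         alpha_p=2.0, beta_p=1.0)
    nm = normalize_params(t, params, h)
    assert nm.D == pytest.approx(1.0)
    assert nm.T == pytest.approx(1.5)
    xs = np.linspace(-2, 4, 31)
    assert np.allclose(nm.phi(xs), h(xs / 0.5))
    # W = 1 leaves the response untouched
    t1 = TissueGraph(2, [(0, 1)])
    assert np.allclose(normalize_params(t1, params, h).phi(xs), h(xs))


@pytest.mark.parametrize("phi", ALL_KINDS, ids=lambda p: p.kind)
def test_scaled_input_equals_composition(phi):
    xs = np.linspace(-1, 5, 40)
    assert np.allclose(phi.scaled_input(0.4)(xs), phi(xs / 0.4), rtol=1e-12)


@pytest.mark.parametrize("eps", [0.1, 0.003, 17.0])
def test_eps_scaling_preserves_c(eps):
    params = ModelParams(mu=0.5, lam=2.0, alpha_p=3.0, beta_p=1.5, gamma_D=0.2)
    scaled = apply_eps_scaling(params, eps, D0=0.7)
    assert scaled.c == pytest.approx(params.c, rel=1e-14)
    assert scaled.gamma_D == pytest.approx(0.7 * eps)


def test_state_validation(two_cell):
    with pytest.raises(StructuralError):
        State(np.ones(3), np.zeros(2)).check(two_cell)
    with pytest.raises(StructuralError):
        State(np.ones(2), -np.ones(2)).check(two_cell)
    with pytest.raises(StructuralError):
        State(np.ones(2), np.zeros(2)).check(two_cell, "extended")
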