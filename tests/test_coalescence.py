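"""Coalescence engine: meeting times, N_eff, closed forms, perturbations."""

import numpy as np
import pytest

from coalfix.coalescence import (
    closed_form_neff_fan,
    closed_form_neff_sh_limit,
    closed_form_neff_si_limit,
    coalescence_times,
    construct_amplifier,
    covariance_identity_residual,
    effective_population_size,
    er_meanfield_ratio,
    meanfield_neff,
    neff_gradient,
    remeeting_times,
    weak_selection_fixation,
)
from coalfix.graphs import (
    DisconnectedGraphError,
    InvalidParameterError,
    WeightedGraph,
    make_complete,
    make_cycle,
    make_erdos_renyi,
    make_fan,
    make_random_regular,
    make_separated_hubs,
    make_star,
    make_star_of_islands,
)


@pytest.mark.parametrize("N", [3, 5, 8])
def test_complete_graph_pair_times(N):
    """On K_N symmetry forces tau_ij = N-1 off-diagonal, tau_i = N."""
    G = make_complete(N)
    tau = coalescence_times(G)
    off = tau[~np.eye(N, dtype=bool)]
    assert np.allclose(off, N - 1, atol=1e-10)
    assert np.allclose(np.diag(tau), 0.0)
    assert np.allclose(remeeting_times(G, tau), N, atol=1e-10)


def test_cycle4_hand_solved_values():
    """C_4 reduces to two unknowns: adjacent pairs meet in 3, antipodal in 4."""
    tau = coalescence_times(make_cycle(4))
    assert tau[0, 1] == pytest.approx(3.0, abs=1e-10)
    assert tau[0, 2] == pytest.approx(4.0, abs=1e-10)
    assert tau[1, 2] == pytest.approx(3.0, abs=1e-10)


@pytest.mark.parametrize("n", [2, 3, 5, 9])
def test_star_effective_size(n):
    """Star: tau_hub = tau_leaf = N_eff = 4n/(n+1) — a weak-selection suppressor."""
    res = effective_population_size(make_star(n))
    expected = 4 * n / (n + 1)
    assert np.allclose(res.tau_remeet, expected, atol=1e-9)
    assert res.n_eff == pytest.approx(expected, abs=1e-9)
    assert res.n_eff < n + 1


def test_star_of_islands_published_value():
    res = effective_population_size(make_star_of_islands(2, 3, 3, 0.1))
    assert res.n_eff == pytest.approx(8.89, abs=0.005)


MIXED_GRAPHS = [
    make_complete(6),
    make_star(5),
    make_cycle(7),
    make_fan(3, 2, 0.1),
    make_separated_hubs(3, 2, 2, 0.05),
    make_star_of_islands(2, 3, 3, 0.1),
    make_erdos_renyi(25, 5.0, seed=11),
    make_random_regular(14, 3, seed=4),
]


@pytest.mark.parametrize("G", MIXED_GRAPHS, ids=lambda g: g.meta["family"])
def test_kac_identity(G):
    """sum_i pi_i^2 tau_i = 1 for every connected graph."""
    res = effective_population_size(G)
    assert res.kac_residual <= 1e-8


@pytest.mark.parametrize("G", MIXED_GRAPHS, ids=lambda g: g.meta["family"])
def test_covariance_identity(G):
    """(N - N_eff)/N^2 equals cov(pi_i, pi_i tau_i) over vertices."""
    assert covariance_identity_residual(G) <= 1e-10


def test_covariance_sign_tracks_weak_classification():
    # complete graph: all pi equal, covariance exactly 0
    res = effective_population_size(make_complete(6))
    assert res.n_eff == pytest.approx(6.0, abs=1e-10)
    # star: suppressor => positive covariance (N_eff < N)
    assert effective_population_size(make_star(5)).n_eff < 6
    # near-limit Fan: amplifier => negative covariance (N_eff > N)
    assert effective_population_size(make_fan(4, 2, 1e-3)).n_eff > 9


ISOTHERMAL_GRAPHS = (
    [make_cycle(N) for N in range(3, 9)]
    + [make_complete(N) for N in range(3, 9)]
    + [make_random_regular(8, 3, seed=s) for s in range(2)]
    + [make_random_regular(10, 4, seed=s) for s in range(2)]
    + [
        make_fan(n, m, (m - 1) / (n * m - 1))
        for n, m in [(2, 2), (3, 2), (2, 3), (3, 3)]
    ],
)[0]


def test_weak_selection_isothermal_theorem():
    """Isothermal graphs have N_eff = N: they neither amplify nor suppress."""
    assert len(ISOTHERMAL_GRAPHS) >= 20
    for G in ISOTHERMAL_GRAPHS:
        res = effective_population_size(G)
        assert abs(res.n_eff - G.N) <= 1e-8, G.meta


def test_weak_selection_expansion():
    G = make_complete(8)
    ws = weak_selection_fixation(G)
    assert ws.slope == pytest.approx((8 - 2) / 16)
    assert ws.rho_at(0.0) == pytest.approx(1 / 8)
    # star: expansion 1/N + delta (N-2)/N^2, i.e. slope (N-2)/N^2
    n = 5
    ws = weak_selection_fixation(make_star(n))
    N = n + 1
    assert ws.slope == pytest.approx((N - 2) / N**2, abs=1e-10)


@pytest.mark.parametrize(
    "n,m,eps", [(3, 2, 0.05), (2, 2, 1 / 3), (4, 3, 0.2), (2, 5, 0.6)]
)
def test_fan_closed_form_matches_solver(n, m, eps):
    cf = closed_form_neff_fan(n, m, eps)
    num = effective_population_size(make_fan(n, m, eps)).n_eff
    assert cf == pytest.approx(num, abs=1e-8)


def test_fan_closed_form_limits():
    # isothermal point: correction vanishes, N_eff = N exactly
    assert closed_form_neff_fan(4, 3, 2 / 11) == pytest.approx(13.0, abs=1e-12)
    # eps -> 0 limit
    assert closed_form_neff_fan(4, 3, 0.0) == 15.0
    # amplification window: N_eff > N for 0 < eps < (m-1)/(nm-1)
    assert closed_form_neff_fan(3, 2, 0.1) > 7
    assert closed_form_neff_fan(3, 2, 0.5) < 7


def test_sh_si_limit_closed_forms():
    # SH limit independent of h; small-eps solver agrees to O(eps)
    assert closed_form_neff_sh_limit(3, 2, 2) == 8.0
    assert closed_form_neff_sh_limit(3, 2, 5) == 8.0
    num = effective_population_size(make_separated_hubs(3, 2, 2, 1e-6)).n_eff
    assert abs(num - 8.0) < 1e-3
    # SI: m = h makes the correction vanish; sign follows m - h
    assert closed_form_neff_si_limit(3, 4, 4) == 16.0
    assert closed_form_neff_si_limit(3, 4, 2) > 14
    assert closed_form_neff_si_limit(3, 2, 4) < 10
    num = effective_population_size(make_star_of_islands(2, 3, 3, 1e-6)).n_eff
    assert abs(num - closed_form_neff_si_limit(2, 3, 3)) < 1e-3


def test_meanfield_approximation():
    # exact on isothermal graphs
    assert meanfield_neff(make_cycle(8)) == pytest.approx(8.0, abs=1e-10)
    # star: mu1 = 2n/(n+1), mu2 = n => N mu1^2/mu2 = 4n/(n+1)
    n = 7
    assert meanfield_neff(make_star(n)) == pytest.approx(4 * n / (n + 1), abs=1e-10)
    # never exceeds N
    for G in MIXED_GRAPHS:
        assert meanfield_neff(G) <= G.N + 1e-10


def test_er_meanfield_ratio():
    assert er_meanfield_ratio(10, 1.0) == pytest.approx(1.0)
    assert er_meanfield_ratio(20, 4 / 19) == pytest.approx(
        19 * (4 / 19) / (18 * (4 / 19) + 1)
    )
    with pytest.raises(InvalidParameterError):
        er_meanfield_ratio(10, 1.5)


def test_neff_gradient_uniform_scaling_is_flat():
    """Scaling all weights leaves pi unchanged, so the gradient vanishes."""
    G = make_cycle(6)
    perturb = {(i, j): w for i, j, w in G.edges()}
    assert neff_gradient(G, perturb) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize(
    "G0", [make_cycle(6), make_random_regular(10, 3, seed=3)], ids=["C6", "RRG"]
)
def test_neff_gradient_matches_finite_difference(G0):
    grad = neff_gradient(G0, {(0, int(np.nonzero(G0.w[0])[0][0])): -1.0})
    j = int(np.nonzero(G0.w[0])[0][0])
    h = 1e-5
    vals = []
    for sgn in (+1, -1):
        Gp = G0.copy()
        Gp.w[0, j] -= sgn * h
        Gp.w[j, 0] -= sgn * h
        vals.append(effective_population_size(Gp).n_eff)
    fd = (vals[0] - vals[1]) / (2 * h)
    assert grad == pytest.approx(fd, abs=1e-3 * max(1.0, abs(fd)))


def test_neff_gradient_requires_isothermal():
    with pytest.raises(InvalidParameterError):
        neff_gradient(make_star(4), {(0, 1): -1.0})


def test_construct_amplifier_self_consistency():
    G0 = make_random_regular(12, 3, seed=0)
    G1, res = construct_amplifier(G0, eps=0.05)
    assert res.n_eff == pytest.approx(
        effective_population_size(G1).n_eff, abs=1e-10
    )
    assert G1.meta["amplifier_of_weak_selection"] == (res.n_eff > 12)
    # eps = 0 leaves the isothermal graph untouched: N_eff = N
    _, res0 = construct_amplifier(G0, eps=0.0)
    assert res0.n_eff == pytest.approx(12.0, abs=1e-8)


def test_construct_amplifier_produces_amplifiers_at_small_eps():
    """Down-weighting an edge at the max-remeeting-time vertex amplifies."""
    hits = 0
    for seed in range(10):
        G0 = make_random_regular(12, 3, seed=100 * seed)
        _, res = construct_amplifier(G0, eps=0.05)
        hits += res.n_eff > 12
    assert hits == 10


def test_edge_deletion_amplifier_exists():
    """Some 3-regular size-12 graph stays an amplifier with an edge deleted."""
    found = None
    for seed in range(200):
        G0 = make_random_regular(12, 3, seed=seed)
        try:
            _, res = construct_amplifier(G0, eps=1.0)
        except DisconnectedGraphError:
            continue
        if res.n_eff > 12:
            found = (seed, res.n_eff)
            break
    assert found is not None
    assert found[1] > 12.0


def test_disconnected_graph_rejected():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    with pytest.raises(DisconnectedGraphError):
        coalescence_times(WeightedGraph(w))


def test_remeeting_dimension_mismatch():
    with pytest.raises(ValueError):
        remeeting_times(make_complete(4), np.zeros((3, 3)))
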