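"""Graph constructors, degree statistics and edge-list round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalfix.graphs import (
    DegenerateVertexError,
    EdgeListFormatError,
    InvalidParameterError,
    InvalidSizeError,
    WeightedGraph,
    degree_moments,
    graph_from_json,
    graph_to_json,
    is_isothermal,
    make_barabasi_albert,
    make_complete,
    make_cycle,
    make_erdos_renyi,
    make_fan,
    make_random_regular,
    make_separated_hubs,
    make_star,
    make_star_of_islands,
    read_edgelist,
    stationary_distribution,
    step_probabilities,
    weighted_degrees,
    write_edgelist,
)

ALL_CONSTRUCTORS = [
    make_complete(5),
    make_star(4),
    make_cycle(6),
    make_fan(3, 3, 0.5),
    make_separated_hubs(3, 2, 2, 0.1),
    make_star_of_islands(2, 3, 3, 0.1),
    make_erdos_renyi(15, 4.0, seed=1),
    make_barabasi_albert(15, 3, seed=1),
    make_random_regular(12, 3, seed=1),
]


@pytest.mark.parametrize("G", ALL_CONSTRUCTORS, ids=lambda g: g.meta["family"])
def test_constructor_invariants(G):
    """Symmetry, zero diagonal and connectivity hold for every family."""
    assert np.array_equal(G.w, G.w.T)
    assert np.all(np.diag(G.w) == 0)
    assert np.all(G.w >= 0)
    assert G.is_connected()


@pytest.mark.parametrize("G", ALL_CONSTRUCTORS, ids=lambda g: g.meta["family"])
def test_walk_quantities_normalized(G):
    """Step-probability rows and the stationary distribution sum to 1."""
    p = step_probabilities(G)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
    pi = stationary_distribution(G)
    assert abs(pi.sum() - 1.0) <= 1e-12
    # pi is stationary for the walk: pi P = pi
    assert np.allclose(pi @ p, pi, atol=1e-12)


def test_complete_graph_structure():
    G = make_complete(3)
    assert np.allclose(weighted_degrees(G), 2.0)
    assert make_complete(2).N == 2
    assert np.allclose(stationary_distribution(make_complete(5)), 0.2)
    with pytest.raises(InvalidSizeError):
        make_complete(1)


def test_star_structure():
    G = make_star(3)
    deg = weighted_degrees(G)
    assert deg[0] == 3 and np.all(deg[1:] == 1)
    # hub holds half the stationary mass: pi_hub = n/(2n)
    pi = stationary_distribution(make_star(9))
    assert pi[0] == pytest.approx(0.5, abs=1e-12)
    assert np.allclose(pi[1:], 1 / 18)
    with pytest.raises(InvalidSizeError):
        make_star(1)


def test_cycle_structure():
    assert np.array_equal(make_cycle(3).w, make_complete(3).w)
    G = make_cycle(6)
    assert np.allclose(weighted_degrees(G), 2.0)
    assert is_isothermal(G)
    with pytest.raises(InvalidSizeError):
        make_cycle(2)


def test_fan_structure():
    G = make_fan(3, 3, 0.5)
    assert G.N == 10
    deg = weighted_degrees(G)
    assert deg[1] == pytest.approx((3 - 1) + 0.5)  # blade vertex
    assert deg[0] == pytest.approx(9 * 0.5)  # hub
    with pytest.raises(InvalidParameterError):
        make_fan(3, 3, 0.0)


@pytest.mark.parametrize("n", [2, 3, 4, 5])
@pytest.mark.parametrize("m", [2, 3, 4, 5])
def test_fan_isothermal_point(n, m):
    """The Fan is isothermal exactly at eps = (m-1)/(nm-1)."""
    eps = (m - 1) / (n * m - 1)
    assert is_isothermal(make_fan(n, m, eps), tol=1e-12)
    assert not is_isothermal(make_fan(n, m, eps * 2), tol=1e-9)


def test_separated_hubs_structure():
    G = make_separated_hubs(3, 2, 2, 0.1)
    assert G.N == 8
    # hubs are mutually unconnected; hub degree = n*m*eps
    assert np.all(G.w[:2, :2] == 0)
    assert weighted_degrees(G)[0] == pytest.approx(6 * 0.1)
    # h=1 reduces exactly to the Fan
    assert np.array_equal(
        make_separated_hubs(3, 2, 1, 0.25).w, make_fan(3, 2, 0.25).w
    )


def test_star_of_islands_structure():
    G = make_star_of_islands(2, 3, 3, 0.1)
    assert G.N == 9
    deg = weighted_degrees(G)
    assert deg[0] == pytest.approx((3 - 1) + 6 * 0.1)  # hub vertex
    assert deg[3] == pytest.approx((3 - 1) + 3 * 0.1)  # island vertex
    with pytest.raises(InvalidSizeError):
        make_star_of_islands(2, 3, 1, 0.1)


def test_erdos_renyi_complete_at_minimum_size():
    """At N = <k>+1 the link probability is 1 and the draw is complete."""
    G = make_erdos_renyi(5, 4.0, seed=3)
    assert np.array_equal(G.w, make_complete(5).w)
    with pytest.raises(InvalidParameterError):
        make_erdos_renyi(4, 4.0, seed=3)


def test_erdos_renyi_determinism_and_mean_degree():
    a = make_erdos_renyi(20, 4.0, seed=7)
    b = make_erdos_renyi(20, 4.0, seed=7)
    assert np.array_equal(a.w, b.w)
    # empirical mean degree over many seeds matches binomial sampling
    degs = [
        weighted_degrees(make_erdos_renyi(20, 4.0, seed=s, require_connected=False)).mean()
        for s in range(100)
    ]
    se = np.std(degs, ddof=1) / 10
    assert abs(np.mean(degs) - 4.0) < 3 * se + 0.05


def test_barabasi_albert_construction():
    assert np.array_equal(make_barabasi_albert(5, 3, seed=0).w, make_complete(5).w)
    G = make_barabasi_albert(50, 3, seed=2)
    assert weighted_degrees(G).min() >= 3
    assert np.array_equal(G.w, make_barabasi_albert(50, 3, seed=2).w)
    with pytest.raises(InvalidSizeError):
        make_barabasi_albert(4, 3, seed=0)


def test_random_regular_degrees():
    with pytest.raises(InvalidParameterError):
        make_random_regular(9, 3, seed=0)  # N*k odd
    for s in range(10):
        G = make_random_regular(12, 3, seed=s)
        assert np.all(weighted_degrees(G) == 3.0)
        assert G.is_connected()
    # k=2 with connectivity enforcement is the cycle (up to relabeling)
    G = make_random_regular(8, 2, seed=1)
    assert np.all(weighted_degrees(G) == 2.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_degree_moment_inequality(seed):
    """Second moment dominates squared first moment (variance >= 0)."""
    G = make_erdos_renyi(20, 5.0, seed=seed, require_connected=False)
    if weighted_degrees(G).min() == 0:
        return
    mom = degree_moments(G)
    assert mom.mu2 >= mom.mu1**2 - 1e-12
    assert mom.mu1 > 0


def test_isolated_vertex_rejected():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    G = WeightedGraph(w)
    with pytest.raises(DegenerateVertexError):
        step_probabilities(G)
    assert not G.is_connected()


def test_edgelist_roundtrip(tmp_path):
    for G in [make_complete(4), make_fan(2, 3, 0.125), make_erdos_renyi(10, 3.0, 5)]:
        path = tmp_path / "g.tsv"
        write_edgelist(G, path)
        H = read_edgelist(path)
        assert np.array_equal(G.w, H.w)


def test_edgelist_rejects_malformed(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("0\t0\t1.0\n")
    with pytest.raises(EdgeListFormatError):
        read_edgelist(path)
    path.write_text("0\t1\t-2.0\n")
    with pytest.raises(EdgeListFormatError):
        read_edgelist(path)
    path.write_text("0\t1\t1.0\n1\t0\t2.0\n")
    with pytest.raises(EdgeListFormatError):
        read_edgelist(path)
    # both directions with equal weight: deduplicated, not an error
    path.write_text("0\t1\t1.5\n1\t0\t1.5\n")
    assert read_edgelist(path).w[0, 1] == 1.5


def test_json_roundtrip():
    G = make_star_of_islands(2, 2, 2, 0.25)
    H = graph_from_json(graph_to_json(G))
    assert np.array_equal(G.w, H.w)
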