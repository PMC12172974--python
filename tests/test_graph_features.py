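"""Segregation/integration metrics on weighted positive graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepgraph import graph

from conftest import naive_mdp_pcp, random_signed_graph


@pytest.fixture
def four_node():
    """Hand-worked 4-node graph: communities A={0,1}, B={2,3};
    w01=0.6, w02=0.2, w12=0.1, w13=0.3, w23=0.8, w03=-0.4 (removed)."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.6
    w[0, 2] = w[2, 0] = 0.2
    w[1, 2] = w[2, 1] = 0.1
    w[1, 3] = w[3, 1] = 0.3
    w[2, 3] = w[3, 2] = 0.8
    w[0, 3] = w[3, 0] = -0.4
    comm = graph.CommunityAssignment(("A", "A", "B", "B"))
    return w, comm


def test_positive_part_removes_negatives_and_is_idempotent(four_node):
    w, _ = four_node
    wp = graph.positive_part(w)
    assert wp[0, 3] == 0.0 and wp[3, 0] == 0.0
    assert wp[0, 1] == 0.6
    assert np.array_equal(graph.positive_part(wp), wp)
    assert np.array_equal(graph.positive_part(-np.abs(w)), np.zeros((4, 4)))
    nonneg = np.abs(w)
    np.fill_diagonal(nonneg, 0)
    assert np.array_equal(graph.positive_part(nonneg), nonneg)


def test_hand_worked_mdp_and_pcp(four_node):
    w, comm = four_node
    fv = graph.build_feature_vector(w, comm)
    # exhaustive hand summation: MDP = [0.6, 0.6, 0.8, 0.8]
    assert np.allclose(fv.mdp, [0.6, 0.6, 0.8, 0.8])
    # node 0: k=0.8, within 0.6, cross 0.2 -> 1 - (0.75^2 + 0.25^2)
    assert np.isclose(fv.pcp[0], 0.375)
    assert fv.values.shape == (8,)
    # ordering contract: feature j < n is MDP of node j, feature n+j its PCP
    assert np.allclose(fv.values[:4], fv.mdp) and np.allclose(fv.values[4:], fv.pcp)
    assert fv.labels()[0] == "mdp_0" and fv.labels()[4] == "pcp_0"


def test_no_positive_edges_gives_zero_features():
    comm = graph.CommunityAssignment(("A", "A", "B", "B"))
    fv = graph.build_feature_vector(-np.ones((4, 4)) + np.eye(4), comm)
    assert np.all(fv.mdp == 0) and np.all(fv.pcp == 0)


def test_single_community_limit_mdp_equals_strength():
    # all real nodes share one network; a disconnected dummy node carries
    # the second label so the >=2-networks invariant holds
    rng = np.random.default_rng(0)
    w = np.abs(rng.uniform(size=(5, 5)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    w[4, :] = w[:, 4] = 0.0
    comm = graph.CommunityAssignment(("A", "A", "A", "A", "B"))
    fv = graph.build_feature_vector(w, comm)
    assert np.allclose(fv.mdp[:4], w[:4].sum(axis=1))
    assert np.allclose(fv.pcp[:4], 0.0)  # all strength inside own network


def test_even_split_pcp_reaches_one_minus_one_over_m():
    # node 0 with equal strength into each of 3 networks -> PCP = 1 - 1/3
    w = np.zeros((7, 7))
    for j, v in [(1, 0.2), (2, 0.2), (3, 0.2)]:
        w[0, j] = w[j, 0] = v
    labels = ("A", "A", "B", "C", "A", "B", "C")
    comm = graph.CommunityAssignment(labels)
    pcp = graph.participation_coefficient_positive(graph.positive_part(w), comm)
    assert np.isclose(pcp[0], 1 - 1 / 3)


def test_matches_naive_oracle_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(5, 26))
        m = int(rng.integers(2, min(7, n)))
        w, comm = random_signed_graph(rng, n, m)
        wp = graph.positive_part(w)
        mdp = graph.within_module_degree_positive(wp, comm)
        pcp = graph.participation_coefficient_positive(wp, comm)
        mdp_o, pcp_o = naive_mdp_pcp(w, comm)
        assert np.allclose(mdp, mdp_o, atol=1e-10)
        assert np.allclose(pcp, pcp_o, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), lam=st.floats(0.1, 10.0))
def test_bounds_and_scale_behavior(seed, lam):
    """PCP in [0, 1-1/M]; MDP <= strength; weights*lam scales MDP by lam
    and leaves PCP unchanged; both invariant to node permutation."""
    rng = np.random.default_rng(seed)
    n, m = 12, 3
    w, comm = random_signed_graph(rng, n, m)
    fv = graph.build_feature_vector(w, comm)
    strength = graph.positive_part(w).sum(axis=1)
    assert np.all(fv.pcp >= 0) and np.all(fv.pcp <= 1 - 1 / m + 1e-12)
    assert np.all(fv.mdp <= strength + 1e-12)
    fv2 = graph.build_feature_vector(lam * w, comm)
    assert np.allclose(fv2.mdp, lam * fv.mdp)
    assert np.allclose(fv2.pcp, fv.pcp, atol=1e-10)
    perm = rng.permutation(n)
    comm_p = graph.CommunityAssignment(
        tuple(np.asarray(comm.node_to_network)[perm]), comm.networks
    )
    fv3 = graph.build_feature_vector(w[np.ix_(perm, perm)], comm_p)
    assert np.allclose(fv3.mdp, fv.mdp[perm]) and np.allclose(fv3.pcp, fv.pcp[perm])


def test_edge_vectorizer_roundtrip():
    rng = np.random.default_rng(1)
    w, _ = random_signed_graph(rng, 6, 2)
    v = graph.vectorize_edges(w)
    assert v.size == 15
    assert np.allclose(graph.unvectorize_edges(v, 6), w)
    # signed values retained, row-major strict upper triangle
    w3 = np.array([[0, 0.5, -0.2], [0.5, 0, 0.9], [-0.2, 0.9, 0]])
    assert np.allclose(graph.vectorize_edges(w3), [0.5, -0.2, 0.9])


def test_node_count_mismatch_errors(four_node):
    w, _ = four_node
    comm5 = graph.CommunityAssignment(("A", "A", "B", "B", "B"))
    with pytest.raises(ValueError, match="nodes"):
        graph.within_module_degree_positive(w, comm5)
    with pytest.raises(ValueError, match="nodes"):
        graph.participation_coefficient_positive(w, comm5)
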