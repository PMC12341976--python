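"""Markov clustering: matrix construction, expansion, inflation, partitions."""

import numpy as np
import pytest

from modex.mcl import (
    MCLConfig,
    build_stochastic_matrix,
    expand,
    inflate,
    node_ordering,
    run_mcl,
)

from conftest import graph_from_edges


def partition_sets(p):
    return {frozenset(c) for c in p.clusters}


def test_config_defaults():
    c = MCLConfig()
    assert (c.inflation, c.expansion, c.prune_threshold, c.max_iterations,
            c.convergence_tol) == (4.0, 2, 1e-5, 100, 1e-6)


def test_config_warns_outside_usual_inflation_range():
    with pytest.warns(UserWarning):
        MCLConfig(inflation=50.0)


def test_two_node_matrix_closed_form():
    g = graph_from_edges([("a", "b")])
    assert np.allclose(build_stochastic_matrix(g), [[0.5, 0.5], [0.5, 0.5]])


def test_isolated_node_self_loop_only():
    g = graph_from_edges([], extra_nodes=["q"])
    assert np.allclose(build_stochastic_matrix(g), [[1.0]])


def test_path_graph_column_normalization():
    # a-b-c with self-loops: b's column sums three ones, a/c two
    g = graph_from_edges([("a", "b"), ("b", "c")])
    m = build_stochastic_matrix(g)
    order = node_ordering(g)
    b = order.index("b")
    assert np.allclose(m[:, b], [1 / 3, 1 / 3, 1 / 3])
    a = order.index("a")
    assert np.allclose(sorted(m[:, a]), [0.0, 0.5, 0.5])
    assert np.allclose(m.sum(axis=0), 1.0, atol=1e-12)


def test_expand_identity_and_idempotent():
    assert np.allclose(expand(np.eye(3), 5), np.eye(3))
    half = np.full((2, 2), 0.5)
    assert np.allclose(expand(half, 2), half)


def test_expand_matches_direct_product():
    g = graph_from_edges([("a", "b"), ("b", "c")])
    m = build_stochastic_matrix(g)
    assert np.allclose(expand(m, 2), m @ m)
    assert np.allclose(expand(m, 3), m @ m @ m)


def test_inflate_hand_arithmetic():
    col = np.array([[0.8], [0.2]])
    out = inflate(col, 2.0)
    assert np.allclose(out, [[16 / 17], [1 / 17]])


def test_inflate_symmetric_and_fixed_point():
    assert np.allclose(inflate(np.array([[0.5], [0.5]]), 2.0), [[0.5], [0.5]])
    assert np.allclose(inflate(np.array([[1.0], [0.0]]), 7.0), [[1.0], [0.0]])


def test_inflate_prunes_and_renormalizes():
    col = np.array([[0.99], [0.01]])
    out = inflate(col, 2.0, prune_threshold=1e-3)
    assert out[1, 0] == 0.0 and out[0, 0] == 1.0


def test_inflate_restores_emptied_column():
    col = np.array([[0.6], [0.4]])
    out = inflate(col, 2.0, prune_threshold=0.5)  # prunes both entries
    assert np.allclose(out, [[1.0], [0.0]])


TRIANGLES = [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]


def test_disjoint_triangles_two_clusters():
    p = run_mcl(graph_from_edges(TRIANGLES), MCLConfig(inflation=4))
    assert partition_sets(p) == {frozenset("abc"), frozenset("xyz")}


def test_bridge_splits_at_bridge():
    p = run_mcl(graph_from_edges(TRIANGLES + [("c", "x")]), MCLConfig(inflation=4))
    assert partition_sets(p) == {frozenset("abc"), frozenset("xyz")}


def test_complete_graph_single_cluster():
    k4 = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
    p = run_mcl(graph_from_edges(k4), MCLConfig(inflation=2))
    assert partition_sets(p) == {frozenset("abcd")}


def _random_graph_edges(rng, n, p_edge):
    nodes = [f"n{i}" for i in range(n)]
    return [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1:]
        if rng.random() < p_edge
    ], nodes


@pytest.mark.parametrize("seed", range(8))
def test_partition_disjoint_covering_and_stochasticity(seed):
    rng = np.random.default_rng(seed)
    pairs, nodes = _random_graph_edges(rng, 10, 0.25)
    g = graph_from_edges(pairs, extra_nodes=nodes)
    m = build_stochastic_matrix(g)
    cfg = MCLConfig(inflation=4)
    for _ in range(6):
        m = inflate(expand(m, cfg.expansion), cfg.inflation, cfg.prune_threshold)
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-10)
    p = run_mcl(g, cfg)
    seen = set()
    for c in p.clusters:
        assert not (c & seen)
        seen |= c
    assert seen == g.nodes


@pytest.mark.parametrize("seed", range(5))
def test_components_never_merge(seed):
    import networkx as nx

    rng = np.random.default_rng(seed)
    pairs, nodes = _random_graph_edges(rng, 9, 0.3)
    g = graph_from_edges(pairs, extra_nodes=nodes)
    ug = nx.Graph(pairs)
    ug.add_nodes_from(nodes)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(ug)):
        for n in comp:
            comp_of[n] = ci
    for cluster in run_mcl(g, MCLConfig(inflation=4)).clusters:
        assert len({comp_of[n] for n in cluster}) == 1


def test_determinism_under_relabeling():
    pairs = [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"),
             ("e", "f"), ("f", "d")]
    p1 = run_mcl(graph_from_edges(pairs), MCLConfig(inflation=4))
    relabel = {c: c.upper() for c in "abcdef"}
    pairs2 = [(relabel[a], relabel[b]) for a, b in pairs]
    p2 = run_mcl(graph_from_edges(pairs2), MCLConfig(inflation=4))
    mapped = {frozenset(relabel[n] for n in c) for c in p1.clusters}
    assert mapped == {frozenset(c) for c in p2.clusters}


def test_granularity_increases_with_inflation():
    rng = np.random.default_rng(3)
    pairs, nodes = _random_graph_edges(rng, 12, 0.3)
    g = graph_from_edges(pairs, extra_nodes=nodes)
    n_low = len(run_mcl(g, MCLConfig(inflation=1.5)).clusters)
    n_high = len(run_mcl(g, MCLConfig(inflation=6)).clusters)
    assert n_high >= n_low


def test_node_overlap_definition():
    g = graph_from_edges(
        [("a", "b")], ce_triples=[("b", "+", "x"), ("x", "+", "a")]
    )
    p = run_mcl(g, MCLConfig(inflation=2))
    for c, bm, no in zip(p.clusters, p.bm_part, p.node_overlap):
        assert 0.0 <= no <= 1.0
        assert no == len(bm) / len(c)
        assert (no == 1.0) == (c <= g.bm_nodes)
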