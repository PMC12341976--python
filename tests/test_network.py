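"""Extended-graph construction, CE-edge categories and return paths."""

import networkx as nx
import numpy as np
import pytest

from modex.model import CandidateEventSet, SignedEdge
from modex.network import (
    build_extended_graph,
    category_counts,
    classify_ce_edge,
    find_return_paths,
    has_return_path,
)

from conftest import make_model


@pytest.fixture
def abc_model():
    return make_model([("A", "", "", 1), ("B", "A", "", 0), ("C", "B", "", 0)])


def test_union_graph(abc_model):
    ce = CandidateEventSet([SignedEdge("C", "D", "+"), SignedEdge("D", "A", "+")])
    g = build_extended_graph(abc_model, ce)
    assert g.nodes == {"A", "B", "C", "D"}
    assert len(g.edges) == 4
    assert g.node_origin["D"] == "CE"
    assert g.node_origin["C"] == "both"
    assert g.node_origin["B"] == "BM"


def test_edge_present_in_both_sets_labeled_both(abc_model):
    ce = CandidateEventSet([SignedEdge("A", "B", "+")])
    g = build_extended_graph(abc_model, ce)
    assert g.edge_origin[("A", "B", "+")] == "both"
    assert len(g.edges) == 2  # not duplicated


@pytest.mark.parametrize(
    "edge,cat",
    [
        (SignedEdge("A", "B", "+"), "i"),
        (SignedEdge("A", "X", "+"), "ii"),
        (SignedEdge("X", "B", "-"), "ii"),
        (SignedEdge("X", "Y", "+"), "iii"),
    ],
)
def test_ce_edge_categories(abc_model, edge, cat):
    assert classify_ce_edge(edge, abc_model) == cat


def test_category_counts(abc_model):
    ce = CandidateEventSet(
        [SignedEdge("A", "B", "-"), SignedEdge("A", "X", "+"), SignedEdge("X", "Y", "+")]
    )
    g = build_extended_graph(abc_model, ce)
    assert category_counts(g) == {"i": 1, "ii": 1, "iii": 1}


def test_ce_names_matched_case_insensitively(abc_model):
    ce = CandidateEventSet([SignedEdge("a", "b", "+")])
    g = build_extended_graph(abc_model, ce)
    assert g.ce_edges[0].source == "A" and g.ce_edges[0].target == "B"


def test_single_return_path():
    edges = [SignedEdge("A", "X", "+"), SignedEdge("X", "B", "-")]
    paths = find_return_paths(edges, {"A", "B"}, max_len=5)
    assert len(paths) == 1
    assert paths[0].node_sequence == ("A", "X", "B")
    assert len(paths[0]) == 2


def test_dead_end_is_no_return_path():
    edges = [SignedEdge("A", "X", "+")]
    assert find_return_paths(edges, {"A", "B"}, max_len=5) == []
    assert not has_return_path(edges, {"A", "B"})


def test_single_bm_to_bm_edge_is_length_one_return_path():
    edges = [SignedEdge("A", "B", "+")]
    paths = find_return_paths(edges, {"A", "B"}, max_len=3)
    assert [len(p) for p in paths] == [1]
    assert has_return_path(edges, {"A", "B"})


def test_chain_leaving_and_never_returning():
    edges = [SignedEdge("A", "X", "+"), SignedEdge("X", "Y", "+")]
    assert not has_return_path(edges, {"A", "B"})


def test_multi_cluster_style_return_path():
    # baseline -> cluster 1 -> cluster 2 -> baseline
    edges = [
        SignedEdge("BM1", "u1", "+"),
        SignedEdge("u1", "u2", "+"),
        SignedEdge("u2", "v1", "-"),
        SignedEdge("v1", "BM2", "+"),
    ]
    assert has_return_path(edges, {"BM1", "BM2"})
    paths = find_return_paths(edges, {"BM1", "BM2"}, max_len=4)
    assert any(p.node_sequence == ("BM1", "u1", "u2", "v1", "BM2") for p in paths)


def _oracle_paths(edges, bm_nodes, max_len):
    """Brute force via networkx all_simple_paths over every BM pair."""
    g = nx.DiGraph()
    g.add_edges_from((e.source, e.target) for e in edges)
    found = set()
    for s in bm_nodes:
        for t in bm_nodes:
            if s == t or s not in g or t not in g:
                continue
            for p in nx.all_simple_paths(g, s, t, cutoff=max_len):
                found.add(tuple(p))
    return found


def _random_digraph(rng, n_nodes, p_edge):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        SignedEdge(a, b, "+" if rng.random() < 0.5 else "-")
        for a in nodes
        for b in nodes
        if a != b and rng.random() < p_edge
    ]
    return nodes, edges


@pytest.mark.parametrize("seed", range(20))
def test_return_paths_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    nodes, edges = _random_digraph(rng, 8, 0.25)
    bm = set(rng.choice(nodes, size=3, replace=False))
    ours = {p.node_sequence for p in find_return_paths(edges, bm, max_len=6)}
    assert ours == _oracle_paths(edges, bm, 6)
    assert has_return_path(edges, bm) == bool(
        _oracle_paths(edges, bm, max_len=len(edges))
    )


def test_returned_paths_satisfy_invariants():
    rng = np.random.default_rng(42)
    _, edges = _random_digraph(rng, 9, 0.3)
    bm = {"n0", "n1", "n2"}
    for p in find_return_paths(edges, bm, max_len=5):
        assert p.start in bm and p.end in bm
        for e1, e2 in zip(p.edge_sequence, p.edge_sequence[1:]):
            assert e1.target == e2.source
        nodes = p.node_sequence
        assert len(set(nodes)) == len(nodes)  # simple


def test_monotonicity_adding_edges_preserves_paths():
    rng = np.random.default_rng(7)
    _, edges = _random_digraph(rng, 8, 0.2)
    bm = {"n0", "n1"}
    before = {p.node_sequence for p in find_return_paths(edges, bm, max_len=5)}
    extended = edges + [SignedEdge("n0", "n7", "+"), SignedEdge("n7", "n1", "+")]
    after = {p.node_sequence for p in find_return_paths(extended, bm, max_len=5)}
    assert before <= after
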