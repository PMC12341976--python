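"""Candidate assembly: rule revision, cluster enumeration, NO values."""

import pytest

from modex.assembly import (
    assemble_all,
    assemble_candidate,
    enumerate_candidate_clusters,
    revise_update_rules,
)
from modex.mcl import ClusterPartition, MCLConfig, run_mcl
from modex.model import CandidateEventSet, SignedEdge
from modex.network import build_extended_graph
from modex.rules import parse_rule, rule_to_string

from conftest import make_model


@pytest.fixture
def bcd_model():
    return make_model([
        ("A", "", "", 1),
        ("B", "C OR D", "", 0),
        ("C", "", "", 1),
        ("D", "", "", 0),
    ])


def test_or_default_rule_extension(bcd_model):
    # new positive regulator A of B joins the old rule with OR
    revised, added, skipped = revise_update_rules(bcd_model, [SignedEdge("A", "B", "+")])
    assert rule_to_string(revised.elements["B"].positive) == "C OR D OR A"
    assert [e.key for e in added] == [("A", "B", "+")]
    assert skipped == []


def test_new_element_positive_and_negative_composition(bcd_model):
    edges = [SignedEdge("A", "X", "+"), SignedEdge("C", "X", "-")]
    revised, added, _ = revise_update_rules(bcd_model, edges)
    x = revised.elements["X"]
    assert x.positive == parse_rule("A")
    assert x.negative == parse_rule("C")
    assert x.initial == {"1": 0}  # new elements default inactive


def test_duplicate_regulation_skipped(bcd_model):
    _, added, skipped = revise_update_rules(bcd_model, [SignedEdge("C", "B", "+")])
    assert added == []
    assert skipped[0][1] == "duplicate"


def test_contradictory_regulation_skipped():
    m = make_model([("A", "", "", 1), ("B", "", "A", 0)])
    revised, added, skipped = revise_update_rules(m, [SignedEdge("A", "B", "+")])
    assert added == []
    assert skipped[0][1] == "contradiction"
    assert revised.elements["B"].positive is None  # unchanged


def test_rule_revision_idempotent(bcd_model):
    edges = [SignedEdge("A", "B", "+"), SignedEdge("B", "X", "-")]
    once, _, _ = revise_update_rules(bcd_model, edges)
    twice, added2, _ = revise_update_rules(once, edges)
    assert added2 == []
    assert twice == once


def test_baseline_preserved(bcd_model):
    edges = [SignedEdge("A", "X", "+"), SignedEdge("X", "B", "+"),
             SignedEdge("D", "A", "-")]
    revised, _, _ = revise_update_rules(bcd_model, edges)
    bm_edges = set(e.key for e in bcd_model.edges())
    assert bm_edges <= set(e.key for e in revised.edges())
    assert set(bcd_model.nodes) <= set(revised.nodes)


def _pipeline_parts(model, ce_edges):
    ce = CandidateEventSet(ce_edges)
    graph = build_extended_graph(model, ce)
    partition = run_mcl(graph, MCLConfig(inflation=4))
    return graph, partition


def test_candidate_count_individual_plus_pairs(bcd_model):
    # with n clusters there are at most n + n(n-1)/2 entries pre-filter
    graph, partition = _pipeline_parts(
        bcd_model, [SignedEdge("A", "X", "+"), SignedEdge("X", "B", "+")]
    )
    n = len(partition.clusters)
    entries = enumerate_candidate_clusters(partition, graph)
    assert len(entries) <= n + n * (n - 1) // 2
    # every entry passes the return-path filter by construction
    from modex.network import has_return_path

    for e in entries:
        assert has_return_path(e.ce_edges, graph.bm_nodes)


def test_cluster_without_return_to_bm_excluded(bcd_model):
    # CE chain leaves the model and never returns
    graph, partition = _pipeline_parts(
        bcd_model, [SignedEdge("B", "X", "+"), SignedEdge("X", "Y", "+")]
    )
    entries = enumerate_candidate_clusters(partition, graph)
    assert entries == []


def test_merged_pair_candidate_when_path_crosses_clusters():
    m = make_model([("A", "", "", 1), ("B", "A", "", 0)])
    # two CE chains that only return when merged: A->x->y->B with x,y far apart
    ce = [SignedEdge("A", "x", "+"), SignedEdge("x", "y", "+"), SignedEdge("y", "B", "+")]
    graph = build_extended_graph(m, CandidateEventSet(ce))
    # force a partition splitting x and y into different clusters
    partition = ClusterPartition(
        clusters=[{"A", "x"}, {"B", "y"}],
        bm_part=[{"A"}, {"B"}],
        ce_part=[{"x"}, {"y"}],
        node_overlap=[0.5, 0.5],
    )
    entries = enumerate_candidate_clusters(partition, graph)
    labels = {e.label for e in entries}
    assert labels == {"C0+C1"}  # neither cluster alone forms a return path


def test_assemble_candidate_counts_and_no():
    m = make_model([("A", "", "", 1), ("B", "A", "", 0), ("C", "B", "", 0)])
    ce = [SignedEdge("A", "X", "+"), SignedEdge("X", "B", "+")]
    graph = build_extended_graph(m, CandidateEventSet(ce))
    partition = ClusterPartition(
        clusters=[{"A", "B", "X"}, {"C"}],
        bm_part=[{"A", "B"}, {"C"}],
        ce_part=[{"X"}, set()],
        node_overlap=[2 / 3, 1.0],
    )
    entries = enumerate_candidate_clusters(partition, graph)
    entry = next(e for e in entries if e.cluster_ids == (0,))
    cm = assemble_candidate(m, entry, partition, graph)
    assert len(cm.model.elements) == 4
    assert len(cm.added_edges) == 2
    assert cm.node_overlap == 2 / 3
    assert set(e.key for e in m.edges()) <= set(e.key for e in cm.model.edges())


def test_merged_cluster_no_is_union_based():
    m = make_model([("A", "", "", 1), ("B", "A", "", 0)])
    ce = [SignedEdge("A", "x1", "+"), SignedEdge("x1", "B", "+")]
    graph = build_extended_graph(m, CandidateEventSet(ce))
    # sizes 4 (1 BM node) and 6 (2 BM nodes) -> union NO = 3/10
    c1 = {"A"} | {f"p{i}" for i in range(3)}
    c2 = {"B", "x1"} | {f"q{i}" for i in range(3)} | {"A2"}
    partition = ClusterPartition(
        clusters=[c1, c2],
        bm_part=[{"A"}, {"B", "A2"}],
        ce_part=[c1 - {"A"}, c2 - {"B", "A2"}],
        node_overlap=[1 / 4, 2 / 6],
    )
    graph.bm_nodes |= {"A2"}
    graph.nodes |= c1 | c2
    entries = enumerate_candidate_clusters(partition, graph)
    merged = next(e for e in entries if e.cluster_ids == (0, 1))
    cm = assemble_candidate(m, merged, partition, graph)
    assert cm.node_overlap == pytest.approx(3 / 10)


def test_assemble_all_on_mcl_partition(bcd_model):
    graph, partition = _pipeline_parts(
        bcd_model, [SignedEdge("A", "X", "+"), SignedEdge("X", "B", "+")]
    )
    cms = assemble_all(bcd_model, partition, graph)
    assert cms, "the return path A->X->B must yield at least one candidate"
    for cm in cms:
        cm.model.validate()
        assert set(e.key for e in bcd_model.edges()) <= set(
            e.key for e in cm.model.edges()
        )
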