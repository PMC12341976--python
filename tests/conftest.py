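import pytest

from modex.model import CandidateEventSet, Element, Model, SignedEdge
from modex.network import ExtendedGraph
from modex.rules import parse_rule


def make_model(rows, scenarios=("1",)):
    """rows: (name, pos_expr, neg_expr, init_value or dict)."""
    model = Model()
    for row in rows:
        name, pos, neg, init = row
        if not isinstance(init, dict):
            init = {sc: init for sc in scenarios}
        model.add_element(
            Element(name=name, positive=parse_rule(pos), negative=parse_rule(neg),
                    initial=init)
        )
    model.canonicalize_rules()
    model.validate()
    return model


def graph_from_edges(bm_pairs, ce_triples=(), extra_nodes=()):
    """Build an ExtendedGraph directly from edge lists (tests only)."""
    bm_edges = [SignedEdge(a, b, "+") for a, b in bm_pairs]
    bm_nodes = {n for p in bm_pairs for n in p} | set(extra_nodes)
    ce_edges = [SignedEdge(s, t, sign) for s, sign, t in ce_triples]
    edges = list(bm_edges)
    origin = {e.key: "BM" for e in bm_edges}
    for e in ce_edges:
        if e.key in origin:
            origin[e.key] = "both"
        else:
            origin[e.key] = "CE"
            edges.append(e)
    nodes = bm_nodes | {n for e in ce_edges for n in (e.source, e.target)}
    node_origin = {}
    ce_nodes = {n for e in ce_edges for n in (e.source, e.target)}
    for n in nodes:
        if n in bm_nodes and n in ce_nodes:
            node_origin[n] = "both"
        elif n in bm_nodes:
            node_origin[n] = "BM"
        else:
            node_origin[n] = "CE"
    return ExtendedGraph(nodes=nodes, edges=edges, edge_origin=origin,
                         node_origin=node_origin, bm_nodes=bm_nodes, ce_edges=ce_edges)


@pytest.fixture
def chain_model():
    """A -> B -> C cascade; A constant on."""
    return make_model([
        ("A", "", "", 1),
        ("B", "A", "", 0),
        ("C", "B", "", 0),
    ])


@pytest.fixture
def toggle_model():
    """Self-repressor: A oscillates under synchronous update."""
    return make_model([("A", "", "A", 0)])
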