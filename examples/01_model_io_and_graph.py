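"""Build a small executable model and a candidate-event set, merge them
into the extended graph, and look for return paths.

A return path is a chain of candidate interactions that leaves the
baseline model at one node and re-enters it at another — the
connectivity test deciding whether new knowledge can be attached.
"""

from modex import (
    CandidateEventSet,
    Element,
    Model,
    SignedEdge,
    build_extended_graph,
    classify_ce_edge,
    find_return_paths,
)
from modex.rules import parse_rule

# a three-element cascade: A -> B -> C, A constitutively active
model = Model([
    Element("A", initial={"1": 1}),
    Element("B", positive=parse_rule("A"), initial={"1": 0}),
    Element("C", positive=parse_rule("B"), initial={"1": 0}),
])
model.validate()

# candidate events mined from "literature": a feedback loop through a
# new element X, plus a dangling edge that never returns
ce = CandidateEventSet([
    SignedEdge("C", "X", "+", provenance="paper-1"),
    SignedEdge("X", "A", "-", provenance="paper-2"),
    SignedEdge("B", "Y", "+", provenance="paper-3"),
])

graph = build_extended_graph(model, ce)
print(f"baseline: {sorted(model.nodes)}  ({len(model.edges())} edges)")
print(f"extended graph: {sorted(graph.nodes)}  ({len(graph.edges)} edges)")
for e in ce.edges:
    print(f"  CE edge {e.source} -{e.sign}-> {e.target}: category "
          f"({classify_ce_edge(e, model)})")

paths = find_return_paths(graph.ce_edges, graph.bm_nodes, max_len=4)
print(f"return paths found: {len(paths)}")
for p in paths:
    print("  " + " -> ".join(p.node_sequence))
# The C->X->A chain is a return path (it re-enters the model at A), so
# its cluster can be used to extend the model; B->Y dangles and cannot.
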