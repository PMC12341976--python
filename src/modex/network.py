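"""Extended-graph construction and return-path search.

G^new is the union of the baseline model graph G_BM and the candidate
event set: V^new = V_BM ∪ V_CE, E^new = E_BM ∪ E_CE.  CE edges fall in
three categories by how many endpoints already belong to the baseline
model: (i) both, (ii) exactly one, (iii) neither.

A *return path* is a chain of CE edges that starts at a baseline-model
node and ends at a baseline-model node; it is the connectivity
criterion deciding whether a cluster of candidate interactions can be
attached to the model.  Paths here are simple (no repeated node), which
bounds the search; a single category-(i) edge is a return path of
length 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .model import CandidateEventSet, Model, SignedEdge

logger = logging.getLogger(__name__)


@dataclass
class ExtendedGraph:
    """Union graph of baseline model and CE set with origin labels."""

    nodes: set[str]
    edges: list[SignedEdge]
    edge_origin: dict[tuple[str, str, str], str]
    node_origin: dict[str, str]
    bm_nodes: set[str]
    ce_edges: list[SignedEdge]

    @property
    def ce_nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.ce_edges:
            out.update((e.source, e.target))
        return out


@dataclass
class ReturnPath:
    """A chain of CE edges from one baseline node back to another."""

    edge_sequence: list[SignedEdge]

    @property
    def start(self) -> str:
        return self.edge_sequence[0].source

    @property
    def end(self) -> str:
        return self.edge_sequence[-1].target

    @property
    def node_sequence(self) -> tuple[str, ...]:
        return (self.start,) + tuple(e.target for e in self.edge_sequence)

    def __len__(self) -> int:
        return len(self.edge_sequence)


def classify_ce_edge(edge: SignedEdge, model: Model) -> str:
    """Category 'i' (both endpoints in V_BM), 'ii' (one), 'iii' (none)."""
    n = (model.resolve(edge.source) is not None) + (model.resolve(edge.target) is not None)
    return {2: "i", 1: "ii", 0: "iii"}[n]


def build_extended_graph(model: Model, ce: CandidateEventSet) -> ExtendedGraph:
    """Form G^new = G_BM ∪ G_CE with per-node and per-edge origin labels.

    CE element names are matched to model names case-insensitively; a CE
    node matching a model element is recorded under the model's
    canonical spelling.
    """
    bm_edges = model.edges()
    bm_nodes = set(model.nodes)

    def canon(name: str) -> str:
        return model.resolve(name) or name

    edge_origin: dict[tuple[str, str, str], str] = {}
    node_origin: dict[str, str] = {n: "BM" for n in bm_nodes}
    edges: list[SignedEdge] = []
    for e in bm_edges:
        edge_origin[e.key] = "BM"
        edges.append(e)

    ce_edges: list[SignedEdge] = []
    categories = {"i": 0, "ii": 0, "iii": 0}
    for e in ce.edges:
        ec = SignedEdge(canon(e.source), canon(e.target), e.sign, e.provenance, e.score)
        ce_edges.append(ec)
        categories[classify_ce_edge(ec, model)] += 1
        if ec.key in edge_origin:
            edge_origin[ec.key] = "both"
        else:
            edge_origin[ec.key] = "CE"
            edges.append(ec)
        for n in (ec.source, ec.target):
            # nodes in V_BM ∩ V_CE are labeled "both"; NO counts them as BM
            node_origin[n] = "both" if n in bm_nodes else "CE"

    nodes = bm_nodes | {n for e in ce_edges for n in (e.source, e.target)}

    logger.info(
        "G^new: %d nodes, %d edges; CE categories i=%d ii=%d iii=%d",
        len(nodes), len(edges), categories["i"], categories["ii"], categories["iii"],
    )
    return ExtendedGraph(
        nodes=nodes,
        edges=edges,
        edge_origin=edge_origin,
        node_origin=node_origin,
        bm_nodes=bm_nodes,
        ce_edges=ce_edges,
    )


def category_counts(graph: ExtendedGraph) -> dict[str, int]:
    counts = {"i": 0, "ii": 0, "iii": 0}
    for e in graph.ce_edges:
        n = (e.source in graph.bm_nodes) + (e.target in graph.bm_nodes)
        counts[{2: "i", 1: "ii", 0: "iii"}[n]] += 1
    return counts


def _adjacency(edges: Iterable[SignedEdge]) -> dict[str, list[SignedEdge]]:
    adj: dict[str, list[SignedEdge]] = {}
    for e in edges:
        adj.setdefault(e.source, []).append(e)
    for lst in adj.values():
        lst.sort(key=lambda e: (e.target, e.sign))
    return adj


def find_return_paths(
    cluster_ce_edges: Iterable[SignedEdge],
    bm_nodes: set[str],
    max_len: int,
) -> list[ReturnPath]:
    """Enumerate all simple CE-edge paths from a BM node back to BM.

    Intermediate nodes are unconstrained (they are typically new CE
    elements); edge signs are carried but do not affect existence.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    edges = list(cluster_ce_edges)
    adj = _adjacency(edges)
    out: list[ReturnPath] = []

    def dfs(node: str, visited: set[str], prefix: list[SignedEdge]) -> None:
        for e in adj.get(node, []):
            if e.target in visited:
                continue
            path = prefix + [e]
            if e.target in bm_nodes:
                out.append(ReturnPath(path))
            if len(path) < max_len:
                dfs(e.target, visited | {e.target}, path)

    for start in sorted(n for n in adj if n in bm_nodes):
        dfs(start, {start}, [])
    return out


def has_return_path(cluster_ce_edges: Iterable[SignedEdge], bm_nodes: set[str]) -> bool:
    """Existence check by forward reachability over CE edges.

    True iff some chain of the given CE edges leaves a BM node and
    reaches a BM node (a single BM->BM edge qualifies).
    """
    edges = list(cluster_ce_edges)
    adj = _adjacency(edges)
    for start in (n for n in adj if n in bm_nodes):
        # paths are simple, so a walk closing back onto its own start
        # does not count as a return; any other BM node does
        frontier = [start]
        seen = {start}
        while frontier:
            node = frontier.pop()
            for e in adj.get(node, []):
                if e.target in bm_nodes and e.target != start:
                    return True
                if e.target not in seen:
                    seen.add(e.target)
                    frontier.append(e.target)
    return False


def export_graph(graph: ExtendedGraph, path) -> None:
    """Write G^new as an edge-list TSV with an origin column."""
    import pandas as pd

    rows = [
        {
            "Source": e.source,
            "Sign": e.sign,
            "Target": e.target,
            "Origin": graph.edge_origin[e.key],
        }
        for e in graph.edges
    ]
    pd.DataFrame(rows, columns=["Source", "Sign", "Target", "Origin"]).to_csv(
        path, sep="\t", index=False
    )
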