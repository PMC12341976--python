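"""Candidate model assembly from clusters that form return paths.

For every individual cluster and every unordered pair of clusters, the
CE edges attachable to that cluster (union) are gathered; if they form
a return path with the baseline model, a candidate model (CM) is built
by adding those edges — and any new elements they introduce — to the
baseline, never removing anything from it.

Rule revision follows the OR-default: a new positive regulator A of B
turns ``x_B = f(x_C, x_D)`` into ``x_B = f(x_C, x_D) OR x_A``; new
negative regulators extend the negative expression the same way, and an
element is active iff its positive expression holds and its negative
expression does not.  A CE edge duplicating an existing regulation is
skipped; one contradicting an existing regulation (same source/target,
opposite sign) is skipped with a warning — resolving contradictions is
out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .mcl import ClusterPartition
from .model import CandidateEventSet, Element, Model, SignedEdge, ValidationError
from .network import ExtendedGraph, has_return_path
from .rules import or_join, rule_identifiers

logger = logging.getLogger(__name__)


@dataclass
class ClusterEntry:
    """A candidate cluster (or merged pair) and its attachable CE edges."""

    cluster_ids: tuple[int, ...]
    nodes: set[str]
    ce_edges: list[SignedEdge]

    @property
    def label(self) -> str:
        return "+".join(f"C{i}" for i in self.cluster_ids)


@dataclass
class CandidateModel:
    model: Model
    source_clusters: tuple[int, ...]
    added_edges: list[SignedEdge]
    node_overlap: float
    skipped_edges: list[tuple[SignedEdge, str]] = field(default_factory=list)

    @property
    def candidate_id(self) -> str:
        return "+".join(f"C{i}" for i in self.source_clusters)


def _attachable_edges(
    union_nodes: set[str], graph: ExtendedGraph
) -> list[SignedEdge]:
    """CE edges belonging to a cluster union.

    An edge qualifies when both endpoints lie in the union, or when one
    endpoint lies in the union and the other is a baseline node — except
    that an edge with *both* endpoints in the baseline model must have
    both inside the union (a baseline-to-baseline shortcut spanning two
    clusters belongs to their merged pair only).
    """
    out = []
    for e in graph.ce_edges:
        s_in, t_in = e.source in union_nodes, e.target in union_nodes
        if s_in and t_in:
            out.append(e)
        elif e.source in graph.bm_nodes and e.target in graph.bm_nodes:
            continue
        elif (s_in and e.target in graph.bm_nodes) or (t_in and e.source in graph.bm_nodes):
            out.append(e)
    return out


def enumerate_candidate_clusters(
    partition: ClusterPartition, graph: ExtendedGraph
) -> list[ClusterEntry]:
    """Individual clusters and unordered pairs passing the return-path filter."""
    entries: list[ClusterEntry] = []
    ids = range(len(partition.clusters))
    singles = [(i,) for i in ids]
    pairs = list(combinations(ids, 2))
    for id_set in singles + pairs:
        union: set[str] = set()
        for i in id_set:
            union |= partition.clusters[i]
        edges = _attachable_edges(union, graph)
        if edges and has_return_path(edges, graph.bm_nodes):
            entries.append(ClusterEntry(tuple(id_set), union, edges))
    logger.info(
        "candidate clusters: %d of %d individual+merged entries form return paths",
        len(entries), len(singles) + len(pairs),
    )
    return entries


def revise_update_rules(
    model: Model, added_edges: list[SignedEdge], initial_value: int = 0
) -> tuple[Model, list[SignedEdge], list[tuple[SignedEdge, str]]]:
    """Extend a copy of the model with new signed regulations.

    Returns (revised model, edges actually added, skipped edges with
    reasons).  New elements get Boolean levels and the given initial
    value in every scenario.  Revision is idempotent: re-applying the
    same edges changes nothing.
    """
    out = model.copy()
    scenarios = out.scenarios or ["1"]
    added: list[SignedEdge] = []
    skipped: list[tuple[SignedEdge, str]] = []

    for e in added_edges:
        src = out.resolve(e.source) or e.source
        tgt = out.resolve(e.target) or e.target
        for name in (src, tgt):
            if out.resolve(name) is None:
                out.add_element(
                    Element(name=name, levels=2, initial={sc: initial_value for sc in scenarios})
                )
        tgt = out.resolve(tgt)
        el = out.elements[tgt]
        same = el.regulators(e.sign)
        opposite = el.regulators("-" if e.sign == "+" else "+")
        if src in same:
            skipped.append((e, "duplicate"))
            logger.debug("skipping duplicate regulation %s", e)
            continue
        if src in opposite:
            skipped.append((e, "contradiction"))
            logger.warning("skipping contradictory regulation %s", e)
            continue
        if e.sign == "+":
            el.positive = or_join(el.positive, [src])
        else:
            el.negative = or_join(el.negative, [src])
        added.append(SignedEdge(src, tgt, e.sign, e.provenance, e.score))

    out.validate()
    return out, added, skipped


def assemble_candidate(
    model: Model,
    entry: ClusterEntry,
    partition: ClusterPartition,
    graph: ExtendedGraph,
    initial_value: int = 0,
) -> CandidateModel:
    """Build one candidate model from a cluster entry.

    The baseline is preserved verbatim; the entry's CE edges are added
    with revised rules; node overlap is the NO of the generating
    cluster union.
    """
    revised, added, skipped = revise_update_rules(model, entry.ce_edges, initial_value)
    bm_in_union = entry.nodes & graph.bm_nodes
    no = len(bm_in_union) / len(entry.nodes) if entry.nodes else 0.0
    return CandidateModel(
        model=revised,
        source_clusters=entry.cluster_ids,
        added_edges=added,
        node_overlap=no,
        skipped_edges=skipped,
    )


def assemble_all(
    model: Model,
    partition: ClusterPartition,
    graph: ExtendedGraph,
    initial_value: int = 0,
) -> list[CandidateModel]:
    """Assemble every candidate passing the return-path filter.

    A candidate failing post-assembly validation is dropped with a log
    entry; the pipeline continues with the rest.
    """
    out = []
    for entry in enumerate_candidate_clusters(partition, graph):
        try:
            out.append(assemble_candidate(model, entry, partition, graph, initial_value))
        except ValidationError as exc:
            logger.error("candidate %s dropped: %s", entry.label, exc)
    return out
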