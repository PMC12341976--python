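"""Synthetic golden/baseline/CE/property fixtures with known ground truth.

The generator emulates the standard ablation benchmark for model
extension: start from a *golden* model (a random Boolean network taken
as the published reference), remove a few interactions to obtain the
*baseline*, and offer the removed interactions back — optionally mixed
with decoy interactions — as the candidate event (CE) set.  A pipeline
that works should find the ablated structure, and its top candidate
should bring the model's dynamic behavior back toward the golden
model's.

Properties are BLTL statements of the form ``F[s1]G[s2](x = v)`` whose
goal probabilities are *measured* on the golden model by simulation, so
P_t takes values anywhere in [0,1], not just the endpoints.  Property
elements are chosen preferentially among elements whose behavior the
ablated interactions actually change (largest golden-vs-baseline
estimate gap): these are the behaviors a modeler would write
requirements about, and they are exactly the behaviors the baseline
fails to reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bltl import Property, estimate_probability, parse_formula
from .model import CandidateEventSet, Element, Model, SignedEdge
from .rules import or_join
from .simulate import SimulationConfig

_SCENARIO = "1"


@dataclass
class FixtureSpec:
    n_elements: int = 12
    edge_density: float = 0.15
    n_removed_edges: int = 3
    n_decoy_edges: int = 0
    decoy_mode: str = "mixed"
    n_properties: int = 5
    seed: int = 0
    measure_runs: int = 200
    hold_steps: int = 5  # the G[s2] bound

    def __post_init__(self):
        if self.n_elements < 3:
            raise ValueError("need at least 3 elements")
        if self.decoy_mode not in ("connected", "disconnected", "mixed"):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")

    @property
    def settle_steps(self) -> int:
        """The F[s1] bound: asynchronous updates touch each element about
        once per n steps, so 5n steps let a cascade of depth ~5 settle."""
        return 5 * self.n_elements


@dataclass
class Fixture:
    golden: Model
    baseline: Model
    ce: CandidateEventSet
    properties: list[Property]
    removed_edges: list[SignedEdge]
    decoy_edges: list[SignedEdge]
    spec: FixtureSpec
    sim_config: SimulationConfig = field(default=None)


def _build_model(
    n: int,
    regulators: dict[str, dict[str, list[str]]],
    initial: dict[str, int],
) -> Model:
    model = Model()
    for name in sorted(initial):
        pos = or_join(None, sorted(regulators[name]["+"]))
        neg = or_join(None, sorted(regulators[name]["-"]))
        model.add_element(
            Element(name=name, positive=pos, negative=neg, levels=2,
                    initial={_SCENARIO: initial[name]})
        )
    model.validate()
    return model


def _random_structure(spec: FixtureSpec, rng: np.random.Generator):
    """Random connected signed digraph plus initial values."""
    n = spec.n_elements
    names = [f"N{i:02d}" for i in range(1, n + 1)]
    pairs: set[tuple[str, str]] = set()
    edges: list[SignedEdge] = []

    def add_edge(s: str, t: str) -> None:
        sign = "+" if rng.random() < 0.75 else "-"
        pairs.add((s, t))
        edges.append(SignedEdge(s, t, sign))

    # spanning backbone keeps the graph weakly connected
    for i in range(1, n):
        j = int(rng.integers(0, i))
        s, t = (names[j], names[i]) if rng.random() < 0.7 else (names[i], names[j])
        add_edge(s, t)
    for i in range(n):
        for j in range(n):
            if i != j and (names[i], names[j]) not in pairs and (names[j], names[i]) not in pairs:
                if rng.random() < spec.edge_density:
                    add_edge(names[i], names[j])

    initial = {name: int(rng.integers(0, 2)) for name in names}
    return names, edges, initial


def _regulator_table(names: list[str], edges: list[SignedEdge]):
    regs: dict[str, dict[str, list[str]]] = {n: {"+": [], "-": []} for n in names}
    for e in edges:
        regs[e.target][e.sign].append(e.source)
    return regs


def _choose_removals(
    edges: list[SignedEdge], k: int, rng: np.random.Generator
) -> list[SignedEdge]:
    """Pick a *connected* set of k edges to ablate.

    Real ablation benchmarks remove a coherent region of the published
    model (a pathway chunk), not scattered independent edges, so the
    removed edges grow from a random seed edge through shared endpoints.
    The removal also orphans no node — every node keeps at least one
    incident edge, so V_BM = V_GM and the ablation is purely structural.
    """
    if k >= len(edges):
        raise ValueError("cannot remove as many edges as the golden model has")
    all_nodes = {n for e in edges for n in (e.source, e.target)}
    for _ in range(500):
        removed = [edges[int(rng.integers(0, len(edges)))]]
        touched_nodes = set(removed[0].key[:2])
        while len(removed) < k:
            adjacent = [
                e for e in edges
                if e not in removed and (e.source in touched_nodes or e.target in touched_nodes)
            ]
            if not adjacent:
                break
            pick = adjacent[int(rng.integers(0, len(adjacent)))]
            removed.append(pick)
            touched_nodes.update((pick.source, pick.target))
        if len(removed) < k:
            continue
        kept = [e for e in edges if e not in removed]
        if {n for e in kept for n in (e.source, e.target)} == all_nodes:
            return removed
    raise ValueError("could not find a removal set that keeps every element in play")


def _decoys(
    spec: FixtureSpec, bm_nodes: list[str], rng: np.random.Generator
) -> list[SignedEdge]:
    """Decoy CE edges.  Every decoy touches at least one fresh node, so
    decoys can never duplicate or contradict a golden interaction.
    Disconnected decoys live entirely among fresh nodes and can never
    form a return path; connected decoys hang off the baseline."""
    out: list[SignedEdge] = []
    fresh_count = 0

    def fresh() -> str:
        nonlocal fresh_count
        fresh_count += 1
        return f"D{fresh_count:02d}"

    connected_pool: list[str] = []
    disconnected_pool: list[str] = []
    for i in range(spec.n_decoy_edges):
        if spec.decoy_mode == "connected":
            connected = True
        elif spec.decoy_mode == "disconnected":
            connected = False
        else:
            connected = i % 2 == 0
        sign = "+" if rng.random() < 0.75 else "-"
        if connected:
            if connected_pool and rng.random() < 0.5:
                x = connected_pool[int(rng.integers(0, len(connected_pool)))]
            else:
                x = fresh()
                connected_pool.append(x)
            b = bm_nodes[int(rng.integers(0, len(bm_nodes)))]
            s, t = (b, x) if rng.random() < 0.5 else (x, b)
        else:
            if len(disconnected_pool) < 2:
                disconnected_pool.append(fresh())
            if len(disconnected_pool) < 2 or rng.random() < 0.4:
                disconnected_pool.append(fresh())
            a, b2 = rng.choice(len(disconnected_pool), size=2, replace=False)
            s, t = disconnected_pool[int(a)], disconnected_pool[int(b2)]
        if (s, t) not in {(e.source, e.target) for e in out}:
            out.append(SignedEdge(s, t, sign, provenance="decoy"))
    return out


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a golden/baseline/CE/property quadruple, reproducibly.

    The CE set is exactly the ablated golden edges plus the requested
    decoys, so on a zero-decoy fixture the candidate that adds every CE
    edge restores the golden structure exactly.
    """
    rng = np.random.default_rng(spec.seed)
    names, edges, initial = _random_structure(spec, rng)
    golden = _build_model(spec.n_elements, _regulator_table(names, edges), initial)

    removed = _choose_removals(edges, spec.n_removed_edges, rng)
    kept = [e for e in edges if e not in removed]
    baseline = _build_model(spec.n_elements, _regulator_table(names, kept), initial)

    decoys = _decoys(spec, names, rng)
    ce = CandidateEventSet(
        [SignedEdge(e.source, e.target, e.sign, provenance="ablated") for e in removed]
        + decoys
    )

    sim = SimulationConfig(
        scheme="random_asynchronous",
        steps=spec.settle_steps + spec.hold_steps,
        runs=spec.measure_runs,
        seed=int(spec.seed % 2**20) + 1000,
        scenario=_SCENARIO,
    )
    props = _measure_properties(spec, golden, baseline, removed, sim, rng)
    return Fixture(golden, baseline, ce, props, removed, decoys, spec, sim)


def _measure_properties(
    spec: FixtureSpec,
    golden: Model,
    baseline: Model,
    removed: list[SignedEdge],
    sim: SimulationConfig,
    rng: np.random.Generator,
) -> list[Property]:
    from .simulate import simulate

    golden_traces = simulate(golden, sim)
    baseline_traces = simulate(baseline, sim)

    # candidate elements: targets of ablated edges first, then the rest
    targets = []
    for e in removed:
        if e.target not in targets:
            targets.append(e.target)
    rest = [n for n in sorted(golden.nodes) if n not in targets]
    candidates = targets + rest

    gap: list[tuple[float, str, float]] = []
    for name in candidates:
        text = f"F[{spec.settle_steps}]G[{spec.hold_steps}]({name} = 1)"
        prop = Property("probe", parse_formula(text), 0.5, text)
        pg = estimate_probability(golden, prop, sim, traces=golden_traces).estimate
        pb = estimate_probability(baseline, prop, sim, traces=baseline_traces).estimate
        gap.append((abs(pg - pb), name, pg))
    # direct targets of the ablated interactions are always probed; the
    # remaining slots go to the elements whose behavior changed the most
    n_targets = min(len(targets), spec.n_properties)
    chosen = list(range(n_targets))
    order = sorted(
        range(n_targets, len(gap)), key=lambda i: (-gap[i][0], gap[i][1])
    )
    chosen += order[: spec.n_properties - n_targets]

    props = []
    for rank, i in enumerate(sorted(chosen), start=1):
        _, name, pg = gap[i]
        text = f"F[{spec.settle_steps}]G[{spec.hold_steps}]({name} = 1)"
        props.append(Property(f"t{rank}", parse_formula(text), pg, text))
    return props


def recovery_report(
    top_candidate_added_edges: list[SignedEdge],
    fixture: Fixture,
    baseline_eps_avg: float,
    candidate_eps_avg: float,
) -> dict[str, float]:
    """Ground-truth recovery metrics for a pipeline run on a fixture.

    * ``recovery_fraction`` — share of ablated golden edges (E_GM\\E_BM)
      present in the top candidate;
    * ``selectivity`` — |E_CM \\ E_BM| / |E_CE|, the share of offered
      candidate interactions actually adopted;
    * ``error_reduction_percent`` — relative drop in average model error
      from baseline to top candidate.
    """
    added_keys = {(e.source, e.target, e.sign) for e in top_candidate_added_edges}
    removed_keys = {(e.source, e.target, e.sign) for e in fixture.removed_edges}
    recovery = (
        len(added_keys & removed_keys) / len(removed_keys) if removed_keys else math.nan
    )
    selectivity = len(added_keys) / len(fixture.ce.edges) if fixture.ce.edges else math.nan
    reduction = (
        100.0 * (baseline_eps_avg - candidate_eps_avg) / baseline_eps_avg
        if baseline_eps_avg > 0
        else math.nan
    )
    return {
        "recovery_fraction": recovery,
        "selectivity": selectivity,
        "baseline_eps_avg": baseline_eps_avg,
        "candidate_eps_avg": candidate_eps_avg,
        "error_reduction_percent": reduction,
    }
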