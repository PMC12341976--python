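"""End-to-end orchestration: graph union -> clustering -> candidate
assembly -> simulation + property checking -> scoring -> ranked report.

The pipeline is deterministic for a fixed seed and configuration: node
orderings are sorted, candidates are enumerated in a fixed order, and
every simulation batch is seeded, so reruns produce bit-identical
artifact files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .assembly import CandidateModel, assemble_all
from .bltl import Property, estimate_probability, required_horizon
from .mcl import ClusterPartition, MCLConfig, run_mcl
from .model import CandidateEventSet, Model, ValidationError, write_model
from .network import ExtendedGraph, build_extended_graph, category_counts, export_graph
from .scoring import CandidateScores, ScoreReport, ScoringConfig, rank_candidates
from .simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)


class NoCandidatesError(RuntimeError):
    """No cluster (individual or merged) forms a return path."""

    def __init__(self, counts: dict[str, int]):
        self.category_counts = counts
        super().__init__(
            "no candidate clusters form a return path with the baseline model "
            f"(CE edge categories: {counts})"
        )


@dataclass
class RunConfig:
    """File-based configuration mirroring the CLI."""

    model_path: str
    ce_path: str
    properties_path: str
    out_dir: str
    mcl: MCLConfig = field(default_factory=MCLConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    graph: ExtendedGraph
    partition: ClusterPartition
    candidates: list[CandidateModel]
    scored: list[CandidateScores]
    baseline_scores: Optional[CandidateScores]
    report: ScoreReport
    property_status: dict[str, str]
    estimates: pd.DataFrame

    @property
    def top_by_sigma(self) -> CandidateScores:
        """Best candidate by sigma-score; ties go to the most parsimonious
        extension (fewest added edges), then to the smallest id."""
        n_added = {cm.candidate_id: len(cm.added_edges) for cm in self.candidates}
        return min(
            self.scored,
            key=lambda c: (-c.sigma, n_added.get(c.candidate_id, 0), c.candidate_id),
        )

    def candidate(self, candidate_id: str) -> CandidateModel:
        for cm in self.candidates:
            if cm.candidate_id == candidate_id:
                return cm
        raise KeyError(candidate_id)


def check_properties(
    model: Model, ce: CandidateEventSet, properties: list[Property]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Classify every property element as present-in-BM, CE-only or absent.

    A property whose formula mentions an element absent from both
    V_BM and V_CE can never be satisfied by any candidate and is
    flagged ``unsatisfiable-input`` rather than silently scored.
    """
    ce_nodes_fold = {n.casefold() for n in ce.nodes}
    status: dict[str, str] = {}
    rows = []
    for prop in properties:
        ok = True
        for name in sorted(prop.elements):
            if model.resolve(name) is not None:
                where = "BM"
            elif name.casefold() in ce_nodes_fold:
                where = "CE-only"
            else:
                where = "absent"
                ok = False
            rows.append({"property": prop.id, "element": name, "location": where})
        status[prop.id] = "ok" if ok else "unsatisfiable-input"
    return status, pd.DataFrame(rows, columns=["property", "element", "location"])


def _score_model(
    model: Model,
    candidate_id: str,
    properties: list[Property],
    sim_config: SimulationConfig,
    node_overlap: float,
    delta: float,
) -> CandidateScores:
    """Simulate once, evaluate every property on the shared trace batch.

    A property whose elements are missing from this particular model is
    recorded as NaN and excluded from the aggregates.
    """
    traces = simulate(model, sim_config)
    estimates: dict[str, float] = {}
    for prop in properties:
        if any(model.resolve(n) is None for n in prop.elements):
            estimates[prop.id] = math.nan
            continue
        res = estimate_probability(model, prop, sim_config, traces=traces)
        estimates[prop.id] = res.estimate
    goals = {p.id: p.goal_probability for p in properties}
    return CandidateScores(candidate_id, estimates, goals, node_overlap, delta)


def run_pipeline(
    model: Model,
    ce: CandidateEventSet,
    properties: list[Property],
    mcl_config: Optional[MCLConfig] = None,
    sim_config: Optional[SimulationConfig] = None,
    scoring_config: Optional[ScoringConfig] = None,
    out_dir: Optional[str | Path] = None,
    score_baseline: bool = True,
) -> PipelineResult:
    """Run the full recommendation flow on in-memory inputs.

    Artifacts (cluster tables, candidate model files, estimate and
    score tables, a run log) are written when ``out_dir`` is given.
    """
    model.validate()
    mcl_config = mcl_config or MCLConfig()
    sim_config = sim_config or SimulationConfig()
    scoring_config = scoring_config or ScoringConfig()

    status, status_df = check_properties(model, ce, properties)
    scorable = [p for p in properties if status[p.id] == "ok"]
    if not scorable:
        raise ValidationError("no property has all its elements in V_BM ∪ V_CE")
    horizon = max(required_horizon(p.formula) for p in scorable)
    if sim_config.steps < horizon:
        raise ValidationError(
            f"simulation steps {sim_config.steps} below required horizon {horizon}"
        )

    graph = build_extended_graph(model, ce)
    partition = run_mcl(graph, mcl_config)
    candidates = assemble_all(model, partition, graph)
    if not candidates:
        raise NoCandidatesError(category_counts(graph))

    scored = [
        _score_model(cm.model, cm.candidate_id, scorable, sim_config,
                     cm.node_overlap, scoring_config.delta)
        for cm in candidates
    ]
    baseline_scores = None
    if score_baseline:
        bm_no = 1.0  # the baseline is all baseline nodes by definition
        baseline_scores = _score_model(
            model, "BM", scorable, sim_config, bm_no, scoring_config.delta
        )
    report = rank_candidates(scored, scoring_config)

    est_rows = []
    all_scored = scored + ([baseline_scores] if baseline_scores else [])
    for cs in all_scored:
        for pid in sorted(cs.estimates):
            est_rows.append(
                {"candidate": cs.candidate_id, "property": pid,
                 "estimate": cs.estimates[pid]}
            )
    estimates = pd.DataFrame(est_rows, columns=["candidate", "property", "estimate"])

    result = PipelineResult(
        graph=graph,
        partition=partition,
        candidates=candidates,
        scored=scored,
        baseline_scores=baseline_scores,
        report=report,
        property_status=status,
        estimates=estimates,
    )
    if out_dir is not None:
        _write_artifacts(
            Path(out_dir), result, status_df, model, mcl_config, sim_config, scoring_config
        )
    return result


def run_accordant(config: RunConfig) -> PipelineResult:
    """File-based entry point used by the CLI."""
    from .bltl import read_properties
    from .model import read_ce_set, read_model

    model = read_model(config.model_path)
    ce = read_ce_set(config.ce_path)
    properties = read_properties(config.properties_path)
    sim = config.sim
    sim.seed = config.seed
    return run_pipeline(
        model, ce, properties,
        mcl_config=config.mcl, sim_config=sim, scoring_config=config.scoring,
        out_dir=config.out_dir,
    )


def _write_artifacts(
    out: Path,
    result: PipelineResult,
    status_df: pd.DataFrame,
    model: Model,
    mcl_config: MCLConfig,
    sim_config: SimulationConfig,
    scoring_config: ScoringConfig,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "candidates").mkdir(exist_ok=True)

    rows = []
    for ci, cluster in enumerate(result.partition.clusters):
        for node in sorted(cluster):
            rows.append(
                {"node": node, "cluster": ci, "origin": result.graph.node_origin[node]}
            )
    pd.DataFrame(rows, columns=["node", "cluster", "origin"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "cluster": ci,
                "size": len(c),
                "n_bm": len(result.partition.bm_part[ci]),
                "n_ce": len(result.partition.ce_part[ci]),
                "node_overlap": result.partition.node_overlap[ci],
            }
            for ci, c in enumerate(result.partition.clusters)
        ]
    ).to_csv(out / "clusters_summary.tsv", sep="\t", index=False)

    export_graph(result.graph, out / "graph.tsv")

    manifest = []
    for cm in result.candidates:
        fname = f"CM_{cm.candidate_id}.tsv"
        write_model(cm.model, out / "candidates" / fname)
        manifest.append(
            {
                "candidate": cm.candidate_id,
                "clusters": "+".join(str(i) for i in cm.source_clusters),
                "n_added_edges": len(cm.added_edges),
                "node_overlap": cm.node_overlap,
                "model_file": f"candidates/{fname}",
            }
        )
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)

    result.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
    result.report.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
    status_df.to_csv(out / "property_status.tsv", sep="\t", index=False)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"modex {__version__}\n")
        fh.write(f"mcl: {mcl_config}\n")
        fh.write(f"sim: {sim_config}\n")
        fh.write(f"scoring: {scoring_config}\n")
        fh.write(f"elements: {len(model.elements)}\n")
        fh.write(f"ce_edges: {len(result.graph.ce_edges)}\n")
        fh.write(f"clusters: {len(result.partition.clusters)}\n")
        fh.write(f"candidates: {len(result.candidates)}\n")
        fh.write(f"recommended: {', '.join(result.report.recommended)}\n")


def sweep_inflation(
    model: Model,
    ce: CandidateEventSet,
    properties: list[Property],
    r_values: list[float],
    sim_config: Optional[SimulationConfig] = None,
    scoring_config: Optional[ScoringConfig] = None,
    score: bool = True,
) -> pd.DataFrame:
    """Cluster-granularity and score summary across inflation values.

    Larger r yields finer partitions; the table reports, per r, the
    cluster count, the number of candidates passing the return-path
    filter, and (optionally) the best sigma-score.
    """
    if len(r_values) < 2:
        raise ValueError("need at least two inflation values to sweep")
    rows = []
    for r in r_values:
        mcl_config = MCLConfig(inflation=r)
        row: dict[str, float] = {"r": r}
        try:
            result = run_pipeline(
                model, ce, properties,
                mcl_config=mcl_config, sim_config=sim_config,
                scoring_config=scoring_config, score_baseline=False,
            ) if score else None
        except NoCandidatesError:
            result = None
        if result is not None:
            row["n_clusters"] = len(result.partition.clusters)
            row["n_candidates"] = len(result.candidates)
            row["best_sigma"] = max(c.sigma for c in result.scored)
        else:
            graph = build_extended_graph(model, ce)
            partition = run_mcl(graph, MCLConfig(inflation=r))
            candidates = assemble_all(model, partition, graph)
            row["n_clusters"] = len(partition.clusters)
            row["n_candidates"] = len(candidates)
            row["best_sigma"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["r", "n_clusters", "n_candidates", "best_sigma"])
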