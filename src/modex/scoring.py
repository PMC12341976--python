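"""Candidate scoring and recommendation.

Given per-candidate property probability estimates p_t and the goal
probabilities P_t, the metrics are:

* model property error        eps_t   = |p_t - P_t|
* average model error         eps_avg = mean_t eps_t
* sigma-score                 sigma   = 1 - eps_avg           (higher = better)
* delta-score (percent)       N_delta = 100 * #{t : eps_t <= delta} / |T|
* joint property probability  p~      = prod_t p_t   (independence assumption)

Candidates are additionally ranked by the node overlap NO of their
generating cluster.  Each metric is min-max normalized across the
candidate set so the best candidate per metric is 1.0; the recommended
set is the union of per-metric winners — different metrics can and do
disagree, and all tied winners are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


@dataclass
class ScoringConfig:
    delta: float = 0.3
    normalization: str = "minmax"
    joint_rule: str = "product"

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")
        if self.normalization not in ("minmax", "none"):
            raise ValueError("normalization must be 'minmax' or 'none'")
        if self.joint_rule != "product":
            raise ValueError("only the product joint rule is implemented")


def property_error(p: float, goal: float) -> float:
    """eps_t = |p_t - P_t|."""
    for v in (p, goal):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"probability {v} out of [0, 1]")
    return abs(p - goal)


def average_error(errors: list[float]) -> float:
    if not errors:
        raise ValueError("no property errors to average")
    return sum(errors) / len(errors)


def sigma_score(errors: list[float]) -> float:
    """sigma = 1 - mean error; 1 means all goals met exactly."""
    return 1.0 - average_error(errors)


def delta_score(errors: list[float], delta: float) -> float:
    """Percent of properties with error within delta of the goal."""
    if not errors:
        raise ValueError("no property errors to score")
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must be in [0, 1]")
    return 100.0 * sum(1 for e in errors if e <= delta) / len(errors)


def joint_probability(estimates: list[float]) -> float:
    """p~ = product of per-property estimates (independence assumption)."""
    return math.prod(estimates) if estimates else float("nan")


@dataclass
class CandidateScores:
    """Scores for one candidate; NaN estimates (properties whose elements
    the candidate lacks) are excluded from the aggregates and counted in
    ``unsupported``."""

    candidate_id: str
    estimates: dict[str, float]
    goals: dict[str, float]
    node_overlap: float
    delta: float = 0.3

    errors: dict[str, float] = field(init=False)
    unsupported: list[str] = field(init=False)

    def __post_init__(self):
        self.errors = {}
        self.unsupported = []
        for pid, p in self.estimates.items():
            if p is None or (isinstance(p, float) and math.isnan(p)):
                self.unsupported.append(pid)
            else:
                self.errors[pid] = property_error(p, self.goals[pid])

    @property
    def error_list(self) -> list[float]:
        return [self.errors[k] for k in sorted(self.errors)]

    @property
    def eps_avg(self) -> float:
        return average_error(self.error_list)

    @property
    def sigma(self) -> float:
        return sigma_score(self.error_list)

    @property
    def delta_score(self) -> float:
        return delta_score(self.error_list, self.delta)

    @property
    def joint(self) -> float:
        return joint_probability(
            [self.estimates[k] for k in sorted(self.errors)]
        )


METRICS = ("sigma", "delta_score", "joint", "node_overlap")


@dataclass
class ScoreReport:
    candidates: list[CandidateScores]
    normalized: dict[str, dict[str, float]]  # metric -> candidate_id -> value
    best: dict[str, list[str]]  # metric -> tied winners
    recommended: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "candidate": c.candidate_id,
                "eps_avg": c.eps_avg,
                "sigma": c.sigma,
                "delta_score": c.delta_score,
                "joint": c.joint,
                "node_overlap": c.node_overlap,
                "n_properties": len(c.errors),
                "n_unsupported": len(c.unsupported),
            }
            for m in METRICS:
                row[f"{m}_norm"] = self.normalized[m][c.candidate_id]
            row["recommended"] = c.candidate_id in self.recommended
            rows.append(row)
        return pd.DataFrame(rows)

    def estimates_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: candidate, property, estimate."""
        rows = [
            {"candidate": c.candidate_id, "property": pid, "estimate": p}
            for c in self.candidates
            for pid, p in sorted(c.estimates.items())
        ]
        return pd.DataFrame(rows, columns=["candidate", "property", "estimate"])


def _minmax(values: dict[str, float]) -> dict[str, float]:
    finite = [v for v in values.values() if not math.isnan(v)]
    lo, hi = min(finite), max(finite)
    if hi == lo:
        return {k: 1.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def rank_candidates(
    scored: list[CandidateScores], config: Optional[ScoringConfig] = None
) -> ScoreReport:
    """Normalize metrics, find per-metric winners, and recommend.

    All metrics here are higher-is-better; ties are all reported, and
    the recommended set is the union of winners across the four metrics.
    """
    if not scored:
        raise ValueError("no candidates to rank")
    config = config or ScoringConfig()
    raw = {
        "sigma": {c.candidate_id: c.sigma for c in scored},
        "delta_score": {c.candidate_id: c.delta_score for c in scored},
        "joint": {c.candidate_id: c.joint for c in scored},
        "node_overlap": {c.candidate_id: c.node_overlap for c in scored},
    }
    if config.normalization == "minmax":
        normalized = {m: _minmax(v) for m, v in raw.items()}
    else:
        normalized = raw
    best: dict[str, list[str]] = {}
    for m, vals in raw.items():
        finite = {k: v for k, v in vals.items() if not math.isnan(v)}
        top = max(finite.values())
        best[m] = sorted(k for k, v in finite.items() if v == top)
    recommended = sorted({cid for winners in best.values() for cid in winners})
    return ScoreReport(scored, normalized, best, recommended)
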