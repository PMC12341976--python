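"""Stochastic discrete-state simulation of executable models.

Each element holds a discrete state in [0, levels-1].  An element's
next target is levels-1 when its rule fires and 0 otherwise, where the
rule fires iff the positive influence expression is true AND the
negative influence expression is false (an element with only negative
regulators fires iff none of them is active; an element with no
regulators at all holds its state).  Multi-level elements move one
increment per update toward the target, so Boolean elements switch in
one update.

Two schemes are provided:

* ``synchronous`` — every element updates simultaneously each step from
  the previous state (deterministic given the initial state);
* ``random_asynchronous`` — each step one element, chosen uniformly at
  random, updates while all others hold; this is the default and is the
  source of run-to-run stochasticity.

All randomness flows from a single integer seed; run k of a batch uses
the substream ``seed + k``, so batches are reproducible and individual
runs re-creatable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import Model, ValidationError
from .rules import RuleNode

Truthy = Callable[[np.ndarray], bool]


@dataclass
class SimulationConfig:
    scheme: str = "random_asynchronous"
    steps: int = 100
    runs: int = 200
    seed: int = 0
    scenario: str = "1"

    def __post_init__(self):
        if self.scheme not in ("synchronous", "random_asynchronous"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.steps < 1 or self.runs < 1:
            raise ValueError("steps and runs must be positive")


@dataclass
class Trace:
    """One run's trajectories: states[t, i] is element i's state at step t."""

    elements: list[str]
    states: np.ndarray  # shape (steps+1, n_elements), integer
    run_id: int
    seed: int

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.elements.index(name)]

    @property
    def steps(self) -> int:
        return self.states.shape[0] - 1


def _compile_rule(node: RuleNode | None, index: dict[str, int]):
    """Compile a rule AST into a closure over the state vector.

    A variable is truthy when its state is > 0.  Returns None for an
    empty expression.
    """
    if node is None:
        return None
    op = node[0]
    if op == "var":
        i = index[node[1]]
        return lambda s: s[i] > 0
    if op == "not":
        f = _compile_rule(node[1], index)
        return lambda s: not f(s)
    a = _compile_rule(node[1], index)
    b = _compile_rule(node[2], index)
    if op == "and":
        return lambda s: a(s) and b(s)
    return lambda s: a(s) or b(s)


class _CompiledModel:
    def __init__(self, model: Model):
        model.validate()
        self.order = list(model.elements)
        index = {n: i for i, n in enumerate(self.order)}
        self.levels = np.array([model.elements[n].levels for n in self.order])
        self.targets = []
        for name in self.order:
            el = model.elements[name]
            idx = {ref: index[model.resolve(ref)] for ref in
                   (el.regulators("+") | el.regulators("-"))}
            pos = _compile_rule(el.positive, idx)
            neg = _compile_rule(el.negative, idx)
            if pos is None and neg is None:
                self.targets.append(None)  # no regulators: hold state
            else:
                self.targets.append(self._make_target(pos, neg))

    @staticmethod
    def _make_target(pos, neg):
        def fires(s) -> bool:
            p = True if pos is None else pos(s)
            n = False if neg is None else neg(s)
            return p and not n
        return fires

    def initial_state(self, model: Model, scenario: str) -> np.ndarray:
        if scenario not in model.scenarios:
            raise ValidationError(f"scenario {scenario!r} not defined in model")
        return np.array(
            [model.elements[n].initial.get(scenario, 0) for n in self.order],
            dtype=np.int64,
        )

    def update_one(self, state: np.ndarray, i: int) -> None:
        fires = self.targets[i]
        if fires is None:
            return
        target = self.levels[i] - 1 if fires(state) else 0
        if state[i] < target:
            state[i] += 1
        elif state[i] > target:
            state[i] -= 1


def simulate(model: Model, config: SimulationConfig) -> list[Trace]:
    """Run the configured number of seeded simulations.

    Identical (model, config) always yields bit-identical traces.
    """
    cm = _CompiledModel(model)
    init = cm.initial_state(model, config.scenario)
    n = len(cm.order)
    traces: list[Trace] = []
    for run in range(config.runs):
        run_seed = config.seed + run
        rng = np.random.default_rng(run_seed)
        states = np.empty((config.steps + 1, n), dtype=np.int64)
        states[0] = init
        state = init.copy()
        if config.scheme == "synchronous":
            for t in range(1, config.steps + 1):
                prev = state.copy()
                for i in range(n):
                    fires = cm.targets[i]
                    if fires is None:
                        continue
                    target = cm.levels[i] - 1 if fires(prev) else 0
                    if state[i] < target:
                        state[i] += 1
                    elif state[i] > target:
                        state[i] -= 1
                states[t] = state
        else:
            picks = rng.integers(0, n, size=config.steps)
            for t in range(1, config.steps + 1):
                cm.update_one(state, int(picks[t - 1]))
                states[t] = state
        traces.append(Trace(cm.order, states, run, run_seed))
    return traces


def state_distribution(
    model: Model, config: SimulationConfig, step: int
) -> dict[tuple[int, ...], float]:
    """Empirical distribution of the full state vector at a given step."""
    if step > config.steps:
        raise ValueError("step exceeds configured trace length")
    counts: dict[tuple[int, ...], int] = {}
    traces = simulate(model, config)
    for tr in traces:
        key = tuple(int(v) for v in tr.states[step])
        counts[key] = counts.get(key, 0) + 1
    total = len(traces)
    return {k: v / total for k, v in counts.items()}


def write_traces(traces: list[Trace], path) -> None:
    """Export traces as TSV: one row per (run, step), one column per element."""
    import pandas as pd

    rows = []
    for tr in traces:
        for t in range(tr.states.shape[0]):
            row = {"run": tr.run_id, "step": t}
            row.update({e: int(v) for e, v in zip(tr.elements, tr.states[t])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
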