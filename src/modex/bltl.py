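"""Bounded Linear Temporal Logic (BLTL) properties and statistical
model checking.

A property pairs a BLTL formula with a *goal probability* P_t in [0,1]:
the likelihood with which the real (or desired) system exhibits the
behavior.  Formulas are built from atoms ``element cmp constant``
(cmp in =, <, >, <=, >=), Boolean connectives ``not``/``and``/``or``,
and the bounded temporal operators

* ``F[k] phi`` — phi holds at some step within the next k,
* ``G[k] phi`` — phi holds at every step of the next k,
* ``phi U[k] psi`` — psi holds within k steps and phi holds until then.

Example: ``F[20]G[5](IL2 = 1 and STAT5 = 1)`` — within 20 steps both
elements become active and stay active for 5 steps.

Satisfaction probabilities are estimated by fixed-sample statistical
model checking: simulate N seeded runs, evaluate the formula at trace
position 0 on each, report the satisfied fraction together with a
Chernoff–Hoeffding half-width eps such that
P(|estimate - p| > eps) <= alpha, i.e. eps = sqrt(ln(2/alpha) / (2N)).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import FormatError, Model
from .simulate import SimulationConfig, Trace, simulate

BltlNode = tuple

_CMP_OPS = {"=": "=", "==": "=", "<": "<", ">": ">", "<=": "<=", ">=": ">="}

_TOK_RE = re.compile(
    r"\s*(?:(?P<temporal>[FGU])\s*\[\s*(?P<bound>-?\d+)\s*\]"
    r"|(?P<lp>\()|(?P<rp>\))"
    r"|(?P<cmp><=|>=|==|=|<|>)"
    r"|(?P<num>\d+)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_.\-]*))"
)


class BltlSyntaxError(ValueError):
    """Raised when a BLTL formula cannot be parsed."""


class EvaluationError(ValueError):
    """Raised when a trace is too short or an atom cannot be resolved."""


@dataclass
class Property:
    id: str
    formula: BltlNode
    goal_probability: float
    text: str = ""

    def __post_init__(self):
        if not (0.0 <= self.goal_probability <= 1.0):
            raise ValueError("goal probability must be in [0, 1]")

    @property
    def elements(self) -> set[str]:
        return formula_elements(self.formula)


@dataclass
class CheckResult:
    property_id: str
    estimate: float
    runs: int
    half_width: float
    verdicts: Optional[list[bool]] = field(default=None, repr=False)


def _tokenize(text: str):
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOK_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                return
            raise BltlSyntaxError(f"unexpected character {text[pos]!r} at position {pos}")
        pos = m.end()
        if m.group("temporal"):
            bound = int(m.group("bound"))
            if bound < 0:
                raise BltlSyntaxError(
                    f"negative bound {bound} at position {m.start()}"
                )
            yield (m.group("temporal"), bound, m.start())
        elif m.group("lp"):
            yield ("(", None, m.start())
        elif m.group("rp"):
            yield (")", None, m.start())
        elif m.group("cmp"):
            yield ("cmp", _CMP_OPS[m.group("cmp")], m.start())
        elif m.group("num"):
            yield ("num", int(m.group("num")), m.start())
        else:
            word = m.group("word")
            lw = word.lower()
            if lw in ("and", "or", "not"):
                yield (lw, None, m.start())
            else:
                yield ("ident", word, m.start())


class _Parser:
    """Precedence: U is lowest, then or < and < not/F/G (prefix, tightest)."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise BltlSyntaxError(f"unexpected end of formula: {self.text!r}")
        self.i += 1
        return tok

    def parse(self) -> BltlNode:
        node = self.until()
        tok = self.peek()
        if tok is not None:
            raise BltlSyntaxError(f"trailing input at position {tok[2]} in {self.text!r}")
        return node

    def until(self) -> BltlNode:
        left = self.disjunction()
        tok = self.peek()
        if tok is not None and tok[0] == "U":
            self.next()
            right = self.until()  # right-associative
            return ("U", tok[1], left, right)
        return left

    def disjunction(self) -> BltlNode:
        node = self.conjunction()
        while (tok := self.peek()) is not None and tok[0] == "or":
            self.next()
            node = ("or", node, self.conjunction())
        return node

    def conjunction(self) -> BltlNode:
        node = self.unary()
        while (tok := self.peek()) is not None and tok[0] == "and":
            self.next()
            node = ("and", node, self.unary())
        return node

    def unary(self) -> BltlNode:
        tok = self.peek()
        if tok is None:
            raise BltlSyntaxError(f"unexpected end of formula: {self.text!r}")
        kind = tok[0]
        if kind == "not":
            self.next()
            return ("not", self.unary())
        if kind in ("F", "G"):
            self.next()
            return (kind, tok[1], self.unary())
        return self.primary()

    def primary(self) -> BltlNode:
        kind, value, pos = self.next()
        if kind == "(":
            node = self.until()
            k2, _, p2 = self.next()
            if k2 != ")":
                raise BltlSyntaxError(f"expected ')' at position {p2} in {self.text!r}")
            return node
        if kind == "ident":
            ck, cv, cp = self.next()
            if ck != "cmp":
                raise BltlSyntaxError(f"expected comparison at position {cp} in {self.text!r}")
            nk, nv, np_ = self.next()
            if nk != "num":
                raise BltlSyntaxError(f"expected constant at position {np_} in {self.text!r}")
            return ("atom", value, cv, nv)
        raise BltlSyntaxError(f"unexpected token at position {pos} in {self.text!r}")


def parse_formula(text: str) -> BltlNode:
    if not text or not text.strip():
        raise BltlSyntaxError("empty formula")
    return _Parser(text).parse()


def parse_property(text: str, goal_probability: float, prop_id: str = "t") -> Property:
    """Parse a formula string; the goal probability is supplied separately
    (it lives in its own column of the property file, not in the formula)."""
    return Property(prop_id, parse_formula(text), goal_probability, text.strip())


def formula_elements(node: BltlNode) -> set[str]:
    op = node[0]
    if op == "atom":
        return {node[1]}
    if op in ("not",):
        return formula_elements(node[1])
    if op in ("and", "or"):
        return formula_elements(node[1]) | formula_elements(node[2])
    if op in ("F", "G"):
        return formula_elements(node[2])
    if op == "U":
        return formula_elements(node[2]) | formula_elements(node[3])
    raise ValueError(f"unknown node {op!r}")


def required_horizon(node: BltlNode) -> int:
    """Minimal steps beyond index 0 so evaluation never reads past the trace."""
    op = node[0]
    if op == "atom":
        return 0
    if op == "not":
        return required_horizon(node[1])
    if op in ("and", "or"):
        return max(required_horizon(node[1]), required_horizon(node[2]))
    if op in ("F", "G"):
        return node[1] + required_horizon(node[2])
    if op == "U":
        return node[1] + max(required_horizon(node[2]), required_horizon(node[3]))
    raise ValueError(f"unknown node {op!r}")


def _cmp(a: int, op: str, b: int) -> bool:
    if op == "=":
        return a == b
    if op == "<":
        return a < b
    if op == ">":
        return a > b
    if op == "<=":
        return a <= b
    return a >= b


def evaluate_on_trace(node: BltlNode, trace, position: int = 0) -> bool:
    """Evaluate a formula on a finite trace at the given position.

    ``trace`` is a :class:`~modex.simulate.Trace` or a mapping from
    element name to a state sequence.  Raises :class:`EvaluationError`
    rather than silently truncating a too-short trace.
    """
    if isinstance(trace, Trace):
        series = {name: trace.states[:, i] for i, name in enumerate(trace.elements)}
    else:
        series = trace
    length = min(len(v) for v in series.values()) if series else 0
    horizon = required_horizon(node)
    if position + horizon > length - 1:
        raise EvaluationError(
            f"trace of length {length - 1} too short: need position "
            f"{position} + horizon {horizon}"
        )

    def ev(n: BltlNode, t: int) -> bool:
        op = n[0]
        if op == "atom":
            _, name, cmp_op, const = n
            if name not in series:
                raise EvaluationError(f"atom references unknown element {name!r}")
            return _cmp(int(series[name][t]), cmp_op, const)
        if op == "not":
            return not ev(n[1], t)
        if op == "and":
            return ev(n[1], t) and ev(n[2], t)
        if op == "or":
            return ev(n[1], t) or ev(n[2], t)
        if op == "F":
            return any(ev(n[2], j) for j in range(t, t + n[1] + 1))
        if op == "G":
            return all(ev(n[2], j) for j in range(t, t + n[1] + 1))
        # U
        k, phi, psi = n[1], n[2], n[3]
        for j in range(t, t + k + 1):
            if ev(psi, j):
                return True
            if not ev(phi, j):
                return False
        return False

    return ev(node, position)


def hoeffding_half_width(runs: int, alpha: float = 0.05) -> float:
    """Two-sided Chernoff–Hoeffding bound for a mean of N Bernoulli draws."""
    return math.sqrt(math.log(2.0 / alpha) / (2.0 * runs))


def estimate_probability(
    model: Model,
    prop: Property,
    sim_config: SimulationConfig,
    alpha: float = 0.05,
    traces: Optional[list[Trace]] = None,
) -> CheckResult:
    """Estimate P(model satisfies formula) from seeded simulations.

    ``traces`` may be supplied to share one simulation batch across
    several properties; otherwise the model is simulated here.  The
    configured steps must cover the formula's required horizon.
    """
    horizon = required_horizon(prop.formula)
    if sim_config.steps < horizon:
        raise ValueError(
            f"property {prop.id}: needs {horizon} steps, config has {sim_config.steps}"
        )
    if traces is None:
        traces = simulate(model, sim_config)
    verdicts = [evaluate_on_trace(prop.formula, tr, 0) for tr in traces]
    estimate = sum(verdicts) / len(verdicts)
    return CheckResult(
        property_id=prop.id,
        estimate=estimate,
        runs=len(verdicts),
        half_width=hoeffding_half_width(len(verdicts), alpha),
        verdicts=verdicts,
    )


def read_properties(path: str | Path) -> list[Property]:
    """Load properties from a TSV with columns id, formula, goal probability."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def canon(c: str) -> str:
        return re.sub(r"\s+", " ", c.strip().lower())

    cols = list(df.columns)
    id_col = next((c for c in cols if canon(c) in {"id", "property", "property id", "name"}), None)
    f_col = next((c for c in cols if canon(c) in {"formula", "bltl", "bltl formula", "property formula"}), None)
    p_col = next(
        (c for c in cols if canon(c).startswith("goal") or canon(c) in {"probability", "p_t", "pt"}),
        None,
    )
    if id_col is None or f_col is None or p_col is None:
        raise FormatError("property file needs id, formula and goal probability columns")
    props = []
    for i, row in df.iterrows():
        try:
            props.append(
                parse_property(str(row[f_col]), float(row[p_col]), str(row[id_col]).strip())
            )
        except (BltlSyntaxError, ValueError) as exc:
            raise FormatError(f"row {i + 1}: {exc}") from exc
    return props


def write_properties(props: list[Property], path: str | Path) -> None:
    rows = [
        {"id": p.id, "Formula": p.text or _unparse(p.formula), "Goal probability": p.goal_probability}
        for p in props
    ]
    pd.DataFrame(rows, columns=["id", "Formula", "Goal probability"]).to_csv(
        path, sep="\t", index=False
    )


def _unparse(node: BltlNode) -> str:
    op = node[0]
    if op == "atom":
        return f"{node[1]} {node[2]} {node[3]}"
    if op == "not":
        return f"not ({_unparse(node[1])})"
    if op in ("and", "or"):
        return f"({_unparse(node[1])}) {op} ({_unparse(node[2])})"
    if op in ("F", "G"):
        return f"{op}[{node[1]}]({_unparse(node[2])})"
    return f"({_unparse(node[2])}) U[{node[1]}] ({_unparse(node[3])})"
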