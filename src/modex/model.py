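"""Data model and I/O for discrete executable network models and
candidate-event (CE) sets.

A model is a table of elements; each element carries a positive and a
negative influence set (rule expressions over other element names), a
number of discrete levels (2 = Boolean), and one initial value per
scenario.  The induced directed graph G_BM has an edge v_i -> v_j
whenever v_i appears in v_j's regulator expressions.

A CE set is a signed directed edge list: interactions harvested from
literature or databases that are candidates for extending the model.

File dialect: tab-separated values with a fixed header.  Model columns
are ``Element``, ``Positive Regulators``, ``Negative Regulators``,
``Levels`` (optional) and one or more ``Initial <scenario-id>`` columns;
CE columns are ``Regulator``, ``Sign``, ``Target`` plus optional
``Provenance`` and ``Score``.  Column matching is case-insensitive with
common aliases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .rules import (
    RuleNode,
    parse_rule,
    rule_identifiers,
    rule_to_string,
    rename_identifiers,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A model or edge set violates a structural invariant."""


def normalize_name(name: str) -> str:
    """Trim and replace internal whitespace with underscores; case kept."""
    return re.sub(r"\s+", "_", name.strip())


@dataclass
class Element:
    """One model element (protein, gene, chemical, process)."""

    name: str
    positive: Optional[RuleNode] = None
    negative: Optional[RuleNode] = None
    levels: int = 2
    initial: dict[str, int] = field(default_factory=dict)

    def regulators(self, sign: str) -> set[str]:
        node = self.positive if sign == "+" else self.negative
        return rule_identifiers(node)

    def copy(self) -> "Element":
        return replace(self, initial=dict(self.initial))


@dataclass(frozen=True)
class SignedEdge:
    """A signed directed interaction: source --(+/-)--> target."""

    source: str
    target: str
    sign: str
    provenance: str = ""
    score: Optional[float] = None

    def __post_init__(self):
        if not self.source or not self.target:
            raise ValidationError("edge endpoints must be nonempty")
        if self.sign not in ("+", "-"):
            raise ValidationError(f"sign must be '+' or '-', got {self.sign!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.sign)


class Model:
    """An executable discrete model: ordered elements plus scenarios."""

    def __init__(self, elements: Iterable[Element] = (), scenarios: Iterable[str] = ()):
        self.elements: dict[str, Element] = {}
        self.scenarios: list[str] = list(scenarios)
        for el in elements:
            self.add_element(el)

    def add_element(self, el: Element) -> None:
        if self._fold(el.name) in self._by_fold:
            raise ValidationError(f"duplicate element name: {el.name}")
        self.elements[el.name] = el
        for sc in el.initial:
            if sc not in self.scenarios:
                self.scenarios.append(sc)

    @staticmethod
    def _fold(name: str) -> str:
        return name.casefold()

    @property
    def _by_fold(self) -> dict[str, str]:
        return {self._fold(n): n for n in self.elements}

    def resolve(self, name: str) -> Optional[str]:
        """Case-insensitive lookup of a canonical element name."""
        return self._by_fold.get(self._fold(name))

    @property
    def nodes(self) -> set[str]:
        return set(self.elements)

    def edges(self) -> list[SignedEdge]:
        """Project regulator expressions onto the signed edge set E_BM."""
        out: list[SignedEdge] = []
        seen: set[tuple[str, str, str]] = set()
        for el in self.elements.values():
            for sign in ("+", "-"):
                for src in sorted(el.regulators(sign)):
                    canonical = self.resolve(src) or src
                    key = (canonical, el.name, sign)
                    if key not in seen:
                        seen.add(key)
                        out.append(SignedEdge(canonical, el.name, sign))
        return out

    def validate(self) -> None:
        """Check name resolution, level ranges and initial values."""
        for el in self.elements.values():
            if el.levels < 2:
                raise ValidationError(f"{el.name}: levels must be >= 2")
            for ref in el.regulators("+") | el.regulators("-"):
                if self.resolve(ref) is None:
                    raise ValidationError(
                        f"{el.name}: rule references unknown element {ref!r}"
                    )
            for sc, val in el.initial.items():
                if not (0 <= val <= el.levels - 1):
                    raise ValidationError(
                        f"{el.name}: initial value {val} out of range for scenario {sc}"
                    )

    def canonicalize_rules(self) -> None:
        """Rewrite rule identifiers to canonical element-name casing."""
        for el in self.elements.values():
            el.positive = rename_identifiers(el.positive, lambda n: self.resolve(n) or n)
            el.negative = rename_identifiers(el.negative, lambda n: self.resolve(n) or n)

    def copy(self) -> "Model":
        m = Model()
        m.scenarios = list(self.scenarios)
        for el in self.elements.values():
            m.elements[el.name] = el.copy()
        return m

    def __eq__(self, other) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        if list(self.elements) != list(other.elements):
            return False
        for a, b in zip(self.elements.values(), other.elements.values()):
            if (a.name, a.positive, a.negative, a.levels, a.initial) != (
                b.name,
                b.positive,
                b.negative,
                b.levels,
                b.initial,
            ):
                return False
        return set(self.scenarios) == set(other.scenarios)

    def __repr__(self) -> str:
        return f"Model({len(self.elements)} elements, scenarios={self.scenarios})"


@dataclass
class CandidateEventSet:
    """A set of signed directed candidate interactions (E_CE, V_CE)."""

    edges: list[SignedEdge] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        return out

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# tabular I/O

_ELEMENT_ALIASES = {"element", "element name", "name", "variable"}
_SIGN_ALIASES = {
    "+": "+",
    "positive": "+",
    "pos": "+",
    "-": "-",
    "−": "-",
    "negative": "-",
    "neg": "-",
}


def _canon_header(col: str) -> str:
    return re.sub(r"\s+", " ", col.strip().lower())


def _find_column(columns: list[str], predicate, description: str) -> str:
    for col in columns:
        if predicate(_canon_header(col)):
            return col
    raise FormatError(f"missing required column: {description}")


def read_model(path: str | Path) -> Model:
    """Load a model from a TSV table.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` for duplicate names, unresolvable rule
    identifiers, or out-of-range initial values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    el_col = _find_column(cols, lambda c: c in _ELEMENT_ALIASES, "Element")
    pos_col = _find_column(cols, lambda c: c.startswith("positive"), "Positive Regulators")
    neg_col = _find_column(cols, lambda c: c.startswith("negative"), "Negative Regulators")
    lvl_col = next((c for c in cols if _canon_header(c) == "levels"), None)

    scen_cols: list[tuple[str, str]] = []
    for col in cols:
        c = _canon_header(col)
        if c.startswith("initial"):
            rest = col.strip()[len("initial"):].strip()
            scen_cols.append((col, normalize_name(rest) if rest else "1"))
    if not scen_cols:
        raise FormatError("missing required column: Initial <scenario-id>")

    model = Model()
    for i, row in df.iterrows():
        name = normalize_name(str(row[el_col]))
        if not name:
            raise ValidationError(f"row {i + 1}: empty element name")
        levels = 2
        if lvl_col is not None and str(row[lvl_col]).strip():
            levels = int(str(row[lvl_col]).strip())
        initial: dict[str, int] = {}
        for col, scen in scen_cols:
            raw = str(row[col]).strip()
            initial[scen] = int(raw) if raw else 0
        el = Element(
            name=name,
            positive=parse_rule(str(row[pos_col])),
            negative=parse_rule(str(row[neg_col])),
            levels=levels,
            initial=initial,
        )
        model.add_element(el)

    model.canonicalize_rules()
    model.validate()
    return model


def write_model(model: Model, path: str | Path) -> None:
    """Write a model as TSV; ``read_model`` round-trips it identically."""
    model.validate()
    scen = model.scenarios or ["1"]
    rows = []
    for el in model.elements.values():
        row = {
            "Element": el.name,
            "Positive Regulators": rule_to_string(el.positive),
            "Negative Regulators": rule_to_string(el.negative),
            "Levels": el.levels,
        }
        for sc in scen:
            row[f"Initial {sc}"] = el.initial.get(sc, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ce_set(path: str | Path) -> CandidateEventSet:
    """Load a CE set from a TSV edge list, collapsing exact duplicates.

    Duplicate (source, target, sign) triples are merged into one edge
    with provenance strings concatenated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    src_col = _find_column(
        cols, lambda c: c in {"regulator", "source", "element 1", "src"}, "Regulator"
    )
    sign_col = _find_column(cols, lambda c: c in {"sign", "interaction"}, "Sign")
    tgt_col = _find_column(cols, lambda c: c in {"target", "destination", "tgt"}, "Target")
    prov_col = next((c for c in cols if _canon_header(c) == "provenance"), None)
    score_col = next((c for c in cols if _canon_header(c) == "score"), None)

    merged: dict[tuple[str, str, str], SignedEdge] = {}
    for i, row in df.iterrows():
        raw_sign = str(row[sign_col]).strip().lower()
        if raw_sign not in _SIGN_ALIASES:
            raise FormatError(f"row {i + 1}: unrecognized sign {row[sign_col]!r}")
        sign = _SIGN_ALIASES[raw_sign]
        src = normalize_name(str(row[src_col]))
        tgt = normalize_name(str(row[tgt_col]))
        if not src or not tgt:
            raise FormatError(f"row {i + 1}: empty endpoint")
        prov = str(row[prov_col]).strip() if prov_col is not None else ""
        score = None
        if score_col is not None and str(row[score_col]).strip():
            score = float(str(row[score_col]).strip())
        key = (src, tgt, sign)
        if key in merged:
            old = merged[key]
            prov_cat = "; ".join(p for p in (old.provenance, prov) if p)
            merged[key] = SignedEdge(src, tgt, sign, prov_cat, old.score)
        else:
            merged[key] = SignedEdge(src, tgt, sign, prov, score)

    ce = CandidateEventSet(list(merged.values()))
    if not ce.edges:
        logger.warning("CE set at %s is empty", path)
    logger.info("CE set: %d edges over %d nodes", len(ce.edges), len(ce.nodes))
    return ce


def write_ce_set(ce: CandidateEventSet, path: str | Path) -> None:
    rows = [
        {
            "Regulator": e.source,
            "Sign": e.sign,
            "Target": e.target,
            "Provenance": e.provenance,
            "Score": "" if e.score is None else e.score,
        }
        for e in ce.edges
    ]
    cols = ["Regulator", "Sign", "Target", "Provenance", "Score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
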