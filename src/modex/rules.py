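"""Regulator rule expressions.

An element's positive or negative influence set is written as a small
Boolean expression over element names:

    ``A``            single regulator
    ``A, B``         comma list, read as ``A OR B``
    ``A AND NOT B``  keywords are case-insensitive
    ``(A OR B) AND C``

Precedence: ``NOT`` > ``AND`` > ``OR`` (a comma binds like ``OR``).
The AST is a nested tuple: ``('var', name)``, ``('not', x)``,
``('and', a, b)``, ``('or', a, b)``.
"""

from __future__ import annotations

import re
from typing import Iterator, Optional

RuleNode = tuple

_KEYWORDS = {"and", "or", "not"}

_TOKEN_RE = re.compile(r"\s*(?:(?P<lp>\()|(?P<rp>\))|(?P<comma>,)|(?P<word>[A-Za-z0-9_.\-]+))")


class RuleSyntaxError(ValueError):
    """Raised when a regulator expression cannot be parsed."""


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                return
            raise RuleSyntaxError(f"unexpected character {text[pos]!r} at position {pos}")
        pos = m.end()
        if m.group("lp"):
            yield ("(", "(", m.start())
        elif m.group("rp"):
            yield (")", ")", m.start())
        elif m.group("comma"):
            yield (",", ",", m.start())
        else:
            word = m.group("word")
            if word.lower() in _KEYWORDS:
                yield (word.lower(), word, m.start())
            else:
                yield ("ident", word, m.start())


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of expression: {self.text!r}")
        self.i += 1
        return tok

    def parse(self) -> RuleNode:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise RuleSyntaxError(f"trailing input at position {tok[2]} in {self.text!r}")
        return node

    def expr(self) -> RuleNode:
        node = self.term()
        while True:
            tok = self.peek()
            if tok is not None and tok[0] in ("or", ","):
                self.next()
                node = ("or", node, self.term())
            else:
                return node

    def term(self) -> RuleNode:
        node = self.factor()
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "and":
                self.next()
                node = ("and", node, self.factor())
            else:
                return node

    def factor(self) -> RuleNode:
        kind, value, pos = self.next()
        if kind == "not":
            return ("not", self.factor())
        if kind == "(":
            node = self.expr()
            k2, _, p2 = self.next()
            if k2 != ")":
                raise RuleSyntaxError(f"expected ')' at position {p2} in {self.text!r}")
            return node
        if kind == "ident":
            return ("var", value)
        raise RuleSyntaxError(f"unexpected {value!r} at position {pos} in {self.text!r}")


def parse_rule(text: str | None) -> Optional[RuleNode]:
    """Parse a regulator expression; empty/blank text yields ``None``."""
    if text is None or text.strip() == "":
        return None
    return _Parser(text).parse()


def rule_identifiers(node: Optional[RuleNode]) -> set[str]:
    """All element names referenced by the expression."""
    if node is None:
        return set()
    op = node[0]
    if op == "var":
        return {node[1]}
    if op == "not":
        return rule_identifiers(node[1])
    return rule_identifiers(node[1]) | rule_identifiers(node[2])


_PREC = {"or": 1, "and": 2, "not": 3, "var": 4}


def rule_to_string(node: Optional[RuleNode]) -> str:
    """Canonical text form; ``parse_rule(rule_to_string(x)) == x``."""
    if node is None:
        return ""

    def fmt(n: RuleNode, min_prec: int) -> str:
        op = n[0]
        if op == "var":
            return n[1]
        if op == "not":
            s = "NOT " + fmt(n[1], _PREC["not"])
        else:
            joiner = " OR " if op == "or" else " AND "
            # parsing is left-associative: right operand needs parens at
            # equal precedence to round-trip a right-nested tree
            s = fmt(n[1], _PREC[op]) + joiner + fmt(n[2], _PREC[op] + 1)
        if _PREC[op] < min_prec:
            s = "(" + s + ")"
        return s

    return fmt(node, 0)


def eval_rule(node: Optional[RuleNode], truth) -> bool:
    """Evaluate with ``truth(name) -> bool``; ``None`` evaluates to False."""
    if node is None:
        return False
    op = node[0]
    if op == "var":
        return bool(truth(node[1]))
    if op == "not":
        return not eval_rule(node[1], truth)
    if op == "and":
        return eval_rule(node[1], truth) and eval_rule(node[2], truth)
    return eval_rule(node[1], truth) or eval_rule(node[2], truth)


def rename_identifiers(node: Optional[RuleNode], mapping) -> Optional[RuleNode]:
    """Return a copy with each variable name passed through ``mapping``."""
    if node is None:
        return None
    op = node[0]
    if op == "var":
        return ("var", mapping(node[1]))
    if op == "not":
        return ("not", rename_identifiers(node[1], mapping))
    return (op, rename_identifiers(node[1], mapping), rename_identifiers(node[2], mapping))


def or_join(node: Optional[RuleNode], names: list[str]) -> Optional[RuleNode]:
    """Extend an expression with additional regulators via OR.

    ``or_join(parse_rule("C OR D"), ["A"])`` gives ``(C OR D) OR A``; the
    existing expression is kept verbatim as the left operand.
    """
    out = node
    for name in names:
        leaf = ("var", name)
        out = leaf if out is None else ("or", out, leaf)
    return out
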