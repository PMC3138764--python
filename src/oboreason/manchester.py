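"""Manchester-style text syntax for class expressions and axioms.

Grammar (whitespace-separated tokens; keywords are case-sensitive)::

    expr        := or_expr
    or_expr     := and_expr ( "or" and_expr )*
    and_expr    := primary ( "and" primary )*
    primary     := "not" primary
                 | IDENT ( "some" | "only" ) primary
                 | "Thing" | "Nothing" | IDENT
                 | "(" expr ")"

``some``/``only`` bind tighter than ``and``, which binds tighter than
``or``; ``not`` applies to the following primary.  Identifiers may contain
letters, digits, ``_ - : . ?`` (so OBO identifiers like ``GO:0005634`` and
the template placeholder ``?Y`` are single tokens).  ``Thing`` and
``Nothing`` denote the universal and empty class.

Axiom syntax: ``A SubClassOf: B``, ``A EquivalentTo: B``,
``DisjointClasses: A, B, C``.
"""

from __future__ import annotations

import re
from typing import List

from .dl import (
    And,
    Axiom,
    Bottom,
    ClassExpression,
    DisjointClasses,
    EquivalentClasses,
    Named,
    Not,
    Only,
    Or,
    Some,
    SubClassOf,
    Top,
    _Bottom,
    _Top,
)

KEYWORDS = {"some", "only", "and", "or", "not", "Thing", "Nothing"}

_TOKEN_RE = re.compile(r"\(|\)|,|[A-Za-z0-9_\-:.?'%]+")


class ParseError(ValueError):
    """Syntax error; carries the offending position for caret diagnostics."""

    def __init__(self, message: str, text: str, pos: int):
        self.text = text
        self.pos = pos
        caret = " " * pos + "^"
        super().__init__(f"{message}\n  {text}\n  {caret}")


def tokenize(text: str) -> List[tuple]:
    tokens = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        m = _TOKEN_RE.match(text, i)
        if not m:
            raise ParseError(f"unexpected character {text[i]!r}", text, i)
        tokens.append((m.group(0), i))
        i = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self):
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def next(self):
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.text, len(self.text))
        self.i += 1
        return tok

    def expect(self, tok: str):
        got = self.peek()
        if got != tok:
            raise ParseError(f"expected {tok!r}", self.text, self.pos())
        self.i += 1

    def parse_expr(self) -> ClassExpression:
        args = [self.parse_and()]
        while self.peek() == "or":
            self.next()
            args.append(self.parse_and())
        return Or.of(*args) if len(args) > 1 else args[0]

    def parse_and(self) -> ClassExpression:
        args = [self.parse_primary()]
        while self.peek() == "and":
            self.next()
            args.append(self.parse_primary())
        return And.of(*args) if len(args) > 1 else args[0]

    def parse_primary(self) -> ClassExpression:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.text, len(self.text))
        if tok == "not":
            self.next()
            return Not(self.parse_primary())
        if tok == "(":
            self.next()
            e = self.parse_expr()
            self.expect(")")
            return e
        if tok == "Thing":
            self.next()
            return Top
        if tok == "Nothing":
            self.next()
            return Bottom
        if tok in (")", ",", "some", "only", "and", "or"):
            raise ParseError(f"unexpected {tok!r}", self.text, self.pos())
        self.next()
        nxt = self.peek()
        if nxt in ("some", "only"):
            self.next()
            filler = self.parse_primary()
            return Some(tok, filler) if nxt == "some" else Only(tok, filler)
        return Named(tok)


def parse_expression(text: str) -> ClassExpression:
    p = _Parser(text)
    e = p.parse_expr()
    if p.peek() is not None:
        raise ParseError("trailing input", text, p.pos())
    return e


def parse_axiom(text: str) -> Axiom:
    text = text.strip()
    if text.startswith("DisjointClasses:"):
        body = text[len("DisjointClasses:"):]
        members = [parse_expression(part) for part in body.split(",")]
        return DisjointClasses(members)
    for kw, cls in (("SubClassOf:", SubClassOf), ("EquivalentTo:", EquivalentClasses)):
        if kw in text:
            left, right = text.split(kw, 1)
            return cls(parse_expression(left), parse_expression(right))
    raise ParseError("not an axiom (expected SubClassOf:/EquivalentTo:/DisjointClasses:)", text, 0)


# ---------------------------------------------------------------------------
# Printing
# ---------------------------------------------------------------------------

_PREC_OR, _PREC_AND, _PREC_PRIMARY = 1, 2, 3


def _render(e: ClassExpression, parent_prec: int) -> str:
    if isinstance(e, Named):
        return e.name
    if isinstance(e, _Top):
        return "Thing"
    if isinstance(e, _Bottom):
        return "Nothing"
    if isinstance(e, Not):
        return f"not {_render(e.arg, _PREC_PRIMARY)}"
    if isinstance(e, Some):
        return f"{e.role} some {_render(e.filler, _PREC_PRIMARY)}"
    if isinstance(e, Only):
        return f"{e.role} only {_render(e.filler, _PREC_PRIMARY)}"
    if isinstance(e, And):
        s = " and ".join(_render(a, _PREC_AND) for a in e.args)
        return f"({s})" if parent_prec >= _PREC_AND else s
    if isinstance(e, Or):
        s = " or ".join(_render(a, _PREC_OR) for a in e.args)
        return f"({s})" if parent_prec >= _PREC_OR else s
    raise TypeError(f"not a class expression: {e!r}")


def to_manchester(e: ClassExpression) -> str:
    """Serialize an expression; ``parse_expression`` round-trips it."""
    return _render(e, 0)


def axiom_to_manchester(ax: Axiom) -> str:
    if isinstance(ax, SubClassOf):
        return f"{to_manchester(ax.sub)} SubClassOf: {to_manchester(ax.sup)}"
    if isinstance(ax, EquivalentClasses):
        return f"{to_manchester(ax.a)} EquivalentTo: {to_manchester(ax.b)}"
    if isinstance(ax, DisjointClasses):
        return "DisjointClasses: " + ", ".join(to_manchester(m) for m in ax.members)
    raise TypeError(f"not an axiom: {ax!r}")
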