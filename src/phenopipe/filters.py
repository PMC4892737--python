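"""Color-filter expression language.

Background removal keeps pixels whose color satisfies a logical predicate
over the red/green/blue channels — the canonical example for green plants on
a blue or white background is ``g > b``.  Expressions are plain strings in
the processing template, parsed here into an AST and evaluated vectorised
over whole channel planes.

Grammar (standard precedence, lowest first)::

    or_expr   := and_expr ("or" and_expr)*
    and_expr  := not_expr ("and" not_expr)*
    not_expr  := "not" not_expr | comparison
    comparison:= additive (("<"|"<="|">"|">="|"="|"=="|"!="|"<>") additive)?
    additive  := multiplicative (("+"|"-") multiplicative)*
    multiplicative := unary (("*"|"/") unary)*
    unary     := "-" unary | atom
    atom      := "r" | "g" | "b" | integer | "(" or_expr ")"

Division is real-valued.  Evaluation is pure per pixel: the result for a
pixel depends only on that pixel's (r, g, b).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import FilterParseError

__all__ = ["FilterExpression", "parse_filter"]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+)|(?P<name>[A-Za-z_]+)|(?P<op><=|>=|==|!=|<>|[-+*/<>=()]))"
)

_CHANNELS = {"r": 0, "g": 1, "b": 2}
_KEYWORDS = {"and", "or", "not"}


@dataclass(frozen=True)
class _Token:
    kind: str  # "num" | "name" | "op" | "end"
    text: str
    pos: int


def _tokenize(source: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    while i < len(source):
        m = _TOKEN_RE.match(source, i)
        if m is None or m.end() == i:
            # skip leading whitespace before reporting
            j = i
            while j < len(source) and source[j].isspace():
                j += 1
            if j == len(source):
                break
            raise FilterParseError(f"unexpected character {source[j]!r}", j)
        kind = m.lastgroup or "op"
        tokens.append(_Token(kind, m.group(m.lastgroup), m.start(m.lastgroup)))
        i = m.end()
    tokens.append(_Token("end", "", len(source)))
    return tokens


# AST nodes are plain tuples: ("chan", idx) ("num", v) ("bin", op, l, r)
# ("cmp", op, l, r) ("bool", op, l, r) ("not", x) ("neg", x)
_Node = tuple


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, text: str) -> None:
        tok = self.next()
        if tok.kind != "op" or tok.text != text:
            raise FilterParseError(f"expected {text!r}, found {tok.text or 'end of input'!r}", tok.pos)

    def parse(self) -> _Node:
        node = self.or_expr()
        tok = self.peek()
        if tok.kind != "end":
            raise FilterParseError(f"unexpected trailing {tok.text!r}", tok.pos)
        return node

    def or_expr(self) -> _Node:
        node = self.and_expr()
        while self.peek().kind == "name" and self.peek().text == "or":
            self.next()
            node = ("bool", "or", node, self.and_expr())
        return node

    def and_expr(self) -> _Node:
        node = self.not_expr()
        while self.peek().kind == "name" and self.peek().text == "and":
            self.next()
            node = ("bool", "and", node, self.not_expr())
        return node

    def not_expr(self) -> _Node:
        tok = self.peek()
        if tok.kind == "name" and tok.text == "not":
            self.next()
            return ("not", self.not_expr())
        return self.comparison()

    def comparison(self) -> _Node:
        left = self.additive()
        tok = self.peek()
        if tok.kind == "op" and tok.text in ("<", "<=", ">", ">=", "=", "==", "!=", "<>"):
            self.next()
            op = {"=": "==", "<>": "!="}.get(tok.text, tok.text)
            return ("cmp", op, left, self.additive())
        return left

    def additive(self) -> _Node:
        node = self.multiplicative()
        while self.peek().kind == "op" and self.peek().text in ("+", "-"):
            op = self.next().text
            node = ("bin", op, node, self.multiplicative())
        return node

    def multiplicative(self) -> _Node:
        node = self.unary()
        while self.peek().kind == "op" and self.peek().text in ("*", "/"):
            op = self.next().text
            node = ("bin", op, node, self.unary())
        return node

    def unary(self) -> _Node:
        tok = self.peek()
        if tok.kind == "op" and tok.text == "-":
            self.next()
            return ("neg", self.unary())
        return self.atom()

    def atom(self) -> _Node:
        tok = self.next()
        if tok.kind == "num":
            return ("num", int(tok.text))
        if tok.kind == "name":
            if tok.text in _CHANNELS:
                return ("chan", _CHANNELS[tok.text])
            if tok.text in _KEYWORDS:
                raise FilterParseError(f"misplaced keyword {tok.text!r}", tok.pos)
            raise FilterParseError(f"unknown operand {tok.text!r}", tok.pos)
        if tok.kind == "op" and tok.text == "(":
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise FilterParseError(
            f"expected operand, found {tok.text or 'end of input'!r}", tok.pos
        )


def _eval(node: _Node, channels: np.ndarray):
    """Evaluate an AST over channels shaped (3, H, W); returns float or bool array."""
    kind = node[0]
    if kind == "chan":
        return channels[node[1]]
    if kind == "num":
        return float(node[1])
    if kind == "neg":
        return -_eval(node[1], channels)
    if kind == "bin":
        _, op, l, r = node
        lv, rv = _eval(l, channels), _eval(r, channels)
        if op == "+":
            return lv + rv
        if op == "-":
            return lv - rv
        if op == "*":
            return lv * rv
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.asarray(lv) / rv
    if kind == "cmp":
        _, op, l, r = node
        lv, rv = _eval(l, channels), _eval(r, channels)
        with np.errstate(invalid="ignore"):
            if op == "<":
                return lv < rv
            if op == "<=":
                return lv <= rv
            if op == ">":
                return lv > rv
            if op == ">=":
                return lv >= rv
            if op == "==":
                return lv == rv
            return lv != rv
    if kind == "bool":
        _, op, l, r = node
        lv, rv = np.asarray(_eval(l, channels), bool), np.asarray(_eval(r, channels), bool)
        return (lv & rv) if op == "and" else (lv | rv)
    if kind == "not":
        return ~np.asarray(_eval(node[1], channels), bool)
    raise AssertionError(f"unreachable node kind {kind}")


def _is_boolean(node: _Node) -> bool:
    return node[0] in ("cmp", "bool", "not")


@dataclass(frozen=True)
class FilterExpression:
    """A parsed per-pixel color predicate.

    Instances are immutable and reusable across images.  Construct with
    :func:`parse_filter` or ``FilterExpression.parse``.
    """

    source: str
    ast: _Node

    @classmethod
    def parse(cls, source: str) -> "FilterExpression":
        node = _Parser(source).parse()
        if not _is_boolean(node):
            raise FilterParseError(
                "expression must be a boolean predicate (use a comparison)", 0
            )
        return cls(source=source, ast=node)

    def evaluate(self, image: np.ndarray) -> np.ndarray:
        """Boolean (H, W) array: True where the pixel satisfies the predicate.

        ``image`` is an (H, W, 3) RGB array; arithmetic is done in float64.
        """
        channels = np.moveaxis(image.astype(np.float64), -1, 0)
        result = _eval(self.ast, channels)
        return np.broadcast_to(np.asarray(result, bool), image.shape[:2])

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.evaluate(image)


def parse_filter(source: Union[str, FilterExpression]) -> FilterExpression:
    """Parse ``source`` into a :class:`FilterExpression` (idempotent on instances)."""
    if isinstance(source, FilterExpression):
        return source
    return FilterExpression.parse(source)
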