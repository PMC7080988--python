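"""Boolean expression parsing, evaluation, and truth-table compilation.

Expressions are written over named variables with NOT/AND/OR (also
accepted: ``!``/``&``/``|`` and the Unicode connectives ``¬``/``∧``/``∨``)
plus parentheses and the constants ``0``/``1``.  They are the textual form
of update rules: each rule is parsed once and compiled to a truth table
over its regulators, which is the representation all dynamical code uses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "ExpressionError",
    "parse_expression",
    "expression_variables",
    "compile_truth_table",
    "format_expression",
]


class ExpressionError(ValueError):
    """Raised for malformed Boolean expressions."""


class Expr:
    """Base class for expression AST nodes."""

    def evaluate(self, values: Mapping[str, object]):
        raise NotImplementedError

    def variables(self) -> list[str]:
        """Variable names in order of first appearance."""
        seen: dict[str, None] = {}
        self._collect(seen)
        return list(seen)

    def _collect(self, seen: dict[str, None]) -> None:
        raise NotImplementedError


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, values):
        try:
            return values[self.name]
        except KeyError:
            raise ExpressionError(f"undefined variable {self.name!r}") from None

    def _collect(self, seen):
        seen.setdefault(self.name)


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def evaluate(self, values):
        return self.value

    def _collect(self, seen):
        pass


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, values):
        return self.operand.evaluate(values) ^ 1

    def _collect(self, seen):
        self.operand._collect(seen)


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, values):
        result = self.operands[0].evaluate(values)
        for op in self.operands[1:]:
            result = result & op.evaluate(values)
        return result

    def _collect(self, seen):
        for op in self.operands:
            op._collect(seen)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, values):
        result = self.operands[0].evaluate(values)
        for op in self.operands[1:]:
            result = result | op.evaluate(values)
        return result

    def _collect(self, seen):
        for op in self.operands:
            op._collect(seen)


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<not>!|¬|\bNOT\b)
  | (?P<and>&{1,2}|∧|\bAND\b)
  | (?P<or>\|{1,2}|∨|\bOR\b)
  | (?P<const>\b[01]\b)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    """,
    re.VERBOSE | re.IGNORECASE,
)


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise ExpressionError(
                f"unexpected character {text[pos]!r} at position {pos} in {text!r}"
            )
        pos = match.end()
        kind = match.lastgroup
        if kind != "ws":
            yield kind, match.group()
    yield "end", ""


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.pos]

    def advance(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str) -> str:
        got_kind, value = self.advance()
        if got_kind != kind:
            raise ExpressionError(
                f"expected {kind} but found {value!r} in {self.text!r}"
            )
        return value

    def parse(self) -> Expr:
        expr = self.parse_or()
        kind, value = self.peek()
        if kind != "end":
            raise ExpressionError(f"trailing input {value!r} in {self.text!r}")
        return expr

    def parse_or(self) -> Expr:
        operands = [self.parse_and()]
        while self.peek()[0] == "or":
            self.advance()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and(self) -> Expr:
        operands = [self.parse_unary()]
        while self.peek()[0] == "and":
            self.advance()
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_unary(self) -> Expr:
        kind, value = self.peek()
        if kind == "not":
            self.advance()
            return Not(self.parse_unary())
        if kind == "lpar":
            self.advance()
            expr = self.parse_or()
            self.expect("rpar")
            return expr
        if kind == "const":
            self.advance()
            return Const(int(value))
        if kind == "name":
            self.advance()
            return Var(value)
        raise ExpressionError(f"unexpected token {value!r} in {self.text!r}")


def parse_expression(text: str) -> Expr:
    """Parse a Boolean expression string into an AST."""
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    return _Parser(text).parse()


def expression_variables(text: str) -> list[str]:
    return parse_expression(text).variables()


def compile_truth_table(expr: Expr, regulators: Sequence[str]) -> np.ndarray:
    """Evaluate *expr* on every assignment of *regulators*.

    Rows are ordered by reading the regulator tuple as a binary number with
    the first regulator as the most significant bit.  Returns a uint8 array
    of length ``2**k``.
    """
    k = len(regulators)
    rows = np.arange(1 << k, dtype=np.uint32)
    values = {
        reg: ((rows >> (k - 1 - j)) & 1).astype(np.uint8)
        for j, reg in enumerate(regulators)
    }
    missing = [v for v in expr.variables() if v not in values]
    if missing:
        raise ExpressionError(f"expression uses undeclared regulators: {missing}")
    result = expr.evaluate(values)
    if np.isscalar(result) or getattr(result, "ndim", 1) == 0:
        result = np.full(1 << k, int(result), dtype=np.uint8)
    return np.asarray(result, dtype=np.uint8)


def format_expression(expr: Expr, style: str = "bnet") -> str:
    """Render an AST back to text; ``bnet`` style uses ``!``/``&``/``|``."""
    if style != "bnet":
        raise ValueError(f"unknown style {style!r}")
    return _format(expr, parent_prec=0)


_PREC = {Or: 1, And: 2, Not: 3}


def _format(expr: Expr, parent_prec: int) -> str:
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        inner = _format(expr.operand, _PREC[Not])
        return f"!{inner}"
    if isinstance(expr, (And, Or)):
        prec = _PREC[type(expr)]
        joiner = " & " if isinstance(expr, And) else " | "
        body = joiner.join(_format(op, prec) for op in expr.operands)
        return f"({body})" if prec < parent_prec else body
    raise TypeError(f"not an expression node: {expr!r}")
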