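"""Boolean expressions over variable-state literals for logic-gate tables.

A logic gate (SG variable) maps combinations of risk-factor states to gate
states through an ordered specification table.  Each row carries a boolean
expression over literals of the form ``X74=1`` combined with ``and``, ``or``,
``not`` and parentheses.  Evaluation is against a mapping of variable id to
observed state; variables missing from the mapping default to state 0
(risk factor absent).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping


class ExpressionError(ValueError):
    """Raised for malformed gate expressions."""


@dataclass(frozen=True)
class Literal:
    var: str
    state: int

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return states.get(self.var, 0) == self.state

    def variables(self) -> frozenset[str]:
        return frozenset({self.var})

    def __str__(self) -> str:
        return f"{self.var}={self.state}"


@dataclass(frozen=True)
class Not:
    operand: "Expr"

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return not self.operand.evaluate(states)

    def variables(self) -> frozenset[str]:
        return self.operand.variables()

    def __str__(self) -> str:
        return f"not {_wrap(self.operand)}"


@dataclass(frozen=True)
class And:
    operands: tuple["Expr", ...]

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return all(op.evaluate(states) for op in self.operands)

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(op.variables() for op in self.operands))

    def __str__(self) -> str:
        return " and ".join(_wrap(op) for op in self.operands)


@dataclass(frozen=True)
class Or:
    operands: tuple["Expr", ...]

    def evaluate(self, states: Mapping[str, int]) -> bool:
        return any(op.evaluate(states) for op in self.operands)

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(op.variables() for op in self.operands))

    def __str__(self) -> str:
        return " or ".join(_wrap(op) for op in self.operands)


Expr = Literal | Not | And | Or


def _wrap(expr: Expr) -> str:
    if isinstance(expr, (And, Or)):
        return f"({expr})"
    return str(expr)


_TOKEN = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<lit>[A-Za-z]+\d+\s*=\s*\d+)"
    r"|(?P<word>[A-Za-z]+))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExpressionError(
                    f"unexpected character {text[pos:].strip()[0]!r} in {text!r}"
                )
            break
        pos = m.end()
        if m.lastgroup == "lit":
            tokens.append(("lit", m.group("lit")))
        elif m.lastgroup == "word":
            word = m.group("word").lower()
            if word not in {"and", "or", "not"}:
                raise ExpressionError(f"unknown keyword {word!r} in {text!r}")
            tokens.append((word, word))
        else:
            tokens.append((m.lastgroup, m.group(0).strip()))  # type: ignore[arg-type]
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], source: str):
        self.tokens = tokens
        self.source = source
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.pos != len(self.tokens):
            raise ExpressionError(f"trailing tokens in {self.source!r}")
        return expr

    def parse_or(self) -> Expr:
        operands = [self.parse_and()]
        while self.peek() == "or":
            self.take()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and(self) -> Expr:
        operands = [self.parse_not()]
        while self.peek() == "and":
            self.take()
            operands.append(self.parse_not())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_not(self) -> Expr:
        if self.peek() == "not":
            self.take()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        kind = self.peek()
        if kind == "lparen":
            self.take()
            expr = self.parse_or()
            if self.peek() != "rparen":
                raise ExpressionError(f"unbalanced parentheses in {self.source!r}")
            self.take()
            return expr
        if kind == "lit":
            _, text = self.take()
            var, state = text.split("=")
            return Literal(var.strip(), int(state))
        raise ExpressionError(f"expected literal or '(' in {self.source!r}")


def parse_expr(text: str) -> Expr:
    """Parse a gate-row expression such as ``"X74=1 and not X52=0"``."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return _Parser(tokens, text).parse()
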