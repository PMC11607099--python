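"""A minimal, deterministic boolean expression language.

Sequence-flow guards and decision-table cells need conditions over workflow
variables, but nothing close to full FEEL.  This module implements two small
grammars:

* **Guard expressions** for sequence flows, e.g.::

      x > 5
      shock_class in {"III", "IV"} and not rosc
      airway_patent == false or gcs <= 8

  Comparisons (``< <= > >= == !=``), boolean connectives (``and``, ``or``,
  ``not``), parentheses, and set membership (``in { ... }``).  Literals are
  numbers, ``true``/``false``, and single- or double-quoted strings.
  Evaluating a guard whose variable is absent from scope yields ``False``
  (the flow is simply not satisfied); this keeps XOR routing total.

* **Decision cells** for DMN-style tables: the wildcard ``-``, unary
  comparisons (``< 120``), closed/open intervals (``[30..40)``), and
  enumerations (``"a", "b"`` — bare words are read as strings).

Both parse to small dataclass ASTs so that parse → serialize → parse is the
identity, which the model round-trip tests rely on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any

from .errors import ExpressionError

_TOKEN_RE = re.compile(
    r"""
    \s*(?:
        (?P<number>-?\d+(?:\.\d+)?)
      | (?P<string>"[^"]*"|'[^']*')
      | (?P<op><=|>=|==|!=|<|>|=)
      | (?P<punct>[(){},])
      | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    )
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "in", "true", "false"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"cannot tokenize {rest!r} in {text!r}")
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "name" and value in _KEYWORDS:
            kind = value if value in ("true", "false") else "kw"
        tokens.append((kind, value))
    return tokens


# ---------------------------------------------------------------------------
# Guard expression AST


@dataclass(frozen=True)
class Literal:
    value: Any

    def evaluate(self, scope: dict) -> Any:
        return self.value

    def unparse(self) -> str:
        if isinstance(self.value, bool):
            return "true" if self.value else "false"
        if isinstance(self.value, str):
            return '"' + self.value + '"'
        return _fmt_number(self.value)


@dataclass(frozen=True)
class Var:
    name: str

    def evaluate(self, scope: dict) -> Any:
        if self.name not in scope:
            raise KeyError(self.name)
        return scope[self.name]

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True)
class Compare:
    op: str
    left: Any
    right: Any

    def evaluate(self, scope: dict) -> bool:
        a = self.left.evaluate(scope)
        b = self.right.evaluate(scope)
        if self.op in ("==", "="):
            return a == b
        if self.op == "!=":
            return a != b
        try:
            if self.op == "<":
                return a < b
            if self.op == "<=":
                return a <= b
            if self.op == ">":
                return a > b
            if self.op == ">=":
                return a >= b
        except TypeError as exc:
            raise ExpressionError(f"cannot order {a!r} {self.op} {b!r}") from exc
        raise ExpressionError(f"unknown operator {self.op}")

    def unparse(self) -> str:
        op = "==" if self.op == "=" else self.op
        return f"{self.left.unparse()} {op} {self.right.unparse()}"


@dataclass(frozen=True)
class Membership:
    item: Any
    members: tuple

    def evaluate(self, scope: dict) -> bool:
        v = self.item.evaluate(scope)
        return any(v == m.value for m in self.members)

    def unparse(self) -> str:
        inner = ", ".join(m.unparse() for m in self.members)
        return f"{self.item.unparse()} in {{{inner}}}"


@dataclass(frozen=True)
class Not:
    operand: Any

    def evaluate(self, scope: dict) -> bool:
        return not _truthy(self.operand.evaluate(scope))

    def unparse(self) -> str:
        return f"not {self.operand.unparse()}"


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    operands: tuple

    def evaluate(self, scope: dict) -> bool:
        if self.op == "and":
            return all(_truthy(o.evaluate(scope)) for o in self.operands)
        return any(_truthy(o.evaluate(scope)) for o in self.operands)

    def unparse(self) -> str:
        parts = []
        for o in self.operands:
            text = o.unparse()
            if isinstance(o, BoolOp) and o.op != self.op:
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


def _truthy(v: Any) -> bool:
    if isinstance(v, bool):
        return v
    raise ExpressionError(f"guard expression yielded non-boolean {v!r}")


def _fmt_number(x) -> str:
    if isinstance(x, float) and x == int(x):
        return str(int(x))
    return repr(x) if not isinstance(x, float) else f"{x:g}"


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, kind: str, value: str | None = None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise ExpressionError(
                f"expected {value or kind}, got {v!r} in {self.source!r}"
            )
        return v

    # expr := and_expr ("or" and_expr)*
    def parse_expr(self):
        operands = [self.parse_and()]
        while self.peek() == ("kw", "or"):
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else BoolOp("or", tuple(operands))

    def parse_and(self):
        operands = [self.parse_not()]
        while self.peek() == ("kw", "and"):
            self.next()
            operands.append(self.parse_not())
        return operands[0] if len(operands) == 1 else BoolOp("and", tuple(operands))

    def parse_not(self):
        if self.peek() == ("kw", "not"):
            self.next()
            return Not(self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self):
        left = self.parse_operand()
        kind, value = self.peek()
        if kind == "op":
            self.next()
            right = self.parse_operand()
            return Compare(value, left, right)
        if (kind, value) == ("kw", "in"):
            self.next()
            self.expect("punct", "{")
            members = [self.parse_literal()]
            while self.peek() == ("punct", ","):
                self.next()
                members.append(self.parse_literal())
            self.expect("punct", "}")
            return Membership(left, tuple(members))
        return left

    def parse_operand(self):
        kind, value = self.peek()
        if (kind, value) == ("punct", "("):
            self.next()
            inner = self.parse_expr()
            self.expect("punct", ")")
            return inner
        return self.parse_atom()

    def parse_atom(self):
        kind, value = self.next()
        if kind == "number":
            return Literal(float(value) if "." in value else int(value))
        if kind == "string":
            return Literal(value[1:-1])
        if kind == "true":
            return Literal(True)
        if kind == "false":
            return Literal(False)
        if kind == "name":
            return Var(value)
        raise ExpressionError(f"unexpected token {value!r} in {self.source!r}")

    def parse_literal(self):
        node = self.parse_atom()
        if not isinstance(node, Literal):
            raise ExpressionError(f"expected literal in {self.source!r}")
        return node


def parse_guard(text: str):
    """Parse a sequence-flow guard expression into an AST."""
    parser = _Parser(_tokenize(text), text)
    node = parser.parse_expr()
    if parser.pos != len(parser.tokens):
        raise ExpressionError(f"trailing tokens in {text!r}")
    return node


def evaluate_guard(node, scope: dict) -> bool:
    """Evaluate a parsed guard; an absent variable makes the guard False."""
    try:
        return _truthy(node.evaluate(scope))
    except KeyError:
        return False


# ---------------------------------------------------------------------------
# Decision-table cells


@dataclass(frozen=True)
class Cell:
    """One parsed condition cell of a decision-table rule.

    kind is one of ``wildcard``, ``compare``, ``interval``, ``enum``.
    """

    kind: str
    op: str | None = None          # compare
    value: Any = None              # compare
    low: float | None = None       # interval
    high: float | None = None
    low_closed: bool = True
    high_closed: bool = True
    members: tuple = ()            # enum

    def matches(self, value: Any) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "compare":
            if self.op in ("=", "=="):
                return value == self.value
            if self.op == "!=":
                return value != self.value
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ExpressionError(f"ordered comparison on {value!r}")
            if self.op == "<":
                return value < self.value
            if self.op == "<=":
                return value <= self.value
            if self.op == ">":
                return value > self.value
            if self.op == ">=":
                return value >= self.value
        if self.kind == "interval":
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ExpressionError(f"interval test on {value!r}")
            lo_ok = value >= self.low if self.low_closed else value > self.low
            hi_ok = value <= self.high if self.high_closed else value < self.high
            return lo_ok and hi_ok
        if self.kind == "enum":
            return value in self.members
        raise ExpressionError(f"bad cell kind {self.kind}")

    def unparse(self) -> str:
        if self.kind == "wildcard":
            return "-"
        if self.kind == "compare":
            return f"{self.op} {_literal_text(self.value)}"
        if self.kind == "interval":
            lo = "[" if self.low_closed else "("
            hi = "]" if self.high_closed else ")"
            return f"{lo}{_fmt_number(self.low)}..{_fmt_number(self.high)}{hi}"
        return ", ".join(_literal_text(m) for m in self.members)


def _literal_text(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return '"' + v + '"'
    return _fmt_number(v)


_INTERVAL_RE = re.compile(
    r"^\s*(?P<lo_br>[\[(])\s*(?P<lo>-?\d+(?:\.\d+)?)\s*\.\.\s*"
    r"(?P<hi>-?\d+(?:\.\d+)?)\s*(?P<hi_br>[\])])\s*$"
)
_COMPARE_RE = re.compile(r"^\s*(?P<op><=|>=|!=|==|<|>|=)\s*(?P<rest>.+)$")


def _parse_cell_literal(text: str):
    text = text.strip()
    if re.fullmatch(r"-?\d+(\.\d+)?", text):
        return float(text) if "." in text else int(text)
    if text in ("true", "false"):
        return text == "true"
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "\"'":
        return text[1:-1]
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", text):
        return text  # bare word as string
    raise ExpressionError(f"uninterpretable literal {text!r}")


def parse_cell(text: str) -> Cell:
    """Parse one decision-table condition cell."""
    text = text.strip()
    if text in ("-", ""):
        return Cell("wildcard")
    m = _INTERVAL_RE.match(text)
    if m:
        lo = float(m.group("lo")) if "." in m.group("lo") else int(m.group("lo"))
        hi = float(m.group("hi")) if "." in m.group("hi") else int(m.group("hi"))
        return Cell(
            "interval",
            low=lo,
            high=hi,
            low_closed=m.group("lo_br") == "[",
            high_closed=m.group("hi_br") == "]",
        )
    m = _COMPARE_RE.match(text)
    if m:
        return Cell("compare", op=m.group("op"), value=_parse_cell_literal(m.group("rest")))
    if "," in text:
        members = tuple(_parse_cell_literal(p) for p in text.split(","))
        return Cell("enum", members=members)
    return Cell("compare", op="=", value=_parse_cell_literal(text))


def parse_output_literal(text: str):
    """Parse a decision-table output entry (always a single literal)."""
    return _parse_cell_literal(text)
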