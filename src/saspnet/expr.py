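"""Boolean rule expressions: parsing, evaluation, substitution.

Rules follow the notation used for logical gene-regulation models:
``&`` (and), ``|`` (or) and ``¬`` (not), with ``!``/``NOT``/``AND``/``OR``
accepted as aliases so that files in the BoolNet "targets, factors" dialect
parse unchanged.  Precedence is NOT > AND > OR; parentheses group.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Union

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "ParseError",
    "EvaluationError",
    "parse_rule",
    "evaluate",
    "truth_table",
    "equivalent",
]


class ParseError(ValueError):
    """Raised for malformed rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EvaluationError(KeyError):
    """Raised when a rule references a variable absent from the state."""


class Expr:
    """Base class for Boolean expression trees."""

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def eval_columns(self, columns: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorised evaluation over parallel boolean arrays."""
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def substitute(self, bindings: Mapping[str, Union[int, "Expr"]]) -> "Expr":
        """Replace variables by constants/expressions, simplifying constants."""
        raise NotImplementedError

    def to_infix(self, negation: str = "!") -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_infix()!r})"

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


class Const(Expr):
    def __init__(self, value: int):
        if value not in (0, 1):
            raise ValueError("constant must be 0 or 1")
        self.value = int(value)

    def evaluate(self, state):
        return self.value

    def eval_columns(self, columns):
        n = len(next(iter(columns.values()))) if columns else 1
        return np.full(n, bool(self.value))

    def variables(self):
        return frozenset()

    def substitute(self, bindings):
        return self

    def to_infix(self, negation="!"):
        return str(self.value)

    def _key(self):
        return self.value


class Var(Expr):
    def __init__(self, name: str):
        self.name = name

    def evaluate(self, state):
        try:
            return int(state[self.name])
        except KeyError:
            raise EvaluationError(f"variable {self.name!r} is not assigned") from None

    def eval_columns(self, columns):
        try:
            return columns[self.name]
        except KeyError:
            raise EvaluationError(f"variable {self.name!r} is not assigned") from None

    def variables(self):
        return frozenset((self.name,))

    def substitute(self, bindings):
        if self.name not in bindings:
            return self
        value = bindings[self.name]
        if isinstance(value, Expr):
            return value
        return Const(int(value))

    def to_infix(self, negation="!"):
        return self.name

    def _key(self):
        return self.name


class Not(Expr):
    def __init__(self, child: Expr):
        self.child = child

    def evaluate(self, state):
        return 1 - self.child.evaluate(state)

    def eval_columns(self, columns):
        return ~self.child.eval_columns(columns)

    def variables(self):
        return self.child.variables()

    def substitute(self, bindings):
        child = self.child.substitute(bindings)
        if isinstance(child, Const):
            return Const(1 - child.value)
        return Not(child)

    def to_infix(self, negation="!"):
        child = self.child
        inner = child.to_infix(negation)
        if isinstance(child, (And, Or)):
            inner = f"({inner})"
        return f"{negation}{inner}"

    def _key(self):
        return self.child


class _NaryOp(Expr):
    _symbol = "?"
    _identity = 0  # value that drops out
    _dominant = 1  # value that collapses the whole expression

    def __init__(self, children: Iterable[Expr]):
        self.children = tuple(children)
        if len(self.children) < 2:
            raise ValueError(f"{type(self).__name__} needs at least two operands")

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def substitute(self, bindings):
        new_children = []
        for child in self.children:
            sub = child.substitute(bindings)
            if isinstance(sub, Const):
                if sub.value == self._dominant:
                    return Const(self._dominant)
                continue  # identity element: drop
            if type(sub) is type(self):
                new_children.extend(sub.children)
            else:
                new_children.append(sub)
        if not new_children:
            return Const(self._identity)
        if len(new_children) == 1:
            return new_children[0]
        return type(self)(new_children)

    def to_infix(self, negation="!"):
        parts = []
        for child in self.children:
            text = child.to_infix(negation)
            if self._needs_parens(child):
                text = f"({text})"
            parts.append(text)
        return f" {self._symbol} ".join(parts)

    def _needs_parens(self, child: Expr) -> bool:
        raise NotImplementedError

    def _key(self):
        return self.children


class And(_NaryOp):
    _symbol = "&"
    _identity = 1
    _dominant = 0

    def evaluate(self, state):
        for child in self.children:
            if child.evaluate(state) == 0:
                return 0
        return 1

    def eval_columns(self, columns):
        result = self.children[0].eval_columns(columns)
        for child in self.children[1:]:
            result = result & child.eval_columns(columns)
        return result

    def _needs_parens(self, child):
        return isinstance(child, Or)


class Or(_NaryOp):
    _symbol = "|"
    _identity = 0
    _dominant = 1

    def evaluate(self, state):
        for child in self.children:
            if child.evaluate(state) == 1:
                return 1
        return 0

    def eval_columns(self, columns):
        result = self.children[0].eval_columns(columns)
        for child in self.children[1:]:
            result = result | child.eval_columns(columns)
        return result

    def _needs_parens(self, child):
        return False


# ---------------------------------------------------------------------------
# Parsing (recursive descent; precedence NOT > AND > OR)
# ---------------------------------------------------------------------------

_WORD_OPERATORS = {"not": "!", "and": "&", "or": "|"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()&|":
            tokens.append((ch, ch, i))
            i += 1
        elif ch in "!¬":
            tokens.append(("!", ch, i))
            i += 1
        elif ch.isalnum() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            word = text[i:j]
            kind = _WORD_OPERATORS.get(word.lower(), "NAME")
            tokens.append((kind, word, i))
            i = j
        else:
            raise ParseError(f"unexpected character {ch!r}", i)
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        token = self._peek()
        if token is not None:
            self.pos += 1
        return token

    def _error_position(self):
        token = self._peek()
        return token[2] if token is not None else len(self.text)

    def parse(self) -> Expr:
        if not self.tokens:
            raise ParseError("empty expression", 0)
        expr = self._or()
        if self._peek() is not None:
            kind, word, pos = self._peek()
            raise ParseError(f"unexpected token {word!r}", pos)
        return expr

    def _or(self) -> Expr:
        children = [self._and()]
        while self._peek() is not None and self._peek()[0] == "|":
            self._next()
            children.append(self._and())
        return children[0] if len(children) == 1 else Or(children)

    def _and(self) -> Expr:
        children = [self._factor()]
        while self._peek() is not None and self._peek()[0] == "&":
            self._next()
            children.append(self._factor())
        return children[0] if len(children) == 1 else And(children)

    def _factor(self) -> Expr:
        token = self._peek()
        if token is None:
            raise ParseError("dangling operator: expected an operand", len(self.text))
        kind, word, pos = token
        if kind == "!":
            self._next()
            return Not(self._factor())
        if kind == "(":
            self._next()
            inner = self._or()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                raise ParseError("unbalanced parentheses: expected ')'", self._error_position())
            self._next()
            return inner
        if kind == "NAME":
            self._next()
            if word in ("0", "1"):
                return Const(int(word))
            return Var(word)
        raise ParseError(f"unexpected token {word!r}", pos)


def parse_rule(text: str) -> Expr:
    """Parse a rule string into an expression tree.

    Accepts ``&``/``AND``, ``|``/``OR``, ``¬``/``!``/``NOT``, parentheses and
    the constants ``0``/``1``.  Raises :class:`ParseError` with the offending
    position for malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty expression", 0)
    return _Parser(text).parse()


def evaluate(expr: Expr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` on a total state; pure, returns 0 or 1."""
    return expr.evaluate(state)


def truth_table(expr: Expr, variables: Iterable[str] | None = None) -> tuple[int, ...]:
    """Output column of ``expr`` over all assignments of ``variables``.

    Variable order is sorted if not given; rows are enumerated with the first
    variable as the most significant bit.
    """
    names = sorted(expr.variables()) if variables is None else list(variables)
    rows = []
    for bits in itertools.product((0, 1), repeat=len(names)):
        rows.append(expr.evaluate(dict(zip(names, bits))))
    return tuple(rows)


def equivalent(a: Expr, b: Expr) -> bool:
    """Truth-table equality of two expressions over their joint variables."""
    names = sorted(a.variables() | b.variables())
    return truth_table(a, names) == truth_table(b, names)
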