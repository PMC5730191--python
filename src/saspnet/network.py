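"""Boolean networks, states, and synchronous/asynchronous update semantics."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .expr import Expr, Var, parse_rule

__all__ = [
    "NetworkError",
    "State",
    "BooleanNetwork",
    "Trajectory",
    "synchronous_step",
    "asynchronous_step",
    "simulate",
    "first_activation_time",
]


class NetworkError(ValueError):
    """Raised for ill-formed networks or unknown node references."""


class State(Mapping[str, int]):
    """Immutable assignment of one bit per node, addressable by node name.

    Equality and hashing consider both the node layout and the bits, so two
    states over the same network compare equal iff all bits agree.
    """

    __slots__ = ("_nodes", "_index", "_bits")

    def __init__(self, nodes: Sequence[str], bits: Sequence[int], *, _index=None):
        self._nodes = tuple(nodes)
        self._bits = tuple(int(b) for b in bits)
        if len(self._nodes) != len(self._bits):
            raise NetworkError("state length does not match node count")
        if any(b not in (0, 1) for b in self._bits):
            raise NetworkError("state bits must be 0 or 1")
        self._index = _index if _index is not None else {n: i for i, n in enumerate(self._nodes)}

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def bits(self) -> tuple[int, ...]:
        return self._bits

    def __getitem__(self, name: str) -> int:
        try:
            return self._bits[self._index[name]]
        except KeyError:
            raise NetworkError(f"unknown node {name!r}") from None

    def __iter__(self):
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other) -> bool:
        if isinstance(other, State):
            return self._nodes == other._nodes and self._bits == other._bits
        return NotImplemented

    def __hash__(self) -> int:
        return hash((self._nodes, self._bits))

    def __repr__(self) -> str:
        active = [n for n, b in zip(self._nodes, self._bits) if b]
        return f"State(active={active!r})"

    def replace(self, **changes: int) -> "State":
        bits = list(self._bits)
        for name, value in changes.items():
            if name not in self._index:
                raise NetworkError(f"unknown node {name!r}")
            bits[self._index[name]] = int(value)
        return State(self._nodes, bits, _index=self._index)

    def to_int(self) -> int:
        """Pack bits into an integer, node 0 as the least significant bit."""
        packed = 0
        for i, b in enumerate(self._bits):
            packed |= b << i
        return packed


class BooleanNetwork:
    """A named-node Boolean network with one update rule per node.

    The node order is stable and defines the state-vector layout.  Input
    nodes are exactly those whose rule is the identity on themselves
    (``X, X`` in the BoolNet dialect), representing external signals.
    """

    def __init__(self, rules: Mapping[str, Expr] | Iterable[tuple[str, Expr | str]]):
        items = list(rules.items()) if isinstance(rules, Mapping) else list(rules)
        nodes: list[str] = []
        parsed: dict[str, Expr] = {}
        for name, rule in items:
            if name in parsed:
                raise NetworkError(f"duplicate node {name!r}")
            nodes.append(name)
            parsed[name] = parse_rule(rule) if isinstance(rule, str) else rule
        if not nodes:
            raise NetworkError("a network needs at least one node")
        self._nodes = tuple(nodes)
        self._rules = parsed
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._validate()

    def _validate(self) -> None:
        defined = set(self._nodes)
        for name, expr in self._rules.items():
            unknown = expr.variables() - defined
            if unknown:
                raise NetworkError(
                    f"rule for {name!r} references undefined node(s): {sorted(unknown)}"
                )

    # -- basic introspection -------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def rule(self, name: str) -> Expr:
        try:
            return self._rules[name]
        except KeyError:
            raise NetworkError(f"unknown node {name!r}") from None

    @property
    def rules(self) -> dict[str, Expr]:
        return dict(self._rules)

    @property
    def inputs(self) -> tuple[str, ...]:
        """Nodes whose rule is the identity on themselves, in node order."""
        return tuple(n for n in self._nodes if self._rules[n] == Var(n))

    # -- state construction --------------------------------------------------
    def state(self, assignment: Mapping[str, int] | None = None, default: int = 0) -> State:
        bits = [default] * len(self._nodes)
        if assignment:
            for name, value in assignment.items():
                if name not in self._index:
                    raise NetworkError(f"unknown node {name!r}")
                bits[self._index[name]] = int(value)
        return State(self._nodes, bits, _index=self._index)

    def state_from_int(self, packed: int) -> State:
        bits = [(packed >> i) & 1 for i in range(len(self._nodes))]
        return State(self._nodes, bits, _index=self._index)

    # -- compiled synchronous successor (integer-packed states) -------------
    def compiled_step(self):
        """Return ``f(int) -> int`` computing one synchronous update.

        States are packed with node ``i`` at bit ``i``; used by the attractor
        machinery where per-state dictionary evaluation would dominate.
        """
        index = self._index
        parts = []
        for i, name in enumerate(self._nodes):
            parts.append(f"(({self._expr_to_py(self._rules[name], index)}) << {i})")
        source = "lambda s: " + " | ".join(parts)
        return eval(source, {"__builtins__": {}})  # noqa: S307 - generated from our own AST

    @staticmethod
    def _expr_to_py(expr: Expr, index: Mapping[str, int]) -> str:
        from . import expr as E

        if isinstance(expr, E.Const):
            return str(expr.value)
        if isinstance(expr, E.Var):
            return f"((s >> {index[expr.name]}) & 1)"
        if isinstance(expr, E.Not):
            return f"(1 - {BooleanNetwork._expr_to_py(expr.child, index)})"
        if isinstance(expr, E.And):
            return "(" + " & ".join(BooleanNetwork._expr_to_py(c, index) for c in expr.children) + ")"
        if isinstance(expr, E.Or):
            return "(" + " | ".join(BooleanNetwork._expr_to_py(c, index) for c in expr.children) + ")"
        raise TypeError(f"unsupported expression node {type(expr).__name__}")

    def __repr__(self) -> str:
        return f"BooleanNetwork({len(self)} nodes, inputs={list(self.inputs)!r})"


class Trajectory:
    """A 1-indexed sequence of states; ``t = 1`` is the un-updated initial state.

    When simulation stops because a previously seen state recurs, the
    recurring state is kept as the final entry and ``recurrence_time`` /
    ``first_occurrence`` record where the loop closes.
    """

    def __init__(self, states: Sequence[State], first_occurrence: int | None = None):
        self.states = list(states)
        self.first_occurrence = first_occurrence

    @property
    def recurrence_time(self) -> int | None:
        return len(self.states) if self.first_occurrence is not None else None

    def state_at(self, t: int) -> State:
        if not 1 <= t <= len(self.states):
            raise IndexError(f"time index {t} outside trajectory (1..{len(self.states)})")
        return self.states[t - 1]

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def final(self) -> State:
        return self.states[-1]


def synchronous_step(net: BooleanNetwork, s: State) -> State:
    """Apply every rule simultaneously to ``s``; deterministic and pure."""
    bits = [net.rule(name).evaluate(s) for name in net.nodes]
    return State(net.nodes, bits)


def asynchronous_step(net: BooleanNetwork, s: State, node: str) -> State:
    """Update only ``node``; all other bits are copied unchanged."""
    if node not in net:
        raise NetworkError(f"unknown node {node!r}")
    new_bit = net.rule(node).evaluate(s)
    if new_bit == s[node]:
        return s
    return s.replace(**{node: new_bit})


def simulate(net: BooleanNetwork, initial: State, max_steps: int = 1000) -> Trajectory:
    """Synchronous trajectory from ``initial`` (kept as ``t = 1``).

    Applies at most ``max_steps`` updates, stopping early as soon as a
    previously seen state recurs (every trajectory does within 2**N steps).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    states = [initial]
    seen = {initial: 1}
    current = initial
    for _ in range(max_steps):
        current = synchronous_step(net, current)
        states.append(current)
        if current in seen:
            return Trajectory(states, first_occurrence=seen[current])
        seen[current] = len(states)
    return Trajectory(states, first_occurrence=None)


def first_activation_time(traj: Trajectory, node: str) -> int | None:
    """Smallest ``t`` with the node active, or ``None`` if it never fires."""
    for t, state in enumerate(traj.states, start=1):
        if state[node] == 1:
            return t
    return None
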