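"""Random Boolean networks (N-K style) and a brute-force attractor oracle.

The generator emulates arbitrary Boolean networks — random wiring with a
fixed in-degree K and a tunable truth-table bias p — so the engine, the
attractor strategies and the screen can be validated against an independent
exhaustive oracle on small state spaces.  Rules are realised in
sum-of-products form, so generated networks round-trip through the same
parser and file format as the biological model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attractors import Attractor
from .expr import And, Expr, Not, Or, Var
from .network import BooleanNetwork, State

__all__ = [
    "RandomNetworkSpec",
    "generate_random_network",
    "brute_force_attractors",
    "write_fixture_set",
]


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of one random network; same spec + seed → identical network.

    ``n``: node count; ``k``: exact in-degree of every non-input node;
    ``p``: probability that a truth-table row outputs 1; ``n_inputs``:
    number of self-looped input nodes; ``seed``: RNG seed.
    """

    n: int
    k: int
    p: float = 0.5
    n_inputs: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("truth-table bias p must lie in [0, 1]")
        if not 0 <= self.n_inputs <= self.n:
            raise ValueError("n_inputs must lie in [0, n]")


def _sum_of_products(regulators: tuple[str, ...], outputs: np.ndarray) -> Expr:
    """Realise a truth table as a rule referencing exactly its regulators.

    Rows are indexed with the first regulator as the most significant bit.
    An all-zero table becomes a contradiction that still mentions every
    regulator; an all-one table becomes the corresponding tautology.
    """
    k = len(regulators)
    minterms = []
    for row, out in enumerate(outputs):
        if not out:
            continue
        literals = []
        for i, reg in enumerate(regulators):
            bit = (row >> (k - 1 - i)) & 1
            literals.append(Var(reg) if bit else Not(Var(reg)))
        minterms.append(literals[0] if k == 1 else And(literals))
    if not minterms:
        contradiction = [Var(regulators[0]), Not(Var(regulators[0]))]
        contradiction += [Var(r) for r in regulators[1:]]
        return And(contradiction)
    return minterms[0] if len(minterms) == 1 else Or(minterms)


def generate_random_network(spec: RandomNetworkSpec) -> BooleanNetwork:
    """Draw a network from the spec: K regulators per node, biased tables."""
    rng = np.random.default_rng(spec.seed)
    names = [f"G{i + 1}" for i in range(spec.n)]
    input_nodes = set(rng.choice(spec.n, size=spec.n_inputs, replace=False).tolist())
    rules: list[tuple[str, Expr]] = []
    for i, name in enumerate(names):
        if i in input_nodes:
            rules.append((name, Var(name)))
            continue
        regs = tuple(names[j] for j in sorted(rng.choice(spec.n, size=spec.k, replace=False)))
        outputs = rng.random(1 << spec.k) < spec.p
        rules.append((name, _sum_of_products(regs, outputs)))
    return BooleanNetwork(rules)


def brute_force_attractors(net: BooleanNetwork) -> list[Attractor]:
    """Reference enumeration by direct trajectory-following over all 2**N states.

    Deliberately simple and interpreter-evaluated: the oracle against which
    the vectorised and reduction-based strategies are checked.  Refuses
    N > 20.
    """
    n = len(net)
    if n > 20:
        raise ValueError(f"brute force refuses N={n} > 20 nodes")
    nodes = net.nodes
    rules = [net.rule(name) for name in nodes]
    size = 1 << n

    def successor(packed: int) -> int:
        state = {name: (packed >> i) & 1 for i, name in enumerate(nodes)}
        out = 0
        for i, rule in enumerate(rules):
            out |= rule.evaluate(state) << i
        return out

    succ = [successor(s) for s in range(size)]
    labels = [-1] * size
    cycles: list[list[int]] = []
    for start in range(size):
        if labels[start] != -1:
            continue
        path: list[int] = []
        position: dict[int, int] = {}
        cur = start
        while labels[cur] == -1 and cur not in position:
            position[cur] = len(path)
            path.append(cur)
            cur = succ[cur]
        if labels[cur] == -1:  # closed a new cycle inside this walk
            cycle = path[position[cur]:]
            label = len(cycles)
            cycles.append(cycle)
        else:
            label = labels[cur]
        for s in path:
            labels[s] = label

    basin = [0] * len(cycles)
    for label in labels:
        basin[label] += 1
    out = []
    for i, cycle in enumerate(cycles):
        states = tuple(
            State(nodes, [(x >> j) & 1 for j in range(n)]) for x in cycle
        )
        out.append(Attractor(states, basin_size=basin[i]))
    return sorted(out, key=lambda a: a.states[0].bits)


def write_fixture_set(
    outdir, n: int, k: int, count: int, seed: int, p: float = 0.5, n_inputs: int = 0
) -> list[Path]:
    """Write ``count`` BoolNet-format fixture files derived from one seed."""
    from .io import write_boolnet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(count):
        spec = RandomNetworkSpec(n=n, k=k, p=p, n_inputs=n_inputs, seed=seed + i)
        net = generate_random_network(spec)
        path = outdir / f"net_{i:04d}.bn"
        write_boolnet(net, path)
        paths.append(path)
    return paths
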