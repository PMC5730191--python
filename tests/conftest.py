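"""Shared fixtures: the SASP model and a seeded random-network corpus.

The corpus (200 networks, N = 5..12, K ≤ 3, mixed truth-table bias, 0-2
input nodes) is enumerated once per session with the brute-force oracle and
reused by the engine, attractor and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import saspnet as sn
from saspnet.expr import And, Const, Expr, Not, Or, Var

CORPUS_SIZE = 200


def corpus_spec(i: int) -> sn.RandomNetworkSpec:
    return sn.RandomNetworkSpec(
        n=5 + i % 8,
        k=1 + i % 3,
        p=(0.2, 0.5, 0.8)[i % 3],
        n_inputs=i % 3,
        seed=20_000 + i,
    )


@pytest.fixture(scope="session")
def sasp_model() -> sn.SaspModel:
    return sn.build_sasp_model()


@pytest.fixture(scope="session")
def random_corpus() -> list[sn.BooleanNetwork]:
    return [sn.generate_random_network(corpus_spec(i)) for i in range(CORPUS_SIZE)]


@pytest.fixture(scope="session")
def corpus_brute_attractors(random_corpus) -> list[list[sn.Attractor]]:
    return [sn.brute_force_attractors(net) for net in random_corpus]


def random_expression(rng: np.random.Generator, variables: list[str], depth: int = 3) -> Expr:
    """Small random expression tree over the given variables (test helper)."""
    if depth == 0 or rng.random() < 0.3:
        roll = rng.random()
        if roll < 0.1:
            return Const(int(rng.integers(0, 2)))
        return Var(variables[int(rng.integers(0, len(variables)))])
    kind = rng.integers(0, 3)
    if kind == 0:
        return Not(random_expression(rng, variables, depth - 1))
    arity = int(rng.integers(2, 4))
    children = [random_expression(rng, variables, depth - 1) for _ in range(arity)]
    return And(children) if kind == 1 else Or(children)
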