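"""In-silico knockouts/overexpressions and the IL-6/IL-8 silencing screen.

A perturbation clamps one node's rule to a constant: 0 models a knockout,
1 an overexpression.  The screen asks which single perturbations keep the
readout cytokines (IL-6, IL-8 by default) permanently off in the attractor
reached from a condition — the model's testable predictions for suppressing
the SASP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .attractors import Attractor, attractor_from_state, diff_attractors
from .expr import Const
from .model import SaspModel, condition_state
from .network import BooleanNetwork, NetworkError, Trajectory, simulate

__all__ = [
    "Perturbation",
    "ScreenEntry",
    "ScreenResult",
    "apply_perturbation",
    "run_perturbed_condition",
    "screen_single_perturbations",
    "predicted_unchanged_nodes",
]


@dataclass(frozen=True)
class Perturbation:
    """Clamp ``node`` to ``bit`` (0 = knockout, 1 = overexpression)."""

    node: str
    bit: int

    def __post_init__(self):
        if self.bit not in (0, 1):
            raise ValueError("perturbation bit must be 0 or 1")

    def __str__(self) -> str:
        return f"{self.node}={self.bit}"


def apply_perturbation(
    net: BooleanNetwork, p: Perturbation | Iterable[Perturbation]
) -> BooleanNetwork:
    """New network with the perturbed node's rule replaced by the constant.

    All other rules are unchanged and the original network is unmodified.
    Accepts a single perturbation or an iterable (for double perturbations
    and beyond, by composition).
    """
    perturbations = [p] if isinstance(p, Perturbation) else list(p)
    clamp = {}
    for pert in perturbations:
        if pert.node not in net:
            raise NetworkError(f"unknown node {pert.node!r}")
        clamp[pert.node] = Const(pert.bit)
    return BooleanNetwork(
        [(n, clamp.get(n, net.rule(n))) for n in net.nodes]
    )


def run_perturbed_condition(
    model: SaspModel, p: Perturbation, condition: str, max_steps: int = 200
) -> tuple[Trajectory, Attractor]:
    """Synchronous trajectory + reached attractor of the perturbed network.

    The initial state is the condition preset with the perturbed node forced
    to its clamped bit already at t = 1, matching how a constitutive
    knockout/overexpression is present from the start of the time course.
    """
    net = apply_perturbation(model.network, p)
    initial = condition_state(model, condition).replace(**{p.node: p.bit})
    traj = simulate(net, initial, max_steps=max_steps)
    return traj, attractor_from_state(net, initial)


@dataclass(frozen=True)
class ScreenEntry:
    perturbation: Perturbation
    attractor: Attractor
    readout_bits: dict[str, int]
    silencing: bool


@dataclass(frozen=True)
class ScreenResult:
    condition: str
    readouts: tuple[str, ...]
    entries: tuple[ScreenEntry, ...]

    @property
    def silencing_set(self) -> tuple[Perturbation, ...]:
        return tuple(e.perturbation for e in self.entries if e.silencing)


def _readout_summary(att: Attractor, readouts: Sequence[str]) -> tuple[dict[str, int], bool]:
    # A readout is "silenced" only if it is 0 in *every* phase of the cycle:
    # preventing activation is an always-off claim.
    bits = {r: max(state[r] for state in att.states) for r in readouts}
    return bits, all(b == 0 for b in bits.values())


def screen_single_perturbations(
    model: SaspModel,
    condition: str,
    readouts: Sequence[str] | None = None,
    log=None,
) -> ScreenResult:
    """Scan every single knockout/overexpression for readout silencing.

    Candidates are all 2·N single perturbations except the readouts
    themselves and the declared input nodes (whose values belong to the
    condition, not to an intervention), so
    ``|candidates| = 2 · (N − |readouts| − |inputs|)``.
    """
    readouts = tuple(readouts if readouts is not None else model.readouts)
    if not readouts:
        raise ValueError("readouts must be non-empty")
    net = model.network
    excluded = set(readouts) | set(net.inputs)
    entries = []
    for node in net.nodes:
        if node in excluded:
            continue
        for bit in (0, 1):
            p = Perturbation(node, bit)
            _, att = run_perturbed_condition(model, p, condition)
            bits, silenced = _readout_summary(att, readouts)
            entries.append(ScreenEntry(p, att, bits, silenced))
            if log is not None:
                log(f"screen: {p} -> {bits} silencing={silenced}")
    return ScreenResult(condition, readouts, tuple(entries))


def predicted_unchanged_nodes(
    model: SaspModel, p: Perturbation, condition: str
) -> tuple[str, ...]:
    """Nodes whose attractor bit is identical with and without ``p``.

    Both the wildtype and perturbed runs from the condition must reach point
    attractors; the perturbed node itself is excluded from the report.
    """
    wt = attractor_from_state(model.network, condition_state(model, condition))
    _, perturbed = run_perturbed_condition(model, p, condition)
    if not (wt.is_point and perturbed.is_point):
        raise ValueError("both attractors must be point attractors")
    diff = diff_attractors(wt, perturbed)
    return tuple(n for n in diff.unchanged if n != p.node)
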