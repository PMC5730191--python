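"""The combined DNA-damage + proinflammatory (SASP) network model.

The model couples the DNA-damage response (ATM/ATR → CHK1/CHK2 → p53/p21,
p16INK4 → CDK4/CDK2 cell-cycle arrest) with NF-κB-driven proinflammatory
signaling (IL-1, IL-6, IL-8 and their receptor cascades).  Two self-looped
external inputs drive it: DNAD (severe DNA damage) and Hypoxia.  The
readouts of interest are the key SASP mediators IL-6 and IL-8.

The rules live in a single BoolNet-format file shipped with the package
(``data/sasp_model.bn``); :func:`build_sasp_model` parses that file rather
than duplicating the rules in code.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

from .io import parse_boolnet_text
from .network import BooleanNetwork, NetworkError, State

__all__ = [
    "SaspModel",
    "build_sasp_model",
    "condition_state",
    "CONDITIONS",
    "READOUTS",
    "NODE_ALIASES",
    "DISPLAY_NAMES",
]

#: Condition presets: all nodes start inactive, then the input bits are set.
CONDITIONS: dict[str, dict[str, int]] = {
    "baseline": {},
    "dna_damage": {"DNAD": 1},
    "hypoxia": {"Hypoxia": 1},
    "dna_damage+hypoxia": {"DNAD": 1, "Hypoxia": 1},
}

#: Key SASP mediators used as screen readouts.
READOUTS: tuple[str, ...] = ("IL6", "IL8")

#: Accepted alternative spellings, canonicalized on load.  MPK1 and MKP1
#: denote the same AP1-induced MAPK phosphatase; the canonical name is MKP1.
NODE_ALIASES: dict[str, str] = {"MPK1": "MKP1"}

#: ASCII-safe canonical node names → display forms used in prose.
DISPLAY_NAMES: dict[str, str] = {
    "p16INK4": "p16^INK4A",
    "IkB": "IκB",
    "NFkB": "NF-κB",
    "CEBPbeta": "C/EBPβ",
    "MEK1_2": "MEK1/2",
    "ERK1_2": "ERK1/2",
}


class SaspModel:
    """The SASP network plus its named conditions and readout set."""

    def __init__(self, network: BooleanNetwork, readouts: tuple[str, ...] = READOUTS):
        self.network = network
        self.readouts = tuple(r for r in readouts if r in network)
        self.conditions = dict(CONDITIONS)

    def condition_state(self, condition: str) -> State:
        return condition_state(self, condition)

    def __repr__(self) -> str:
        return f"SaspModel({len(self.network)} nodes, readouts={list(self.readouts)!r})"


def build_sasp_model() -> SaspModel:
    """Load the shipped 51-node model; deterministic, node order as published."""
    text = resources.files("saspnet.data").joinpath("sasp_model.bn").read_text(encoding="utf-8")
    network = parse_boolnet_text(text, aliases=NODE_ALIASES, source="sasp_model.bn")
    return SaspModel(network)


def condition_state(model: SaspModel | BooleanNetwork, condition: str) -> State:
    """All-zero state with the condition's input bits set.

    ``condition`` is one of ``baseline``, ``dna_damage``, ``hypoxia``,
    ``dna_damage+hypoxia``.
    """
    network = model.network if isinstance(model, SaspModel) else model
    if condition not in CONDITIONS:
        raise NetworkError(
            f"unknown condition {condition!r}; choose from {sorted(CONDITIONS)}"
        )
    assignment: Mapping[str, int] = CONDITIONS[condition]
    return network.state(assignment)
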