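"""Reading/writing BoolNet-format files, CSV reports, and the run pipeline.

The on-disk dialect is the BoolNet "targets, factors" text format: a header
line, one ``node, expression`` line per node, ``#`` comments.  ``!`` is
written for negation; ``¬`` is accepted on read.
"""

from __future__ import annotations

import csv
import dataclasses
import sys
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .expr import ParseError
from .network import BooleanNetwork, NetworkError, Trajectory

__all__ = [
    "BoolNetFormatError",
    "read_boolnet",
    "write_boolnet",
    "trajectory_to_csv",
    "attractors_to_csv",
    "screen_to_csv",
    "RunConfig",
    "run_pipeline",
]


class BoolNetFormatError(ValueError):
    """Malformed BoolNet file; message carries the offending line number."""


def read_boolnet(path, aliases: Mapping[str, str] | None = None) -> BooleanNetwork:
    """Parse a BoolNet "targets, factors" file into a network.

    ``aliases`` optionally maps alternative node spellings to canonical
    names (applied to both targets and rule variables).
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_boolnet_text(text, aliases=aliases, source=str(path))


def parse_boolnet_text(
    text: str, aliases: Mapping[str, str] | None = None, source: str = "<string>"
) -> BooleanNetwork:
    aliases = dict(aliases or {})
    lines = text.splitlines()
    header_seen = False
    entries: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            fields = [f.strip().lower() for f in line.split(",")]
            if fields != ["targets", "factors"]:
                raise BoolNetFormatError(
                    f"{source}:{lineno}: expected header 'targets, factors', got {line!r}"
                )
            header_seen = True
            continue
        if "," not in line:
            raise BoolNetFormatError(f"{source}:{lineno}: expected 'target, factors' pair")
        target, rule_text = line.split(",", 1)
        entries.append((target.strip(), rule_text.strip(), lineno))
    if not header_seen:
        raise BoolNetFormatError(f"{source}: missing 'targets, factors' header")
    if not entries:
        raise BoolNetFormatError(f"{source}: no rules defined")

    rules = []
    seen = set()
    for target, rule_text, lineno in entries:
        target = aliases.get(target, target)
        if target in seen:
            raise BoolNetFormatError(f"{source}:{lineno}: duplicate node {target!r}")
        seen.add(target)
        try:
            expr = _parse_with_aliases(rule_text, aliases)
        except ParseError as exc:
            raise BoolNetFormatError(f"{source}:{lineno}: {exc}") from exc
        rules.append((target, expr))
    try:
        return BooleanNetwork(rules)
    except NetworkError as exc:
        raise BoolNetFormatError(f"{source}: {exc}") from exc


def _parse_with_aliases(rule_text: str, aliases: Mapping[str, str]):
    from .expr import Var, parse_rule

    expr = parse_rule(rule_text)
    if aliases:
        expr = expr.substitute({old: Var(new) for old, new in aliases.items()})
    return expr


def write_boolnet(net: BooleanNetwork, path) -> None:
    """Write a network in the BoolNet dialect; round-trips through the reader."""
    if len(net) == 0:  # pragma: no cover - BooleanNetwork forbids empty nets
        raise NetworkError("cannot write an empty network")
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {net.rule(name).to_infix('!')}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV reports (column order always equals node declaration order)
# ---------------------------------------------------------------------------

def trajectory_to_csv(traj: Trajectory, path) -> None:
    nodes = traj.states[0].nodes
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", *nodes])
        for t, state in enumerate(traj.states, start=1):
            writer.writerow([t, *state.bits])


def attractors_to_csv(attractors: Iterable, path) -> None:
    """One row per attractor phase; cyclic attractors share an id."""
    attractors = list(attractors)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        nodes = attractors[0].states[0].nodes if attractors else ()
        writer.writerow(["id", "length", "basin_size", *nodes])
        for i, att in enumerate(attractors, start=1):
            basin = att.basin_size if att.basin_size is not None else ""
            for state in att.states:
                writer.writerow([i, len(att.states), basin, *state.bits])


def screen_to_csv(result, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        readouts = list(result.readouts)
        writer.writerow(["node", "fixed_bit", "attractor_length", *readouts, "silencing"])
        for entry in result.entries:
            bits = [entry.readout_bits[r] for r in readouts]
            writer.writerow(
                [
                    entry.perturbation.node,
                    entry.perturbation.bit,
                    len(entry.attractor.states),
                    *bits,
                    int(entry.silencing),
                ]
            )


# ---------------------------------------------------------------------------
# Run configuration + pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of a run; output is a pure function of it."""

    model: str | None = None  # path to a BoolNet file; None = shipped SASP model
    condition: str = "baseline"
    perturbations: list[str] = dataclasses.field(default_factory=list)  # e.g. ["NEMO=0"]
    scheme: str = "synchronous"  # or "asynchronous"
    max_steps: int = 100
    seed: int = 0
    screen: bool = False
    readouts: list[str] = dataclasses.field(default_factory=lambda: ["IL6", "IL8"])
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False), encoding="utf-8"
        )


def _parse_perturbation_spec(spec: str):
    from .perturb import Perturbation

    if "=" not in spec:
        raise ValueError(f"perturbation must look like NODE=0 or NODE=1, got {spec!r}")
    node, _, bit = spec.partition("=")
    return Perturbation(node.strip(), int(bit))


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute simulate → attractor → (optional) screen and write reports.

    Returns a mapping of artifact names to the files written.  Identical
    configs (including seed) produce byte-identical outputs.
    """
    from . import __version__
    from .attractors import attractor_from_state, async_reachability_sample
    from .model import build_sasp_model
    from .perturb import apply_perturbation, screen_single_perturbations

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.model:
        net = read_boolnet(config.model)
        from .model import SaspModel

        model = SaspModel(net)
    else:
        model = build_sasp_model()

    perturbations = [_parse_perturbation_spec(s) for s in config.perturbations]
    net = model.network
    for p in perturbations:
        net = apply_perturbation(net, p)
    initial = model.condition_state(config.condition)
    for p in perturbations:
        initial = initial.replace(**{p.node: p.bit})

    from .network import simulate

    traj = simulate(net, initial, max_steps=config.max_steps)
    written: dict[str, str] = {}

    traj_path = outdir / "trajectory.csv"
    trajectory_to_csv(traj, traj_path)
    written["trajectory"] = str(traj_path)

    if config.scheme == "asynchronous":
        fixed = async_reachability_sample(
            net, initial, walks=50, steps=50 * len(net), seed=config.seed
        )
        from .attractors import Attractor

        attractors = [Attractor((s,), scheme="asynchronous-point") for s in sorted(fixed, key=lambda s: s.bits)]
    else:
        attractors = [attractor_from_state(net, initial)]
    att_path = outdir / "attractors.csv"
    attractors_to_csv(attractors, att_path)
    written["attractors"] = str(att_path)

    if config.screen:
        result = screen_single_perturbations(model, config.condition, config.readouts)
        screen_path = outdir / "screen.csv"
        screen_to_csv(result, screen_path)
        written["screen"] = str(screen_path)

    log_path = outdir / "run_log.yaml"
    log = {
        "config": dataclasses.asdict(config),
        "saspnet_version": __version__,
        "python": sys.version.split()[0],
        "n_nodes": len(net),
        "trajectory_length": len(traj),
        "n_attractors_reported": len(attractors),
    }
    log_path.write_text(yaml.safe_dump(log, sort_keys=False), encoding="utf-8")
    written["log"] = str(log_path)
    return written
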