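"""Seeded synthetic phosphorylation networks and screening scenarios.

The generator emulates the structure of a curated kinase/phosphatase
network: kinases emit phosphorylation edges, phosphatases emit
de-phosphorylation edges, most proteins are substrate-only, and a small
fraction of enzymes is activated without phosphorylation.  A virtual
stimulus (the disease trigger, absent from the network itself, like a
circulating ligand) acts through a set of direct-target places that the
atrophic state clamps to high activity; a marker panel of substrate
proteins is guaranteed to be reachable from the stimulus.

With ``plant_relay=True`` the scenario additionally wires a ground-truth
therapeutic target: a relay kinase R that is itself one of the stimulus's
direct targets and is the *only* conduit from the stimulus to the markers
(the other direct targets feed R and nothing else; the markers receive
edges only from R).  Under the default dynamics (threshold 35, unit-token
firing, 10 % floor degradation) every marker then reads zero in the
reference state, saturates at a positive level in the atrophic state and
collapses back to zero when R is inhibited, so an in-silico screen must
recover R.  All planted markers are therefore *up* markers: a single
graph-exclusive relay cannot push any downstream enzyme across the
enabling threshold (a lone edge contributes one token per block, which the
10 % degradation caps at nine tokens), so an opposite-direction leg driven
by a relay-activated phosphatase would be dynamically inert; the panel
directions are derived from the wiring that is actually effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .netmodel import (
    DE_PHOSPHORYLATION,
    KINASE,
    PHOSPHATASE,
    PHOSPHORYLATION,
    SUBSTRATE_ONLY,
    WITH_PHOSPHORYLATION,
    WITHOUT_PHOSPHORYLATION,
    Interaction,
    PhosphoNetwork,
    ProteinNode,
    write_network,
)
from .prediction import UP, MarkerPanel, interaction_graph
from .simulator import SimulationConfig, parse_keyvalue_file

#: fraction of enzymes activated without phosphorylation, mirroring the
#: observed minority (25 of 526 enzymes) in curated human networks
DEFAULT_FRAC_WITHOUT = 25 / 526


@dataclass(frozen=True, slots=True)
class SynthSpec:
    """Parameters of a synthetic network + scenario.

    Counts are totals (planted relay machinery included).  The defaults
    give a ~40-node, ~75-edge network — large enough for non-trivial
    dynamics, small enough for exhaustive property checks.
    """

    n_kinases: int = 12
    n_phosphatases: int = 4
    n_substrates: int = 24
    n_phospho_edges: int = 60
    n_dephospho_edges: int = 15
    frac_without_phosph: float = DEFAULT_FRAC_WITHOUT
    n_markers: int = 5
    stimulus_targets: int = 6
    plant_relay: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_kinases, self.n_substrates) <= 0 or self.n_phosphatases < 0:
            raise ValueError("node counts must be positive")
        if not 0.0 <= self.frac_without_phosph < 1.0:
            raise ValueError("frac_without_phosph must lie in [0, 1)")
        if not 0 < self.n_markers <= self.n_substrates:
            raise ValueError("n_markers must lie in [1, n_substrates]")
        if not 0 < self.stimulus_targets <= self.n_kinases:
            raise ValueError("stimulus_targets must lie in [1, n_kinases]")
        if self.n_phospho_edges < 0 or self.n_dephospho_edges < 0:
            raise ValueError("edge counts must be non-negative")
        if self.n_dephospho_edges > 0 and self.n_phosphatases == 0:
            raise ValueError("de-phosphorylation edges require phosphatases")
        if self.plant_relay:
            if self.n_kinases < self.stimulus_targets + 1:
                raise ValueError("plant_relay needs a kinase beyond the stimulus targets")
            planted = (self.stimulus_targets - 1) + self.n_markers
            if self.n_phospho_edges < planted:
                raise ValueError(
                    f"plant_relay needs at least {planted} phosphorylation edges"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthSpec":
        values = parse_keyvalue_file(path)
        kwargs: dict = {}
        casts = {
            "n_kinases": int,
            "n_phosphatases": int,
            "n_substrates": int,
            "n_phospho_edges": int,
            "n_dephospho_edges": int,
            "frac_without_phosph": float,
            "n_markers": int,
            "stimulus_targets": int,
            "plant_relay": lambda v: v.lower() in ("1", "true", "yes"),
            "seed": int,
        }
        for key, cast in casts.items():
            if key in values:
                kwargs[key] = cast(values[key])
        return cls(**kwargs)


@dataclass(frozen=True, slots=True)
class Scenario:
    """Everything beyond the network a screening run needs."""

    stimulus_targets: tuple[str, ...]
    panel: MarkerPanel
    relay: Optional[str] = None


class GenerationError(RuntimeError):
    """The requested spec cannot be realised."""


def _draw_unique_edges(
    rng: np.random.Generator,
    enzymes: list[str],
    substrates: list[str],
    count: int,
    itype: str,
    taken: set[tuple[str, str, str]],
) -> list[Interaction]:
    if count == 0:
        return []
    if not enzymes or not substrates:
        raise GenerationError(f"no eligible endpoints for {count} {itype} edge(s)")
    capacity = sum(1 for e in enzymes for s in substrates if e != s)
    capacity -= sum(1 for (e, s, t) in taken if t == itype and e in enzymes and s in substrates)
    if count > capacity:
        raise GenerationError(
            f"cannot place {count} unique {itype} edges over {capacity} free pairs"
        )
    out: list[Interaction] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 1000 * count + 1000:
            raise GenerationError("edge sampling failed to converge")
        e = enzymes[int(rng.integers(len(enzymes)))]
        s = substrates[int(rng.integers(len(substrates)))]
        if e == s:
            continue  # no catalytic self-loops
        key = (e, s, itype)
        if key in taken:
            continue
        taken.add(key)
        out.append(Interaction(e, s, itype, source="synthetic"))
    return out


def generate_network(spec: SynthSpec) -> tuple[PhosphoNetwork, Scenario]:
    """Generate a reproducible synthetic network and its scenario.

    Phosphorylation edges originate only from kinases, de-phosphorylation
    edges only from phosphatases.  Every marker is reachable (directed)
    from at least one stimulus target — asserted before returning.  See the
    module docstring for the planted-relay wiring.
    """
    rng = np.random.default_rng(spec.seed)
    kinases = [f"K{i + 1:03d}" for i in range(spec.n_kinases)]
    phosphatases = [f"F{i + 1:03d}" for i in range(spec.n_phosphatases)]
    substrates = [f"S{i + 1:03d}" for i in range(spec.n_substrates)]
    markers = substrates[: spec.n_markers]

    relay: Optional[str] = None
    taken: set[tuple[str, str, str]] = set()
    planted: list[Interaction] = []
    if spec.plant_relay:
        relay = kinases[0]
        feeders = kinases[1 : spec.stimulus_targets]  # direct targets besides R
        targets = [relay, *feeders]
        for f in feeders:
            planted.append(Interaction(f, relay, PHOSPHORYLATION, source="planted"))
        for m in markers:
            planted.append(Interaction(relay, m, PHOSPHORYLATION, source="planted"))
        taken.update(i.key for i in planted)
        # the relay machinery is quarantined from the random background so
        # that R remains the unique stimulus->marker conduit
        bg_kinases = kinases[spec.stimulus_targets:]
        bg_p_substrates = [
            n for n in kinases + phosphatases + substrates
            if n not in markers and n not in targets
        ]
        bg_d_substrates = bg_p_substrates
        enzyme_pool_without = bg_kinases + phosphatases
    else:
        targets = kinases[: spec.stimulus_targets]
        bg_kinases = kinases
        bg_p_substrates = kinases + phosphatases + substrates
        bg_d_substrates = bg_p_substrates
        enzyme_pool_without = kinases + phosphatases

    n_bg_p = spec.n_phospho_edges - len(planted)
    if n_bg_p < 0:
        raise GenerationError("n_phospho_edges too small for the planted wiring")
    interactions = list(planted)
    interactions += _draw_unique_edges(
        rng, bg_kinases, bg_p_substrates, n_bg_p, PHOSPHORYLATION, taken
    )
    interactions += _draw_unique_edges(
        rng, phosphatases, bg_d_substrates, spec.n_dephospho_edges, DE_PHOSPHORYLATION, taken
    )

    # activation conditions: planted machinery is with-phosphorylation by
    # construction; background enzymes flip with probability frac_without
    without = {
        e for e in enzyme_pool_without if rng.random() < spec.frac_without_phosph
    }
    nodes: dict[str, ProteinNode] = {}
    for k in kinases:
        act = WITHOUT_PHOSPHORYLATION if k in without else WITH_PHOSPHORYLATION
        nodes[k] = ProteinNode(k, KINASE, act)
    for f in phosphatases:
        act = WITHOUT_PHOSPHORYLATION if f in without else WITH_PHOSPHORYLATION
        nodes[f] = ProteinNode(f, PHOSPHATASE, act)
    for s in substrates:
        nodes[s] = ProteinNode(s, SUBSTRATE_ONLY)

    network = PhosphoNetwork(nodes, interactions)

    if not spec.plant_relay:
        # guarantee directed stimulus -> marker reachability by adding the
        # fewest possible extra phosphorylation edges
        g = interaction_graph(network)
        for m in markers:
            reach = set(targets)
            for t in targets:
                reach |= nx.descendants(g, t)
            if m in reach:
                continue
            candidates = sorted(k for k in kinases if k in reach and k != m)
            src = candidates[int(rng.integers(len(candidates)))]
            extra = Interaction(src, m, PHOSPHORYLATION, source="reachability")
            if extra.key not in taken:
                taken.add(extra.key)
                network.interactions.append(extra)
                g.add_edge(src, m)

    network.validate()
    _assert_scenario(network, targets, markers, relay)

    panel = MarkerPanel(tuple((m, UP) for m in markers))
    return network, Scenario(tuple(targets), panel, relay)


def _assert_scenario(
    network: PhosphoNetwork,
    targets: list[str],
    markers: list[str],
    relay: Optional[str],
) -> None:
    g = interaction_graph(network)
    reach = set(targets)
    for t in targets:
        reach |= nx.descendants(g, t)
    unreachable = [m for m in markers if m not in reach]
    if unreachable:
        raise GenerationError(f"markers {unreachable} unreachable from the stimulus")
    if relay is not None:
        g2 = g.copy()
        g2.remove_node(relay)
        reach2 = set()
        for t in targets:
            if t == relay:
                continue
            reach2 |= {t} | nx.descendants(g2, t)
        leaks = [m for m in markers if m in reach2]
        if leaks:
            raise GenerationError(f"markers {leaks} reachable around the planted relay")


def write_fixture(
    network: PhosphoNetwork,
    scenario: Scenario,
    out_dir: str | Path,
    config: Optional[SimulationConfig] = None,
) -> dict[str, Path]:
    """Write a complete runnable scenario: network TSVs, marker panel and a
    flat key-value scenario configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "annotations": out / "annotations.tsv",
        "panel": out / "panel.tsv",
        "scenario": out / "scenario.cfg",
    }
    write_network(network, paths["interactions"], paths["annotations"])
    scenario.panel.to_tsv(paths["panel"])
    config = config or SimulationConfig()
    lines = [
        f"stimulus_targets = {','.join(scenario.stimulus_targets)}",
        f"relay = {scenario.relay or ''}",
        f"threshold = {config.threshold}",
        f"blocks = {config.blocks}",
        f"degradation_rate = {config.degradation_rate}",
        f"iterations = {config.iterations}",
        f"init_max = {config.effective_init_max}",
        f"seed = {config.seed}",
    ]
    paths["scenario"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def read_scenario(path: str | Path) -> dict[str, str]:
    """Read back a ``scenario.cfg`` written by :func:`write_fixture`."""
    return parse_keyvalue_file(path)
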