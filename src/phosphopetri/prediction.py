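"""Therapeutic-target calling by marker direction reversal.

A marker panel is a small set of proteins whose phosphorylation is known to
change in a fixed direction in the diseased (atrophic) state.  A candidate
enzyme is called a potential therapeutic target when silencing it in the
diseased state *reverses* the disease-induced direction of change for
almost all markers, consistently across replicate screens: a marker counts
as *recovered* when the reference->atrophic and atrophic->inhibited
directions are both non-zero and opposite, and a candidate is selected when
every replicate recovers at least ``min_recovered`` of the markers.

Only the direction of change matters, never its magnitude — the screen is a
sign test, not an effect-size ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .netmodel import ENZYME_ROLES, PhosphoNetwork
from .simulator import (
    Perturbation,
    PhosphoStatus,
    SimulationConfig,
    derive_seed,
    simulate_state,
)

UP = "up"
DOWN = "down"
NONE = "none"

DEFAULT_REPLICATES = 3
DEFAULT_MIN_RECOVERED = 4


@dataclass(frozen=True, slots=True)
class MarkerPanel:
    """Ordered marker proteins with their expected atrophic direction."""

    markers: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError("marker ids must be unique")
        for m, d in self.markers:
            if d not in (UP, DOWN):
                raise ValueError(f"marker {m!r}: expected direction must be up/down, got {d!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.markers)

    @property
    def expected(self) -> dict[str, str]:
        return dict(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"protein_id", "expected_atrophic_direction"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: marker panel needs columns {sorted(required)}")
        return cls(
            tuple(
                (row.protein_id.strip(), row.expected_atrophic_direction.strip())
                for row in df.itertuples(index=False)
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "protein_id": [m for m, _ in self.markers],
                "expected_atrophic_direction": [d for _, d in self.markers],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True, slots=True)
class RecoveryRecord:
    """Per-candidate screen outcome: markers recovered in each replicate."""

    gene: str
    recovered_counts: tuple[int, ...]
    selected: bool


def direction_of_change(status_a: float, status_b: float, eps: float = 0.0) -> str:
    """Sign of the change from ``status_a`` to ``status_b``.

    Changes of magnitude <= ``eps`` (exactly zero by default) count as
    ``none``; ``none`` can never satisfy "opposite", so ties are evidence of
    nothing.
    """
    delta = status_b - status_a
    if delta > eps:
        return UP
    if delta < -eps:
        return DOWN
    return NONE


def count_recovered(
    ref: PhosphoStatus,
    atrophic: PhosphoStatus,
    inhibited: PhosphoStatus,
    panel: MarkerPanel,
    eps: float = 0.0,
) -> int:
    """Number of panel markers whose atrophic direction the inhibition reverses."""
    n = 0
    for marker in panel.ids:
        for status in (ref, atrophic, inhibited):
            if marker not in status:
                raise ValueError(f"marker {marker!r} missing from a phosphorylation status")
        leg1 = direction_of_change(ref[marker], atrophic[marker], eps)
        leg2 = direction_of_change(atrophic[marker], inhibited[marker], eps)
        if {leg1, leg2} == {UP, DOWN}:
            n += 1
    return n


def selection_verdict(recovered_counts: Sequence[int], min_recovered: int) -> bool:
    """Selection rule: every replicate must recover >= ``min_recovered``
    markers."""
    return all(c >= min_recovered for c in recovered_counts)


def interaction_graph(network: PhosphoNetwork) -> nx.DiGraph:
    """Directed enzyme->substrate graph of the network (type-agnostic)."""
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((it.enzyme_id, it.substrate_id) for it in network.interactions)
    return g


def candidate_enzymes(
    network: PhosphoNetwork, panel: MarkerPanel, mode: str = "directed"
) -> set[str]:
    """Enzymes linked to at least one panel marker.

    ``directed`` (default) requires a directed enzyme->...->marker path;
    ``undirected`` only requires membership in the same connected component.
    """
    g = interaction_graph(network)
    markers = [m for m in panel.ids if m in g]
    if mode == "directed":
        linked: set[str] = set()
        for m in markers:
            linked |= nx.ancestors(g, m)
    elif mode == "undirected":
        ug = g.to_undirected()
        linked = set()
        for m in markers:
            linked |= nx.node_connected_component(ug, m)
    else:
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    return {
        pid for pid in linked if network.nodes[pid].role in ENZYME_ROLES
    }


def predict_targets(
    network: PhosphoNetwork,
    config: SimulationConfig,
    panel: MarkerPanel,
    candidates: Iterable[str],
    stimulus_targets: Iterable[str],
    replicates: int = DEFAULT_REPLICATES,
    min_recovered: int = DEFAULT_MIN_RECOVERED,
    eps: float = 0.0,
    reference: Optional[PhosphoStatus] = None,
    atrophic: Optional[PhosphoStatus] = None,
) -> list[RecoveryRecord]:
    """Screen candidate genes for marker recovery under inhibition.

    The reference and atrophic statuses are computed once (or taken from the
    caller) and reused for every candidate.  Each candidate is then
    simulated ``replicates`` times in the inhibited state — the atrophic
    stimulus plus a zero-activity clamp on the candidate — under replicate
    seeds derived from the master seed and the candidate's identifier, so
    candidate order cannot change any result.  A candidate is selected when
    every replicate recovers at least ``min_recovered`` markers.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0 <= min_recovered <= len(panel):
        raise ValueError("min_recovered must lie between 0 and the panel size")
    candidates = sorted(set(candidates))
    unknown = [c for c in candidates if c not in network.nodes]
    if unknown:
        raise ValueError(f"candidate(s) not in network: {unknown}")
    stimulus_targets = frozenset(stimulus_targets)
    if reference is None:
        reference = simulate_state(
            network, config, None, seed=derive_seed(config.seed, "reference")
        )
    if atrophic is None:
        atrophic = simulate_state(
            network,
            config,
            Perturbation.stimulus(stimulus_targets),
            seed=derive_seed(config.seed, "atrophic"),
        )
    records: list[RecoveryRecord] = []
    for gene in candidates:
        perturbation = Perturbation.gene_inhibition(stimulus_targets, gene)
        counts = []
        for r in range(replicates):
            status = simulate_state(
                network,
                config,
                perturbation,
                seed=derive_seed(config.seed, "inhibit", gene, r),
            )
            counts.append(count_recovered(reference, atrophic, status, panel, eps))
        records.append(
            RecoveryRecord(gene, tuple(counts), selection_verdict(counts, min_recovered))
        )
    return records


def records_to_frame(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    """Tabulate screen outcomes as ``gene_id,rep1..repN,selected``."""
    if not records:
        return pd.DataFrame(columns=["gene_id", "selected"])
    n_rep = len(records[0].recovered_counts)
    data = {"gene_id": [r.gene for r in records]}
    for i in range(n_rep):
        data[f"rep{i + 1}"] = [r.recovered_counts[i] for r in records]
    data["selected"] = [r.selected for r in records]
    return pd.DataFrame(data)


def marker_direction_report(
    reference: PhosphoStatus, atrophic: PhosphoStatus, panel: MarkerPanel, eps: float = 0.0
) -> pd.DataFrame:
    """Compare simulated reference->atrophic marker directions with the
    panel's expected directions (the intermediate-validation step)."""
    rows = []
    for marker, expected in panel.markers:
        simulated = direction_of_change(reference[marker], atrophic[marker], eps)
        rows.append(
            {
                "protein_id": marker,
                "expected": expected,
                "simulated": simulated,
                "match": simulated == expected,
            }
        )
    return pd.DataFrame(rows)
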