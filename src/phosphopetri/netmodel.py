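"""Phosphorylation network model: places, transitions and curation steps.

A phosphorylation network is a directed enzyme-to-substrate graph.  Nodes are
proteins (kinases, phosphatases or substrate-only proteins); edges are typed
as phosphorylation or de-phosphorylation events.  Each enzyme additionally
carries an *activation condition*: most kinases and phosphatases are active
when they are themselves phosphorylated above an enabling threshold, but a
small minority are active *without* phosphorylation (i.e. phosphorylation
inhibits them).

This module covers building such a network from tab-separated tables and the
curation steps a real integration pipeline needs: exact-duplicate removal,
resolution of contradictory edge pairs, inference of activation conditions
from pathway-style effect/mechanism annotations, and tissue filtering against
a detected-protein list.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# node roles
KINASE = "kinase"
PHOSPHATASE = "phosphatase"
SUBSTRATE_ONLY = "substrate_only"
ROLES = (KINASE, PHOSPHATASE, SUBSTRATE_ONLY)
ENZYME_ROLES = (KINASE, PHOSPHATASE)

# activation conditions
WITH_PHOSPHORYLATION = "with_phosphorylation"
WITHOUT_PHOSPHORYLATION = "without_phosphorylation"
ACTIVATIONS = (WITH_PHOSPHORYLATION, WITHOUT_PHOSPHORYLATION)

# interaction types
PHOSPHORYLATION = "phosphorylation"
DE_PHOSPHORYLATION = "de_phosphorylation"
ITYPES = (PHOSPHORYLATION, DE_PHOSPHORYLATION)

# annotation effects (pathway-style edge annotations used for activation
# condition inference)
ACTIVATION = "activation"
INHIBITION = "inhibition"

_ITYPE_CODES = {"P": PHOSPHORYLATION, "D": DE_PHOSPHORYLATION}
_ITYPE_TO_CODE = {v: k for k, v in _ITYPE_CODES.items()}
_ROLE_CODES = {"kinase": KINASE, "phosphatase": PHOSPHATASE, "substrate": SUBSTRATE_ONLY}
_ROLE_TO_CODE = {v: k for k, v in _ROLE_CODES.items()}
_ACTIVATION_CODES = {"with": WITH_PHOSPHORYLATION, "without": WITHOUT_PHOSPHORYLATION}
_ACTIVATION_TO_CODE = {v: k for k, v in _ACTIVATION_CODES.items()}


class ParseError(ValueError):
    """A table row could not be interpreted."""


class NetworkValidationError(ValueError):
    """The assembled network violates a structural invariant."""


@dataclass(frozen=True, slots=True)
class ProteinNode:
    """One place of the net: a protein with a role and activation condition.

    Substrate-only proteins never gate a transition, but for uniformity they
    carry the default ``with_phosphorylation`` condition.
    """

    id: str
    role: str
    activation: str = WITH_PHOSPHORYLATION

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("protein id must be non-empty")
        if self.role not in ROLES:
            raise NetworkValidationError(f"unknown role {self.role!r} for {self.id}")
        if self.activation not in ACTIVATIONS:
            raise NetworkValidationError(
                f"unknown activation condition {self.activation!r} for {self.id}"
            )
        if self.role == SUBSTRATE_ONLY and self.activation != WITH_PHOSPHORYLATION:
            raise NetworkValidationError(
                f"substrate-only protein {self.id} must use the default "
                "with_phosphorylation activation condition"
            )


@dataclass(frozen=True, slots=True)
class Interaction:
    """One transition: a typed enzyme -> substrate edge."""

    enzyme_id: str
    substrate_id: str
    itype: str
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise NetworkValidationError(f"unknown interaction type {self.itype!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.enzyme_id, self.substrate_id, self.itype)


@dataclass(frozen=True, slots=True)
class KeggAnnotationPair:
    """A pathway-style annotation: enzyme acts on target with an effect
    (activation/inhibition) through a mechanism ((de-)phosphorylation)."""

    enzyme_id: str
    target_id: str
    effect: str
    mechanism: str

    def __post_init__(self) -> None:
        if self.effect not in (ACTIVATION, INHIBITION):
            raise NetworkValidationError(f"unknown effect {self.effect!r}")
        if self.mechanism not in ITYPES:
            raise NetworkValidationError(f"unknown mechanism {self.mechanism!r}")


@dataclass(slots=True)
class NetworkStats:
    """Counts of nodes by role, edges by type and enzymes by activation."""

    n_nodes: int = 0
    n_kinases: int = 0
    n_phosphatases: int = 0
    n_substrate_only: int = 0
    n_interactions: int = 0
    n_phosphorylation: int = 0
    n_de_phosphorylation: int = 0
    n_enzymes_with_phosphorylation: int = 0
    n_enzymes_without_phosphorylation: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(slots=True)
class PhosphoNetwork:
    """A validated phosphorylation network (places + typed transitions)."""

    nodes: dict[str, ProteinNode] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    @property
    def places(self) -> list[str]:
        """Place identifiers in a stable (insertion) order."""
        return list(self.nodes)

    def validate(self) -> None:
        """Check referential integrity and role constraints.

        Raises :class:`NetworkValidationError` if an interaction endpoint is
        missing from the node table or an edge originates from a
        substrate-only protein.
        """
        for it in self.interactions:
            if it.enzyme_id not in self.nodes:
                raise NetworkValidationError(
                    f"interaction references unknown enzyme {it.enzyme_id!r}"
                )
            if it.substrate_id not in self.nodes:
                raise NetworkValidationError(
                    f"interaction references unknown substrate {it.substrate_id!r}"
                )
            if self.nodes[it.enzyme_id].role not in ENZYME_ROLES:
                raise NetworkValidationError(
                    f"interaction enzyme {it.enzyme_id!r} is not a kinase or phosphatase"
                )

    def copy(self) -> "PhosphoNetwork":
        return PhosphoNetwork(dict(self.nodes), list(self.interactions))


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def load_annotations(path: str | Path) -> dict[str, ProteinNode]:
    """Read a protein annotation TSV (``protein_id  role  activation``)."""
    df = _read_tsv(path, ["protein_id", "role", "activation"])
    nodes: dict[str, ProteinNode] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        pid = row.protein_id.strip()
        role = _ROLE_CODES.get(row.role.strip())
        activation = _ACTIVATION_CODES.get(row.activation.strip())
        if not pid or role is None or activation is None:
            raise ParseError(f"{path}: line {line}: malformed annotation row {tuple(row)!r}")
        if pid in nodes:
            raise ParseError(f"{path}: line {line}: duplicate protein id {pid!r}")
        try:
            nodes[pid] = ProteinNode(pid, role, activation)
        except NetworkValidationError as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    return nodes


def load_interactions(path: str | Path) -> list[Interaction]:
    """Read an interaction TSV (``enzyme_id  substrate_id  itype  [source]``)."""
    df = _read_tsv(path, ["enzyme_id", "substrate_id", "itype"])
    has_source = "source" in df.columns
    interactions: list[Interaction] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        enzyme = row.enzyme_id.strip()
        substrate = row.substrate_id.strip()
        itype = _ITYPE_CODES.get(row.itype.strip())
        if not enzyme or not substrate or itype is None:
            raise ParseError(f"{path}: line {line}: malformed interaction row {tuple(row)!r}")
        source = getattr(row, "source", "").strip() if has_source else None
        interactions.append(Interaction(enzyme, substrate, itype, source or None))
    return interactions


def load_network(interaction_table: str | Path, annotation_table: str | Path) -> PhosphoNetwork:
    """Build a validated :class:`PhosphoNetwork` from the two TSV tables."""
    nodes = load_annotations(annotation_table)
    interactions = load_interactions(interaction_table)
    network = PhosphoNetwork(nodes, interactions)
    network.validate()
    return network


def write_network(
    network: PhosphoNetwork,
    interaction_table: str | Path,
    annotation_table: str | Path,
) -> None:
    """Serialize a network back to the two-TSV external format."""
    ann = pd.DataFrame(
        {
            "protein_id": [n.id for n in network.nodes.values()],
            "role": [_ROLE_TO_CODE[n.role] for n in network.nodes.values()],
            "activation": [_ACTIVATION_TO_CODE[n.activation] for n in network.nodes.values()],
        }
    )
    ann.to_csv(annotation_table, sep="\t", index=False)
    ints = pd.DataFrame(
        {
            "enzyme_id": [i.enzyme_id for i in network.interactions],
            "substrate_id": [i.substrate_id for i in network.interactions],
            "itype": [_ITYPE_TO_CODE[i.itype] for i in network.interactions],
            "source": [i.source or "" for i in network.interactions],
        }
    )
    ints.to_csv(interaction_table, sep="\t", index=False)


def deduplicate(interactions: Iterable[Interaction]) -> list[Interaction]:
    """Collapse exact ``(enzyme, substrate, itype)`` duplicates.

    The first occurrence (and its provenance tag) is kept.  Idempotent.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[Interaction] = []
    for it in interactions:
        if it.key not in seen:
            seen.add(it.key)
            out.append(it)
    return out


def find_conflicts(interactions: Iterable[Interaction]) -> set[tuple[str, str]]:
    """Ordered pairs that carry both a phosphorylation and a
    de-phosphorylation edge."""
    by_pair: dict[tuple[str, str], set[str]] = {}
    for it in interactions:
        by_pair.setdefault((it.enzyme_id, it.substrate_id), set()).add(it.itype)
    return {pair for pair, types in by_pair.items() if len(types) == 2}


def resolve_conflicts(
    interactions: Sequence[Interaction],
    resolution_table: Optional[Mapping[tuple[str, str], str]] = None,
) -> list[Interaction]:
    """Remove contradictory edge pairs.

    A pair ``(enzyme, substrate)`` annotated as both phosphorylation and
    de-phosphorylation is a curation conflict.  When ``resolution_table``
    maps the pair to the interaction type to keep (evidence-based
    resolution), only that edge survives; otherwise both directions are
    dropped conservatively and the count is logged.
    """
    resolution_table = dict(resolution_table or {})
    conflicts = find_conflicts(interactions)
    for pair, keep in resolution_table.items():
        if keep not in ITYPES:
            raise ValueError(f"resolution for {pair} must be one of {ITYPES}, got {keep!r}")
        if pair not in conflicts:
            logger.warning("resolution entry for non-conflicted pair %s ignored", pair)
    out: list[Interaction] = []
    n_dropped = 0
    for it in interactions:
        pair = (it.enzyme_id, it.substrate_id)
        if pair in conflicts:
            keep = resolution_table.get(pair)
            if keep is None or it.itype != keep:
                n_dropped += 1
                continue
        out.append(it)
    if n_dropped:
        logger.warning(
            "removed %d conflicted interaction(s) across %d enzyme-substrate pair(s)",
            n_dropped,
            len(conflicts),
        )
    return out


def infer_activation_condition(
    pairs: Iterable[KeggAnnotationPair], enzyme_id: str
) -> str:
    """Infer the activation condition of ``enzyme_id`` from its incoming
    pathway annotations.

    The default assumption is activation *with* phosphorylation (the
    phosphorylation-cascade picture).  The enzyme is instead classified as
    activated *without* phosphorylation iff some upstream annotation couples
    activation with de-phosphorylation, or inhibition with phosphorylation —
    either combination is direct evidence that phosphate removal turns the
    enzyme on.  Order-independent; special evidence overrides the default.
    """
    for p in pairs:
        if p.target_id != enzyme_id:
            continue
        if (p.effect, p.mechanism) in (
            (ACTIVATION, DE_PHOSPHORYLATION),
            (INHIBITION, PHOSPHORYLATION),
        ):
            return WITHOUT_PHOSPHORYLATION
    return WITH_PHOSPHORYLATION


def load_kegg_annotation_pairs(path: str | Path) -> list[KeggAnnotationPair]:
    """Read an effect/mechanism annotation TSV
    (``enzyme_id  target_id  effect  mechanism{P|D}``)."""
    df = _read_tsv(path, ["enzyme_id", "target_id", "effect", "mechanism"])
    pairs = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        mech = _ITYPE_CODES.get(row.mechanism.strip())
        effect = row.effect.strip()
        if mech is None or effect not in (ACTIVATION, INHIBITION):
            raise ParseError(f"{path}: line {line}: malformed annotation pair {tuple(row)!r}")
        pairs.append(KeggAnnotationPair(row.enzyme_id.strip(), row.target_id.strip(), effect, mech))
    return pairs


def filter_by_tissue(network: PhosphoNetwork, detected_ids: Iterable[str]) -> PhosphoNetwork:
    """Restrict the network to interactions between tissue-detected proteins.

    Interactions with either endpoint outside ``detected_ids`` are removed;
    nodes left without any interaction are dropped as orphans.  Idempotent.
    """
    detected = set(detected_ids)
    kept = [
        it
        for it in network.interactions
        if it.enzyme_id in detected and it.substrate_id in detected
    ]
    used = {it.enzyme_id for it in kept} | {it.substrate_id for it in kept}
    nodes = {pid: node for pid, node in network.nodes.items() if pid in used}
    return PhosphoNetwork(nodes, kept)


def load_detected_ids(path: str | Path) -> set[str]:
    """Read a one-id-per-line detected-protein list."""
    text = Path(path).read_text(encoding="utf-8")
    return {line.strip() for line in text.splitlines() if line.strip()}


def network_stats(network: PhosphoNetwork) -> NetworkStats:
    """Summary counts of a network (nodes by role, edges by type,
    enzymes by activation condition)."""
    roles = Counter(n.role for n in network.nodes.values())
    itypes = Counter(i.itype for i in network.interactions)
    activations = Counter(
        n.activation for n in network.nodes.values() if n.role in ENZYME_ROLES
    )
    return NetworkStats(
        n_nodes=len(network.nodes),
        n_kinases=roles[KINASE],
        n_phosphatases=roles[PHOSPHATASE],
        n_substrate_only=roles[SUBSTRATE_ONLY],
        n_interactions=len(network.interactions),
        n_phosphorylation=itypes[PHOSPHORYLATION],
        n_de_phosphorylation=itypes[DE_PHOSPHORYLATION],
        n_enzymes_with_phosphorylation=activations[WITH_PHOSPHORYLATION],
        n_enzymes_without_phosphorylation=activations[WITHOUT_PHOSPHORYLATION],
    )
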