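"""Phosphorylation-specific Petri net execution.

Semantics
---------
Places are proteins; the integer token count of a place is its amount of
phosphate (its phosphorylation status).  Transitions are typed edges:

* a *phosphorylation* transition adds one token to its substrate place,
* a *de-phosphorylation* transition removes one token (clamped at zero),

and neither changes the enzyme (input) place.  A transition is enabled by
its input place's token count relative to the enabling threshold tau:
enzymes activated *with* phosphorylation fire when ``tokens > tau``, enzymes
activated *without* phosphorylation fire when ``tokens < tau`` — both
inequalities strict, so a count exactly at tau enables nothing.

One *block* is a full pass through a freshly shuffled transition list
followed by a degradation step that removes 10 % (by default) of the tokens
of every place, rounding down.  A simulation starts from a random integer
marking, uniform on ``[0, 2*tau]`` per place, and runs a fixed number of
blocks; token counts saturate well before the final block on networks of
the size studied here.

States are imposed through perturbations applied before every transition
check: a stimulus clamps its direct-target places to high activity
(``2*tau`` tokens); a gene inhibition pins the gene's place at zero tokens
*and* suppresses every transition the gene catalyses (zero tokens would
otherwise count as *active* for a without-phosphorylation enzyme).

The *phosphorylation status* of a state is the per-place arithmetic mean of
the final-block markings over several independently seeded iterations.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .netmodel import (
    PHOSPHORYLATION,
    WITH_PHOSPHORYLATION,
    WITHOUT_PHOSPHORYLATION,
    PhosphoNetwork,
)

Marking = dict[str, int]
PhosphoStatus = dict[str, float]

DEFAULT_THRESHOLD = 35
DEFAULT_BLOCKS = 100
DEFAULT_DEGRADATION_RATE = 0.10
DEFAULT_ITERATIONS = 10


def derive_seed(master: int, *tokens: object) -> int:
    """Deterministically split a master seed into an independent sub-seed.

    The derivation chains a CRC-32 over the string form of ``tokens``, so it
    is stable across processes and platforms (unlike the builtin ``hash``).
    The result is a non-negative 31-bit integer.
    """
    h = zlib.crc32(str(int(master)).encode("utf-8"))
    for t in tokens:
        h = zlib.crc32(str(t).encode("utf-8"), h)
    return h & 0x7FFFFFFF


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Parameters of one Petri net simulation campaign.

    threshold
        Enabling threshold tau (tokens).
    blocks
        Number of shuffled-list passes per simulation.
    degradation_rate
        Fraction of tokens removed from every place after each block.
    iterations
        Number of independently seeded simulations averaged into a
        phosphorylation status.
    init_max
        Upper bound (inclusive) of the uniform random initial marking;
        defaults to ``2 * threshold``.
    seed
        Master seed; every stream of randomness is derived from it.
    """

    threshold: int = DEFAULT_THRESHOLD
    blocks: int = DEFAULT_BLOCKS
    degradation_rate: float = DEFAULT_DEGRADATION_RATE
    iterations: int = DEFAULT_ITERATIONS
    init_max: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be a positive integer")
        if self.blocks <= 0:
            raise ValueError("blocks must be positive")
        if not 0.0 < self.degradation_rate < 1.0:
            raise ValueError("degradation_rate must lie strictly between 0 and 1")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.init_max is not None and self.init_max < 0:
            raise ValueError("init_max must be >= 0")

    @property
    def effective_init_max(self) -> int:
        return 2 * self.threshold if self.init_max is None else self.init_max

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read a flat ``key = value`` configuration file."""
        values = parse_keyvalue_file(path)
        kwargs: dict = {}
        for key, cast in (
            ("threshold", int),
            ("blocks", int),
            ("degradation_rate", float),
            ("iterations", int),
            ("init_max", int),
            ("seed", int),
        ):
            if key in values:
                kwargs[key] = cast(values[key])
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"threshold = {self.threshold}",
            f"blocks = {self.blocks}",
            f"degradation_rate = {self.degradation_rate}",
            f"iterations = {self.iterations}",
            f"init_max = {self.effective_init_max}",
            f"seed = {self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def parse_keyvalue_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file (``#`` starts a comment)."""
    values: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, value = line.split("=", 1)
        values[key.strip()] = value.strip()
    return values


@dataclass(frozen=True)
class Perturbation:
    """State-specific forcing applied before every transition check.

    ``clamp_high`` places are pinned to ``high_value`` tokens (default
    ``2 * tau``, resolved at simulation time); ``inhibit`` places are pinned
    to zero tokens and all transitions they catalyse are suppressed.
    """

    clamp_high: frozenset[str] = frozenset()
    inhibit: frozenset[str] = frozenset()
    high_value: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "clamp_high", frozenset(self.clamp_high))
        object.__setattr__(self, "inhibit", frozenset(self.inhibit))
        overlap = self.clamp_high & self.inhibit
        if overlap:
            raise ValueError(
                f"places {sorted(overlap)} cannot be both clamped high and inhibited"
            )

    @classmethod
    def stimulus(cls, targets: Iterable[str], high_value: Optional[int] = None) -> "Perturbation":
        """High activity on the stimulus's direct targets (atrophic state)."""
        return cls(clamp_high=frozenset(targets), high_value=high_value)

    @classmethod
    def gene_inhibition(
        cls,
        stimulus_targets: Iterable[str],
        gene: str,
        high_value: Optional[int] = None,
    ) -> "Perturbation":
        """Gene inhibition layered on the stimulated (atrophic) state."""
        return cls(
            clamp_high=frozenset(stimulus_targets) - {gene},
            inhibit=frozenset({gene}),
            high_value=high_value,
        )

    def resolved_high_value(self, threshold: int) -> int:
        return 2 * threshold if self.high_value is None else self.high_value


EMPTY_PERTURBATION = Perturbation()


def is_enabled(input_tokens: int, activation: str, threshold: int) -> bool:
    """Enabling rule for one transition given its input place.

    Strict inequalities on both sides: ``tokens == threshold`` enables
    nothing under either activation regime.
    """
    if input_tokens < 0:
        raise ValueError("token counts are non-negative")
    if activation == WITH_PHOSPHORYLATION:
        return input_tokens > threshold
    if activation == WITHOUT_PHOSPHORYLATION:
        return input_tokens < threshold
    raise ValueError(f"unknown activation condition {activation!r}")


def fire(interaction, marking: Marking) -> Marking:
    """Fire one transition: substrate +-1 (clamped at zero), enzyme unchanged."""
    out = dict(marking)
    if interaction.itype == PHOSPHORYLATION:
        out[interaction.substrate_id] += 1
    elif out[interaction.substrate_id] > 0:
        out[interaction.substrate_id] -= 1
    return out


def degrade(marking: Marking, rate: float) -> Marking:
    """Remove a fraction of every place's tokens, rounding down.

    ``floor((1 - rate) * n)`` keeps counts integral and strictly decreases
    every positive count, so an unfed place always decays to zero.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie strictly between 0 and 1")
    keep = 1.0 - rate
    return {p: math.floor(n * keep) for p, n in marking.items()}


def apply_perturbation(marking: Marking, perturbation: Perturbation,
                       threshold: int = DEFAULT_THRESHOLD) -> Marking:
    """Impose a perturbation on a marking (pure; other places untouched)."""
    out = dict(marking)
    high = perturbation.resolved_high_value(threshold)
    for p in perturbation.clamp_high:
        out[p] = high
    for p in perturbation.inhibit:
        out[p] = 0
    return out


def _compile(network: PhosphoNetwork) -> list[tuple[str, str, int, bool]]:
    """Flatten transitions to (enzyme, substrate, delta, enzyme_with_phos)."""
    compiled = []
    for it in network.interactions:
        delta = 1 if it.itype == PHOSPHORYLATION else -1
        with_phos = network.nodes[it.enzyme_id].activation == WITH_PHOSPHORYLATION
        compiled.append((it.enzyme_id, it.substrate_id, delta, with_phos))
    return compiled


def _check_perturbation_places(network: PhosphoNetwork, perturbation: Perturbation) -> None:
    unknown = (perturbation.clamp_high | perturbation.inhibit) - set(network.nodes)
    if unknown:
        raise ValueError(f"perturbation references unknown place(s) {sorted(unknown)}")


def _run_block_inplace(
    compiled: list[tuple[str, str, int, bool]],
    tokens: Marking,
    clamp: tuple[str, ...],
    inhibit: frozenset[str],
    high_value: int,
    threshold: int,
    keep: float,
    order: np.ndarray,
) -> None:
    for idx in order:
        enzyme, substrate, delta, with_phos = compiled[idx]
        for p in clamp:
            tokens[p] = high_value
        for p in inhibit:
            tokens[p] = 0
        if enzyme in inhibit:
            continue
        t = tokens[enzyme]
        enabled = t > threshold if with_phos else t < threshold
        if enabled:
            if delta > 0:
                tokens[substrate] += 1
            elif tokens[substrate] > 0:
                tokens[substrate] -= 1
    # re-impose the state before degradation so the recorded marking honours
    # the perturbation (an inhibited place reads exactly zero in every block)
    for p in clamp:
        tokens[p] = high_value
    for p in inhibit:
        tokens[p] = 0
    for p in tokens:
        tokens[p] = math.floor(tokens[p] * keep)


def run_block(
    network: PhosphoNetwork,
    marking: Marking,
    perturbation: Optional[Perturbation],
    threshold: int,
    rng: np.random.Generator,
    degradation_rate: float = DEFAULT_DEGRADATION_RATE,
) -> Marking:
    """Execute one block: shuffled transition pass, then degradation."""
    perturbation = perturbation or EMPTY_PERTURBATION
    _check_perturbation_places(network, perturbation)
    compiled = _compile(network)
    tokens = dict(marking)
    order = rng.permutation(len(compiled)) if compiled else np.empty(0, dtype=int)
    _run_block_inplace(
        compiled,
        tokens,
        tuple(sorted(perturbation.clamp_high)),
        perturbation.inhibit,
        perturbation.resolved_high_value(threshold),
        threshold,
        1.0 - degradation_rate,
        order,
    )
    return tokens


def _initial_marking(
    network: PhosphoNetwork, config: SimulationConfig, rng: np.random.Generator
) -> Marking:
    draws = rng.integers(0, config.effective_init_max, size=len(network.nodes), endpoint=True)
    return {p: int(v) for p, v in zip(network.places, draws)}


def _simulate(
    network: PhosphoNetwork,
    config: SimulationConfig,
    perturbation: Optional[Perturbation],
    rng: np.random.Generator,
    initial_marking: Optional[Marking],
    record: bool,
) -> tuple[Optional[list[Marking]], Marking]:
    perturbation = perturbation or EMPTY_PERTURBATION
    _check_perturbation_places(network, perturbation)
    compiled = _compile(network)
    clamp = tuple(sorted(perturbation.clamp_high))
    inhibit = perturbation.inhibit
    high = perturbation.resolved_high_value(config.threshold)
    keep = 1.0 - config.degradation_rate
    if initial_marking is None:
        tokens = _initial_marking(network, config, rng)
    else:
        missing = set(network.nodes) - set(initial_marking)
        if missing:
            raise ValueError(f"initial marking misses place(s) {sorted(missing)}")
        tokens = {p: int(initial_marking[p]) for p in network.places}
    trajectory: Optional[list[Marking]] = [] if record else None
    n = len(compiled)
    for _ in range(config.blocks):
        order = rng.permutation(n) if n else np.empty(0, dtype=int)
        _run_block_inplace(compiled, tokens, clamp, inhibit, high, config.threshold, keep, order)
        if record:
            trajectory.append(dict(tokens))
    return trajectory, tokens


def simulate(
    network: PhosphoNetwork,
    config: SimulationConfig,
    perturbation: Optional[Perturbation] = None,
    rng: Optional[np.random.Generator] = None,
    initial_marking: Optional[Marking] = None,
) -> pd.DataFrame:
    """Run one simulation and return its trajectory.

    Returns a DataFrame with one row per block (index 1..blocks) and one
    integer column per place.  The initial marking is drawn uniformly on
    ``[0, init_max]`` unless supplied explicitly.
    """
    if rng is None:
        rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
    trajectory, _ = _simulate(network, config, perturbation, rng, initial_marking, record=True)
    df = pd.DataFrame(trajectory, columns=network.places)
    df.index = pd.RangeIndex(1, config.blocks + 1, name="block")
    return df


def simulate_final(
    network: PhosphoNetwork,
    config: SimulationConfig,
    perturbation: Optional[Perturbation] = None,
    rng: Optional[np.random.Generator] = None,
    initial_marking: Optional[Marking] = None,
) -> Marking:
    """Run one simulation and return only the final-block marking."""
    if rng is None:
        rng = np.random.default_rng(derive_seed(config.seed, "simulate"))
    _, final = _simulate(network, config, perturbation, rng, initial_marking, record=False)
    return final


def simulate_state(
    network: PhosphoNetwork,
    config: SimulationConfig,
    perturbation: Optional[Perturbation] = None,
    seed: Optional[int] = None,
) -> PhosphoStatus:
    """Phosphorylation status of one state.

    Runs ``config.iterations`` simulations under sub-seeds derived from the
    master seed (so results do not depend on how many iterations follow) and
    averages the final-block markings per place.
    """
    master = config.seed if seed is None else seed
    totals = np.zeros(len(network.nodes), dtype=float)
    places = network.places
    for i in range(config.iterations):
        rng = np.random.default_rng(derive_seed(master, "iteration", i))
        final = simulate_final(network, config, perturbation, rng=rng)
        totals += np.array([final[p] for p in places], dtype=float)
    totals /= config.iterations
    return {p: float(v) for p, v in zip(places, totals)}


def status_to_frame(status: PhosphoStatus) -> pd.DataFrame:
    """Tabulate a phosphorylation status as ``place_id,status``."""
    return pd.DataFrame(
        {"place_id": list(status), "status": [status[p] for p in status]}
    )
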