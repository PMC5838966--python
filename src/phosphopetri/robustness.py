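"""Enabling-threshold selection by rank-correlation robustness.

The simulator's behaviour depends on the enabling threshold tau.  A
threshold is considered *robust* when independently seeded simulations
agree on the ordering of places by their saturated (final-block) token
counts.  For each candidate tau the scan runs several simulations per
state, ranks the places of each run by final marking, computes Spearman's
rank correlation for every unordered pair of runs (k runs give
k*(k-1)/2 correlations), and averages.  The tau with the highest mean
correlation — averaged over the reference and stimulated states — wins;
ties go to the smallest tau.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netmodel import PhosphoNetwork
from .simulator import (
    Perturbation,
    SimulationConfig,
    derive_seed,
    simulate_final,
)

#: the candidate grid scanned by default
DEFAULT_THRESHOLDS: tuple[int, ...] = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)

REFERENCE_STATE = "reference"
ATROPHIC_STATE = "atrophic"


def spearman(rank_a: Mapping[str, float], rank_b: Mapping[str, float]) -> float:
    """Spearman's rho between two per-place scores (average-rank ties).

    The inputs map every place to a sortable score (e.g. its final-block
    token count); both mappings must cover the identical id set.
    """
    if set(rank_a) != set(rank_b):
        raise ValueError("rank lists must cover identical place sets")
    ids = sorted(rank_a)
    va = np.array([rank_a[p] for p in ids], dtype=float)
    vb = np.array([rank_b[p] for p in ids], dtype=float)
    if np.ptp(va) == 0.0 or np.ptp(vb) == 0.0:
        # a constant list carries no ordering information
        return float("nan")
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


def avg_pairwise_correlation(lists: Sequence[Mapping[str, float]]) -> float:
    """Mean Spearman's rho over all unordered pairs of ranked lists."""
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")
    rhos = [spearman(a, b) for a, b in itertools.combinations(lists, 2)]
    return float(np.mean(rhos))


@dataclass(frozen=True, slots=True)
class ScanResult:
    """Per-threshold robustness scores and the selected threshold."""

    chosen_threshold: int
    table: pd.DataFrame  # columns: threshold, score_reference, score_atrophic, score_mean


def scan_thresholds(
    network: PhosphoNetwork,
    config: SimulationConfig,
    stimulus_targets: Iterable[str],
    candidate_thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> ScanResult:
    """Score every candidate enabling threshold and pick the most robust.

    For each tau, ``config.iterations`` independently seeded simulations are
    run in the reference state and in the stimulated (atrophic) state; the
    per-state robustness is the average pairwise Spearman correlation of the
    final markings, and the two states' scores are averaged for selection.
    The initial-marking range follows tau (``2 * tau``) unless the
    configuration pins ``init_max`` explicitly.  Fully deterministic under a
    fixed master seed; ties are broken toward the smallest tau.
    """
    candidate_thresholds = list(candidate_thresholds)
    if not candidate_thresholds:
        raise ValueError("candidate threshold list must be non-empty")
    stimulus_targets = frozenset(stimulus_targets)
    perturbations = {
        REFERENCE_STATE: None,
        ATROPHIC_STATE: Perturbation.stimulus(stimulus_targets),
    }
    rows = []
    for tau in candidate_thresholds:
        cfg = replace(config, threshold=tau)
        scores: dict[str, float] = {}
        for state, perturbation in perturbations.items():
            finals = []
            for i in range(cfg.iterations):
                rng = np.random.default_rng(
                    derive_seed(config.seed, "scan", tau, state, i)
                )
                final = simulate_final(network, cfg, perturbation, rng=rng)
                finals.append({p: float(v) for p, v in final.items()})
            scores[state] = avg_pairwise_correlation(finals)
        rows.append(
            {
                "threshold": tau,
                "score_reference": scores[REFERENCE_STATE],
                "score_atrophic": scores[ATROPHIC_STATE],
                "score_mean": 0.5 * (scores[REFERENCE_STATE] + scores[ATROPHIC_STATE]),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["score_mean"].idxmax(), "score_mean"]
    chosen = int(table.loc[table["score_mean"] >= best, "threshold"].min())
    return ScanResult(chosen_threshold=chosen, table=table)
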