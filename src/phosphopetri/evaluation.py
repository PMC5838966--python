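"""Statistical evaluation of a predicted gene set.

Two independent yardsticks:

* **Hypergeometric overlap** — the upper-tail probability of drawing at
  least the observed number of gold-standard genes when the predicted set
  is a random draw from the candidate population.  Computed by exact
  integer summation of the probability mass (the populations here are a few
  hundred genes, so no approximation is needed).
* **Shortest-path proximity** — a static network baseline that ranks genes
  by their average unweighted shortest-path length to a marker panel.  Genes
  tied at the cutoff length are all included, so a requested top-k may
  expand beyond k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .netmodel import PhosphoNetwork
from .prediction import MarkerPanel, interaction_graph


@dataclass(frozen=True, slots=True)
class GeneSetOverlap:
    """An observed overlap and its upper-tail hypergeometric p-value."""

    population_size: int
    gold_in_population: int
    predicted: int
    overlap: int
    p_value: float


@dataclass(frozen=True, slots=True)
class ProximityResult:
    """A gene's average shortest-path length to the marker panel.

    ``avg_shortest_path_length`` is NaN when no marker is reachable;
    ``n_unreachable`` flags markers excluded from the average.
    """

    gene: str
    avg_shortest_path_length: float
    n_unreachable: int
    rank: Optional[int] = None


def _check_hypergeom_args(N: int, K: int, n: int, k: int) -> None:
    if min(N, K, n, k) < 0:
        raise ValueError("hypergeometric arguments must be non-negative")
    if K > N or n > N:
        raise ValueError("K and n must not exceed the population size N")
    if k > min(K, n):
        raise ValueError("k must not exceed min(K, n)")


def hypergeometric_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n), exact."""
    _check_hypergeom_args(N, K, n, k)
    num = math.comb(K, k) * math.comb(N - K, n - k)
    return num / math.comb(N, n)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Exact summation of the probability mass over ``k .. min(K, n)`` in
    arbitrary-precision integer arithmetic; the division to a float is the
    only rounding step.
    """
    _check_hypergeom_args(N, K, n, k)
    hi = min(K, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
    return num / math.comb(N, n)


def overlap_test(
    population: Iterable[str], gold: Iterable[str], predicted: Iterable[str]
) -> GeneSetOverlap:
    """Hypergeometric overlap test of a predicted set against a gold set.

    Both ``gold`` and ``predicted`` must be subsets of ``population``.
    """
    population = set(population)
    gold = set(gold)
    predicted = set(predicted)
    if not gold <= population:
        raise ValueError(f"gold genes outside the population: {sorted(gold - population)}")
    if not predicted <= population:
        raise ValueError(
            f"predicted genes outside the population: {sorted(predicted - population)}"
        )
    N, K, n = len(population), len(gold), len(predicted)
    k = len(gold & predicted)
    return GeneSetOverlap(N, K, n, k, hypergeometric_upper_tail(N, K, n, k))


def avg_path_to_panel(
    network: PhosphoNetwork, gene: str, panel: MarkerPanel, mode: str = "undirected"
) -> float:
    """Average unweighted shortest-path length from ``gene`` to the panel.

    Unreachable markers are excluded from the average; NaN when every
    marker is unreachable.  ``mode`` chooses whether edge direction is
    respected.
    """
    length, n_unreachable = _path_lengths(network, gene, panel, mode)
    return length


def _path_lengths(
    network: PhosphoNetwork, gene: str, panel: MarkerPanel, mode: str
) -> tuple[float, int]:
    if gene not in network.nodes:
        raise ValueError(f"gene {gene!r} not in network")
    g = interaction_graph(network)
    if mode == "undirected":
        g = g.to_undirected(as_view=True)
    elif mode != "directed":
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    dist = nx.single_source_shortest_path_length(g, gene)
    lengths = [dist[m] for m in panel.ids if m in dist]
    n_unreachable = len(panel) - len(lengths)
    if not lengths:
        return math.nan, n_unreachable
    return float(sum(lengths) / len(lengths)), n_unreachable


def proximity_ranking(
    network: PhosphoNetwork,
    genes: Iterable[str],
    panel: MarkerPanel,
    mode: str = "undirected",
) -> list[ProximityResult]:
    """Rank genes by average shortest-path length to the panel (ascending).

    Ties share the smallest rank of their class (competition ranking);
    genes with no reachable marker sort last with rank ``None``.
    """
    results = []
    for gene in sorted(set(genes)):
        length, n_unreachable = _path_lengths(network, gene, panel, mode)
        results.append((gene, length, n_unreachable))
    finite = sorted(
        (r for r in results if not math.isnan(r[1])), key=lambda r: (r[1], r[0])
    )
    ranked: list[ProximityResult] = []
    prev_length: Optional[float] = None
    prev_rank = 0
    for i, (gene, length, n_unreachable) in enumerate(finite, start=1):
        rank = prev_rank if length == prev_length else i
        ranked.append(ProximityResult(gene, length, n_unreachable, rank))
        prev_length, prev_rank = length, rank
    for gene, length, n_unreachable in sorted(r for r in results if math.isnan(r[1])):
        ranked.append(ProximityResult(gene, length, n_unreachable, None))
    return ranked


def top_k_by_proximity(results: Sequence[ProximityResult], k: int) -> set[str]:
    """The k proximity-closest genes, expanded to the full tie class.

    Every gene tied at the k-th smallest length is included, so the
    returned set may exceed ``k`` members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    finite = sorted(
        (r for r in results if not math.isnan(r.avg_shortest_path_length)),
        key=lambda r: (r.avg_shortest_path_length, r.gene),
    )
    if not finite:
        return set()
    if k >= len(finite):
        return {r.gene for r in finite}
    cutoff = finite[k - 1].avg_shortest_path_length
    return {r.gene for r in finite if r.avg_shortest_path_length <= cutoff}
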