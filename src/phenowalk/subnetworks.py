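"""Sub-network extraction, consensus building and significance filtering.

The second stage of the pipeline turns each ranked protein list into
candidate sub-networks by seeded expansion (the GIGA scheme: grow from
locally best-ranked proteins, adding the best-ranked boundary protein and
absorbing better-ranked surroundings, scored by the probability that a
random draw of ``n`` proteins from ``N`` would all rank at least as well as
the worst member).  Proteins present in the extracted sub-networks of every
parameter combination form the consensus; its connected components are
tested against random connected sub-networks of equal size (snowball
sampling) by comparing summed pi-values, and the resulting empirical
p-values are filtered at a Benjamini-Hochberg FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .expression import ExpressionScores
from .heterogeneous import RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "SubNetwork",
    "ConsensusSubnetwork",
    "SamplingConfig",
    "giga_significance",
    "find_local_minima",
    "giga_expand",
    "extract_all",
    "consensus",
    "sample_random_subnetwork",
    "empirical_pvalue",
    "fdr_filter",
]


@dataclass(frozen=True)
class SubNetwork:
    """One extracted sub-network: a connected protein set with its score."""

    members: frozenset[str]
    score_p: float
    seed: str
    alpha: float = float("nan")
    eta: float = float("nan")
    lambda_: float = float("nan")


@dataclass(frozen=True)
class ConsensusSubnetwork:
    """A connected component of the complete-co-occurrence protein set."""

    members: frozenset[str]
    empirical_p: float | None = None
    r: int | None = None
    n: int | None = None
    fdr_pass: bool | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SamplingConfig:
    """Random sub-network sampling and FDR settings."""

    n_samples: int = 10000
    fdr_level: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if not 0.0 < self.fdr_level < 1.0:
            raise ConfigurationError("fdr_level must be in (0, 1)")


def giga_significance(n: int, r_max: int, total: int) -> float:
    """Probability that ``n`` proteins drawn without replacement from
    ``total`` all have rank <= ``r_max``.

    Equals ``C(r_max, n) / C(total, n)``, computed as a running product for
    numerical stability.  Small values mean the member set is improbably
    well ranked.
    """
    if not (1 <= n <= r_max <= total):
        raise ValueError(
            f"require 1 <= n <= r_max <= total, got n={n}, r_max={r_max}, total={total}"
        )
    p = 1.0
    for i in range(n):
        p *= (r_max - i) / (total - i)
    return p


def _rank_map(ranks: RankedList | Mapping[str, int]) -> dict[str, int]:
    if isinstance(ranks, RankedList):
        return ranks.rank_of()
    return dict(ranks)


def find_local_minima(net: nx.Graph, ranks: RankedList | Mapping[str, int]) -> set[str]:
    """Proteins ranked strictly better (smaller rank number) than every
    neighbour; these seed the expansions."""
    rank = _rank_map(ranks)
    missing = set(net.nodes) - set(rank)
    if missing:
        raise ValueError(f"ranking does not cover nodes {sorted(missing)[:5]}")
    return {
        node
        for node in net.nodes
        if all(rank[node] < rank[nb] for nb in net.neighbors(node))
    }


def giga_expand(
    net: nx.Graph,
    ranks: RankedList | Mapping[str, int],
    seed: str,
    max_size: int,
) -> SubNetwork:
    """Grow a sub-network from ``seed`` and return the most significant state.

    At each step the best-ranked boundary protein is added, then boundary
    proteins ranked better than it are absorbed (transitively); each such
    state is a maximal connected set whose worst member rank is the newly
    added protein's rank.  Expansion proceeds until the size cap, the states
    are scored with :func:`giga_significance` (``n`` = size, ``r_max`` =
    worst member rank, ``total`` = number of ranked proteins) and the
    minimal-p state is returned.  When absorption would overshoot the cap,
    the best-ranked absorbable proteins fill the remaining places.
    """
    rank = _rank_map(ranks)
    if max_size < 1:
        raise ConfigurationError(f"max_size must be >= 1, got {max_size}")
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    total = len(rank)

    def significance(members: set[str]) -> float:
        return giga_significance(
            len(members), max(rank[v] for v in members), total
        )

    members: set[str] = {seed}
    best_p = significance(members)
    best_members = frozenset(members)
    while len(members) < max_size:
        boundary = {nb for v in members for nb in net.neighbors(v)} - members
        if not boundary:
            break
        barrier = min(boundary, key=lambda v: (rank[v], v))
        members.add(barrier)
        # transitively absorb boundary proteins ranked better than the barrier
        while len(members) < max_size:
            absorbable = {
                nb
                for v in members
                for nb in net.neighbors(v)
                if nb not in members and rank[nb] < rank[barrier]
            }
            if not absorbable:
                break
            members.add(min(absorbable, key=lambda v: (rank[v], v)))
        p = significance(members)
        if p < best_p:
            best_p = p
            best_members = frozenset(members)
    return SubNetwork(members=best_members, score_p=best_p, seed=seed)


def extract_all(
    net: nx.Graph,
    ranked_lists: Sequence[RankedList],
    max_size: int,
) -> dict[int, list[SubNetwork]]:
    """Run seeded expansion from every local minimum of every ranked list."""
    out: dict[int, list[SubNetwork]] = {}
    for i, ranks in enumerate(ranked_lists):
        subs = [
            replace(
                giga_expand(net, ranks, seed, max_size),
                alpha=ranks.alpha, eta=ranks.eta, lambda_=ranks.lambda_,
            )
            for seed in sorted(find_local_minima(net, ranks))
        ]
        out[i] = subs
    return out


def consensus(
    per_run: Mapping[int, Sequence[SubNetwork]],
    net: nx.Graph,
    min_size: int = 5,
) -> list[ConsensusSubnetwork]:
    """Complete-co-occurrence consensus across all parameter runs.

    A protein is retained iff it appears in the union of extracted
    sub-networks of *every* run.  Consensus sub-networks are the connected
    components of the PPI subgraph induced on the retained proteins;
    components below ``min_size`` proteins are discarded.  Empirical
    p-values are not yet assigned.
    """
    if not per_run:
        raise ConfigurationError("no runs supplied to consensus")
    retained: set[str] | None = None
    for subs in per_run.values():
        union = set().union(*(s.members for s in subs)) if subs else set()
        retained = union if retained is None else retained & union
    if not retained:
        logger.warning("no protein co-occurs across all runs; consensus is empty")
        return []
    components = sorted(
        nx.connected_components(net.subgraph(retained)),
        key=lambda comp: (-len(comp), min(comp)),
    )
    kept = [
        ConsensusSubnetwork(members=frozenset(comp))
        for comp in components
        if len(comp) >= min_size
    ]
    logger.info(
        "consensus: %d proteins retained, %d components, %d of size >= %d",
        len(retained), len(components), len(kept), min_size,
    )
    return kept


def sample_random_subnetwork(
    net: nx.Graph,
    size: int,
    rng: np.random.Generator,
    _adjacency: Mapping[str, list[str]] | None = None,
) -> set[str]:
    """Uniform-start snowball sample of a connected ``size``-protein set.

    Growth repeatedly adds a uniformly random boundary protein; if the
    component around the start is exhausted early the sample restarts from a
    fresh uniformly random start.  Snowball growth is biased towards
    high-degree proteins relative to a uniform draw over all connected
    subgraphs; the same sampler is used for every null draw so the
    comparison is internally consistent.
    """
    nodes = sorted(net.nodes)
    if size > len(nodes):
        raise ValueError(f"sample size {size} exceeds network size {len(nodes)}")
    adj = _adjacency or {v: sorted(net.neighbors(v)) for v in nodes}
    for _ in range(10000):
        start = nodes[rng.integers(len(nodes))]
        members = {start}
        # boundary kept as a swap-pop list + membership set so each distinct
        # boundary node is picked with equal probability, deterministically
        boundary = list(adj[start])
        in_boundary = set(boundary)
        while boundary and len(members) < size:
            idx = int(rng.integers(len(boundary)))
            pick = boundary[idx]
            boundary[idx] = boundary[-1]
            boundary.pop()
            in_boundary.discard(pick)
            members.add(pick)
            for nb in adj[pick]:
                if nb not in members and nb not in in_boundary:
                    boundary.append(nb)
                    in_boundary.add(nb)
        if len(members) == size:
            return members
    raise ConfigurationError(
        f"could not sample a connected sub-network of size {size}; "
        "is any component large enough?"
    )


def empirical_pvalue(
    members: Iterable[str],
    scores: ExpressionScores,
    net: nx.Graph,
    config: SamplingConfig = SamplingConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[float, int, int]:
    """Exceedance probability of the sub-network's summed pi-value.

    Draws ``config.n_samples`` random connected sub-networks of the same
    size, counts how many have a summed pi-value at least as large as the
    observed one (``r``), and returns ``p = (r + 1) / n`` clamped to 1, so
    a sub-network beating all 10000 samples gets p = 1.0e-4.
    """
    members = set(members)
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    pi = {g: scores.pi(g) for g in net.nodes}
    observed = sum(pi[g] for g in members)
    adj = {v: sorted(net.neighbors(v)) for v in sorted(net.nodes)}
    r = 0
    for _ in range(config.n_samples):
        sample = sample_random_subnetwork(net, len(members), rng, _adjacency=adj)
        if sum(pi[g] for g in sample) >= observed:
            r += 1
    p = min((r + 1) / config.n_samples, 1.0)
    return p, r, config.n_samples


def fdr_filter(
    subnetworks: Sequence[ConsensusSubnetwork], level: float = 0.05
) -> list[ConsensusSubnetwork]:
    """Benjamini-Hochberg filter across the consensus empirical p-values.

    Returns the sub-networks that pass at ``level``; every input must
    already carry an empirical p-value.
    """
    if not subnetworks:
        return []
    pvals = []
    for sub in subnetworks:
        if sub.empirical_p is None:
            raise ConfigurationError("empirical p-values must be assigned before FDR")
        pvals.append(sub.empirical_p)
    reject, _, _, _ = multipletests(pvals, alpha=level, method="fdr_bh")
    annotated = [
        replace(sub, fdr_pass=bool(flag)) for sub, flag in zip(subnetworks, reject)
    ]
    return [sub for sub in annotated if sub.fdr_pass]
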