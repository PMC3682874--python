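"""Hierarchical clique clustering (icicle solutions) and the silhouette baseline.

Cliques are clustered agglomeratively on the co-membership similarity matrix,
Johnson-style: at each step the most similar pair of clusters merges, and all
merges tied at one height are applied simultaneously (chains of tied pairs
collapse into a single multi-way merge). One partition is emitted per distinct
merge height, finest (all singletons) first, coarsest (one cluster) last — the
rows of an icicle plot.

The silhouette baseline converts similarity to distance by max-shift and picks
the non-trivial partition maximizing the average silhouette coefficient (ASC);
it is the reference against which the semantic, label-driven solution
selection is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cliques import CoMembershipMatrix

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-9

Cluster = frozenset[int]
Partition = tuple[Cluster, ...]


def _sorted_partition(clusters: Sequence[Cluster]) -> Partition:
    return tuple(sorted(clusters, key=lambda c: sorted(c)))


@dataclass(frozen=True)
class MergeEvent:
    """One (possibly multi-way) merge: child clusters, parent, merge height."""

    children: tuple[Cluster, ...]
    parent: Cluster
    height: float
    row_index: int  # index of the solution this event produced


@dataclass
class SolutionSet:
    """Ordered clustering solutions, finest to coarsest, with merge heights."""

    solutions: list[Partition]
    heights: list[float | None]  # height at which each row formed; None for row 0
    merge_events: list[MergeEvent] = field(default_factory=list)

    @property
    def n_cliques(self) -> int:
        return sum(len(c) for c in self.solutions[0])

    def n_clusters(self, index: int) -> int:
        return len(self.solutions[index])


def _linkage_similarity(
    S: np.ndarray, a: Cluster, b: Cluster, index: dict[int, int], linkage: str
) -> float:
    vals = [S[index[i], index[j]] for i in a for j in b]
    if linkage == "average":
        return float(np.mean(vals))
    if linkage == "single":  # most similar pair
        return float(np.max(vals))
    if linkage == "complete":  # least similar pair
        return float(np.min(vals))
    raise ValueError(f"unknown linkage: {linkage}")


def cluster_cliques(S: CoMembershipMatrix, linkage: str = "average") -> SolutionSet:
    """Agglomerative clustering of cliques on co-membership similarity.

    Returns every distinct-height partition from all-singletons to one cluster.
    A single clique yields a degenerate one-row solution set with a warning.
    """
    ids = S.clique_ids
    index = {cid: i for i, cid in enumerate(ids)}
    clusters: list[Cluster] = [frozenset({cid}) for cid in ids]
    solutions = [_sorted_partition(clusters)]
    heights: list[float | None] = [None]
    events: list[MergeEvent] = []
    if len(ids) == 1:
        logger.warning("only one clique; clustering is degenerate")
        return SolutionSet(solutions=solutions, heights=heights)

    sim = S.matrix.astype(float)
    while len(clusters) > 1:
        pair_sims = {
            (i, j): _linkage_similarity(sim, clusters[i], clusters[j], index, linkage)
            for i in range(len(clusters))
            for j in range(i + 1, len(clusters))
        }
        top = max(pair_sims.values())
        tied = [pair for pair, s in pair_sims.items() if s >= top - _TIE_EPS]
        # union-find over tied pairs: chains of ties merge simultaneously
        parent = list(range(len(clusters)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in tied:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[Cluster]] = {}
        for i, c in enumerate(clusters):
            groups.setdefault(find(i), []).append(c)
        new_clusters: list[Cluster] = []
        row_index = len(solutions)
        for root in sorted(groups):
            members = groups[root]
            merged = frozenset().union(*members)
            new_clusters.append(merged)
            if len(members) > 1:
                events.append(
                    MergeEvent(
                        children=_sorted_partition(members),
                        parent=merged,
                        height=top,
                        row_index=row_index,
                    )
                )
        clusters = new_clusters
        solutions.append(_sorted_partition(clusters))
        heights.append(top)
    return SolutionSet(solutions=solutions, heights=heights, merge_events=events)


def similarity_to_distance(S: CoMembershipMatrix) -> np.ndarray:
    """Max-shift conversion: d[i][j] = max off-diagonal similarity - S[i][j]."""
    sim = S.matrix.astype(float)
    n = sim.shape[0]
    off = sim[~np.eye(n, dtype=bool)]
    shift = float(off.max()) if off.size else 0.0
    d = shift - sim
    np.fill_diagonal(d, 0.0)
    return d


def silhouette_of_partition(d: np.ndarray, partition: Partition, index: dict[int, int]) -> float:
    """Average silhouette coefficient of one partition under distance matrix d.

    Cliques in singleton clusters contribute 0 (Kaufman-Rousseeuw convention).
    """
    scores: list[float] = []
    for cluster in partition:
        others = [c for c in partition if c is not cluster]
        for cid in cluster:
            if len(cluster) == 1:
                scores.append(0.0)
                continue
            i = index[cid]
            a = float(np.mean([d[i, index[j]] for j in cluster if j != cid]))
            b = min(
                float(np.mean([d[i, index[j]] for j in other])) for other in others
            )
            denom = max(a, b)
            scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


@dataclass(frozen=True)
class BaselineResult:
    """The ASC-maximizing non-trivial partition and the per-solution ASC table."""

    index: int
    partition: Partition
    asc: float
    table: tuple[tuple[int, int, float], ...]  # (solution index, n_clusters, ASC)


def silhouette_baseline(S: CoMembershipMatrix, solutions: SolutionSet) -> BaselineResult:
    """Pick the solution with the highest ASC among non-trivial partitions.

    Non-trivial means 2 <= #clusters <= #cliques - 1. Ties go to the partition
    with fewer clusters (the more summary-like solution).
    """
    n = S.n
    if n < 3:
        raise ValueError("silhouette baseline requires at least 3 cliques")
    d = similarity_to_distance(S)
    index = {cid: i for i, cid in enumerate(S.clique_ids)}
    table = []
    for i, part in enumerate(solutions.solutions):
        k = len(part)
        if 2 <= k <= n - 1:
            table.append((i, k, silhouette_of_partition(d, part, index)))
    if not table:
        raise ValueError("no non-trivial clustering solution to evaluate")
    best = max(table, key=lambda row: (row[2], -row[1]))
    return BaselineResult(
        index=best[0],
        partition=solutions.solutions[best[0]],
        asc=best[2],
        table=tuple(table),
    )
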