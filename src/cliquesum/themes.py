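"""Theme labeling via metapredications and semantic solution selection.

Every distinct predication in a cluster is generalized to a metapredication — a
<semantic group> <predicate group> <semantic group> triple — by mapping its
predicate to a predicate group and its arguments' semantic types to semantic
groups. The most frequent metapredication labels the cluster. Labels then
drive two decisions: which icicle row is the optimal clustering solution
(advance from a starting row while consecutive rows only merge same-label
clusters), and, optionally, a dynamic cut that keeps walking the merge tree
and applies only the label-consistent merges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .cliques import Clique
from .clustering import Cluster, Partition, SolutionSet
from .graph_model import DistinctPredication, PredicationGraph, PredicationKey
from .predication_io import AllowedTriple, GroupConfig


class _Unlabeled:
    """Sentinel for clusters whose predications map to no allowed metapredication."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNLABELED"


UNLABELED = _Unlabeled()

Label = AllowedTriple | _Unlabeled


def assign_metapredication(
    pred: DistinctPredication,
    subject_semtypes: Sequence[str],
    object_semtypes: Sequence[str],
    config: GroupConfig,
) -> AllowedTriple | None:
    """Map a predication to its allowed metapredication, or None if unmapped.

    The predicate maps to its predicate group and each argument's semantic
    types map to semantic groups; when an argument has several types, the
    first (in the stored order) that yields an allowed triple wins. Unknown
    predicates or types, or triples outside the allowed list, give None.
    """
    pgroup = config.predicate_to_pgroup.get(pred.predicate)
    if pgroup is None:
        return None
    for st in subject_semtypes:
        sgroup = config.semtype_to_group.get(st)
        if sgroup is None:
            continue
        for ot in object_semtypes:
            ogroup = config.semtype_to_group.get(ot)
            if ogroup is None:
                continue
            triple = config.lookup_triple(sgroup, pgroup, ogroup)
            if triple is not None:
                return triple
    return None


@dataclass(frozen=True)
class ClusterLabel:
    """A cluster of cliques with its predications, metapredication counts and label."""

    cluster: Cluster
    predications: dict[PredicationKey, DistinctPredication]
    assignments: dict[PredicationKey, AllowedTriple | None]
    counts: dict[AllowedTriple, int]
    label: Label

    @property
    def display_name(self) -> str | None:
        return None if self.label is UNLABELED else self.label.display_name


def cluster_predications(
    cluster: Cluster,
    cliques_by_id: Mapping[int, Clique],
    graph: PredicationGraph,
) -> dict[PredicationKey, DistinctPredication]:
    """Predications belonging to a cluster: both arguments inside some member clique."""
    out: dict[PredicationKey, DistinctPredication] = {}
    members = [cliques_by_id[cid].members for cid in cluster]
    for p in graph.predications():
        for m in members:
            if p.subject_id in m and p.object_id in m:
                out[p.key] = p
                break
    return out


def label_cluster(
    cluster: Cluster,
    cliques_by_id: Mapping[int, Clique],
    graph: PredicationGraph,
    config: GroupConfig,
) -> ClusterLabel:
    """Label a cluster with its most frequent metapredication.

    Counting is over distinct predications; unmapped predications stay in the
    predication set but do not vote. Ties break by higher summed citation
    frequency, then by the configured metapredication order. A cluster whose
    predications are all unmapped is UNLABELED.
    """
    if not cluster:
        raise ValueError("cluster must be non-empty")
    preds = cluster_predications(cluster, cliques_by_id, graph)
    assignments = {
        key: assign_metapredication(
            p, graph.node_semtypes(p.subject_id), graph.node_semtypes(p.object_id), config
        )
        for key, p in preds.items()
    }
    counts: Counter[AllowedTriple] = Counter(
        a for a in assignments.values() if a is not None
    )
    if not counts:
        return ClusterLabel(cluster, preds, assignments, {}, UNLABELED)
    freq_sum = {
        triple: sum(
            preds[k].frequency for k, a in assignments.items() if a == triple
        )
        for triple in counts
    }
    label = max(
        counts,
        key=lambda t: (counts[t], freq_sum[t], -config.triple_order(t)),
    )
    return ClusterLabel(cluster, preds, assignments, dict(counts), label)


def make_labeler(
    cliques: Sequence[Clique], graph: PredicationGraph, config: GroupConfig
) -> Callable[[Cluster], ClusterLabel]:
    """A caching cluster labeler bound to a clique set, graph and config."""
    by_id = {c.id: c for c in cliques}
    cache: dict[Cluster, ClusterLabel] = {}

    def labeler(cluster: Cluster) -> ClusterLabel:
        if cluster not in cache:
            cache[cluster] = label_cluster(cluster, by_id, graph, config)
        return cache[cluster]

    return labeler


def _merge_groups(current: Partition, nxt: Partition) -> list[tuple[Cluster, ...]]:
    """Groups of current-row clusters that coalesce into one next-row cluster."""
    groups: dict[Cluster, list[Cluster]] = {}
    for c in current:
        target = next(t for t in nxt if c <= t)
        groups.setdefault(target, []).append(c)
    return [tuple(v) for v in groups.values() if len(v) > 1]


def _labels_consistent(group: Sequence[Cluster], label_of: Callable[[Cluster], Label]) -> bool:
    labels = [label_of(c) for c in group]
    return UNLABELED not in labels and len(set(labels)) == 1


def select_solution(
    solution_set: SolutionSet,
    label_of: Callable[[Cluster], Label],
    max_singletons: int = 3,
    mode: str = "conservative",
) -> int:
    """Index of the optimal clustering solution.

    Scanning finest to coarsest (skipping the all-singleton row), the starting
    row is the first with at most ``max_singletons`` singleton clusters (the
    coarsest row if none qualifies). From there the next row is adopted while
    merge events between consecutive rows are label-consistent: in
    ``conservative`` mode every event must merge clusters sharing one
    non-UNLABELED label; in ``permissive`` mode one such event suffices.
    """
    if mode not in ("conservative", "permissive"):
        raise ValueError(f"unknown mode: {mode}")
    sols = solution_set.solutions
    if len(sols) == 1:
        return 0
    start = None
    for i, part in enumerate(sols):
        if all(len(c) == 1 for c in part):
            continue  # the all-singleton partition is not a candidate row
        if sum(1 for c in part if len(c) == 1) <= max_singletons:
            start = i
            break
    if start is None:
        start = len(sols) - 1
    i = start
    while i + 1 < len(sols):
        groups = _merge_groups(sols[i], sols[i + 1])
        consistent = [_labels_consistent(g, label_of) for g in groups]
        advance = all(consistent) if mode == "conservative" else any(consistent)
        if not advance:
            break
        i += 1
    return i


def dynamic_merge(
    solution_set: SolutionSet,
    selected_index: int,
    label_of: Callable[[Cluster], Label],
) -> Partition:
    """Dynamic-threshold variant: different cut heights on different branches.

    Starting from the selected partition, the remaining merge events of the
    tree are walked in merge order. An event is applied only when every
    current cluster it would merge carries the same non-UNLABELED label;
    otherwise it is skipped (without stopping). Labels of merged clusters are
    recomputed as merging proceeds. The result need not equal any icicle row.
    """
    current: list[Cluster] = list(solution_set.solutions[selected_index])
    for event in solution_set.merge_events:
        if event.row_index <= selected_index:
            continue
        participants = [c for c in current if c & event.parent]
        if len(participants) < 2:
            continue
        if _labels_consistent(participants, label_of):
            merged = frozenset().union(*participants)
            current = [c for c in current if c not in participants] + [merged]
    return tuple(sorted(current, key=lambda c: sorted(c)))
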