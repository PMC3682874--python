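"""Predication graph construction, citation-level frequency, degree centrality.

Concepts are nodes; each unordered concept pair carries one arc holding every
distinct (subject, predicate, object) predication asserted between the two
concepts, in either direction. Directionality (subject to object) is retained
as metadata on each predication, but centrality and cliques operate on the
undirected simple view: a pair contributes one arc no matter how many
predicates or directions connect it.

Frequency of a distinct predication is the number of distinct citations it
occurs in; repeated occurrences within one sentence or one citation count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .predication_io import PredicationRecord

PredicationKey = tuple[str, str, str]


@dataclass(frozen=True)
class DistinctPredication:
    """A distinct (subject, predicate, object) with its supporting citations."""

    subject_id: str
    predicate: str
    object_id: str
    citation_ids: frozenset[str]

    @property
    def key(self) -> PredicationKey:
        return (self.subject_id, self.predicate, self.object_id)

    @property
    def frequency(self) -> int:
        return len(self.citation_ids)


class PredicationGraph:
    """Concept nodes with multi-labeled arcs and per-predication frequencies."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------------

    def add_concept(self, concept_id: str, name: str, semtypes: Iterable[str]) -> None:
        data = self._g.nodes.get(concept_id)
        if data is None:
            self._g.add_node(
                concept_id, name=name, semtypes=tuple(sorted(set(semtypes)))
            )
        else:
            # keep the lexicographically smallest name and the union of types,
            # so construction is invariant to record order
            data["name"] = min(data["name"], name)
            data["semtypes"] = tuple(sorted(set(data["semtypes"]) | set(semtypes)))

    def add_predication(self, pred: DistinctPredication) -> None:
        u, v = pred.subject_id, pred.object_id
        if u == v:
            raise ValueError(f"self-predication not allowed: {pred.key}")
        if u not in self._g or v not in self._g:
            raise KeyError("both endpoints must be added as concepts first")
        if not self._g.has_edge(u, v):
            self._g.add_edge(u, v, predications={})
        self._g.edges[u, v]["predications"][pred.key] = pred

    # -- queries ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self._g.number_of_edges()

    @property
    def n_predications(self) -> int:
        return sum(len(d["predications"]) for _, _, d in self._g.edges(data=True))

    def node_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    def has_node(self, concept_id: str) -> bool:
        return concept_id in self._g

    def node_name(self, concept_id: str) -> str:
        return self._g.nodes[concept_id]["name"]

    def node_semtypes(self, concept_id: str) -> tuple[str, ...]:
        return self._g.nodes[concept_id]["semtypes"]

    def arcs(self) -> Iterator[tuple[str, str, list[DistinctPredication]]]:
        for u, v, d in self._g.edges(data=True):
            yield u, v, list(d["predications"].values())

    def predications(self) -> Iterator[DistinctPredication]:
        for _, _, d in self._g.edges(data=True):
            yield from d["predications"].values()

    def predication_map(self) -> dict[PredicationKey, DistinctPredication]:
        return {p.key: p for p in self.predications()}

    def to_networkx(self) -> nx.Graph:
        """The undirected simple view (shared, do not mutate)."""
        return self._g

    # -- derivation ---------------------------------------------------------

    def keep_predications(self, keys: set[PredicationKey]) -> "PredicationGraph":
        """Subgraph retaining only the given predications.

        Arcs left without predications and nodes left without arcs are dropped.
        """
        out = PredicationGraph()
        for p in self.predications():
            if p.key in keys:
                for cid in (p.subject_id, p.object_id):
                    out.add_concept(cid, self.node_name(cid), self.node_semtypes(cid))
                out.add_predication(p)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredicationGraph):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        for n in self._g.nodes:
            if self.node_name(n) != other.node_name(n):
                return False
            if self.node_semtypes(n) != other.node_semtypes(n):
                return False
        return self.predication_map() == other.predication_map()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<PredicationGraph nodes={self.n_nodes} arcs={self.n_arcs} "
            f"predications={self.n_predications}>"
        )


def count_frequency(records: Sequence[PredicationRecord]) -> int:
    """Citation-level frequency of one distinct predication.

    All records must share the same (subject, predicate, object). Multiple
    occurrences in one sentence or one citation count once.
    """
    if not records:
        raise ValueError("no records given")
    keys = {r.key for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple distinct predications: {sorted(keys)}")
    return len({r.citation_id for r in records})


def build_graph(records: Sequence[PredicationRecord]) -> PredicationGraph:
    """Build the predication graph from occurrence records.

    One node per distinct concept; one arc per unordered concept pair holding
    every distinct predication between the pair, each with its citation set.
    The result is invariant to record order.
    """
    if not records:
        raise ValueError("cannot build a graph from an empty record list")
    graph = PredicationGraph()
    citations: dict[PredicationKey, set[str]] = {}
    for r in records:
        if r.subject_id == r.object_id:
            continue  # self-predications are rejected upstream; be defensive
        graph.add_concept(r.subject_id, r.subject_name, (r.subject_semtype,))
        graph.add_concept(r.object_id, r.object_name, (r.object_semtype,))
        citations.setdefault(r.key, set()).add(r.citation_id)
    for (s, p, o), cits in citations.items():
        graph.add_predication(
            DistinctPredication(s, p, o, citation_ids=frozenset(cits))
        )
    return graph


def degree_centrality(graph: PredicationGraph) -> dict[str, float]:
    """Freeman degree centrality: incident arcs / (n - 1), in [0, 1].

    Arcs are counted once per concept pair regardless of how many predicates
    or directions connect the pair.
    """
    if graph.n_nodes < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    return dict(nx.degree_centrality(graph.to_networkx()))
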