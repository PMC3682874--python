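"""Maximal-clique enumeration and the clique co-membership matrix.

A maximal clique is a complete subgraph not contained in any other. Cliques may
overlap: high-centrality concepts at the core of the summary typically appear
in several cliques, and the co-membership matrix (shared-node counts between
cliques, clique sizes on the diagonal) is what the theme clustering operates
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_model import PredicationGraph


@dataclass(frozen=True)
class Clique:
    """A maximal clique: 1-based id and its member concept ids."""

    id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def find_maximal_cliques(
    graph: PredicationGraph, min_clique_size: int = 3
) -> list[Clique]:
    """All maximal cliques of size >= ``min_clique_size``.

    Enumeration is Bron-Kerbosch with pivoting on the undirected simple view.
    Output order is deterministic (descending size, then lexicographic member
    list) and ids are assigned 1..k in that order.
    """
    if min_clique_size < 1:
        raise ValueError("min_clique_size must be >= 1")
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        return []
    raw = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= min_clique_size]
    raw.sort(key=lambda m: (-len(m), m))
    return [Clique(id=i + 1, members=frozenset(m)) for i, m in enumerate(raw)]


@dataclass(frozen=True)
class CoMembershipMatrix:
    """Symmetric shared-node counts between cliques; diagonal = clique sizes."""

    clique_ids: tuple[int, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.clique_ids), len(self.clique_ids)):
            raise ValueError("matrix shape does not match clique ids")
        if not np.array_equal(m, m.T):
            raise ValueError("co-membership matrix must be symmetric")

    def index_of(self, clique_id: int) -> int:
        return self.clique_ids.index(clique_id)

    @property
    def n(self) -> int:
        return len(self.clique_ids)

    def shared(self, a: int, b: int) -> int:
        return int(self.matrix[self.index_of(a), self.index_of(b)])


def co_membership(cliques: Sequence[Clique]) -> CoMembershipMatrix:
    """Pairwise shared-node counts; S[i][i] is the size of clique i."""
    if not cliques:
        raise ValueError("no cliques given")
    n = len(cliques)
    m = np.zeros((n, n), dtype=int)
    for i, ci in enumerate(cliques):
        m[i, i] = ci.size
        for j in range(i + 1, n):
            shared = len(ci.members & cliques[j].members)
            m[i, j] = m[j, i] = shared
    return CoMembershipMatrix(
        clique_ids=tuple(c.id for c in cliques), matrix=m
    )
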