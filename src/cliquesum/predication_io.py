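"""Reading and writing of predication corpora, group configuration and graph exports.

A predication corpus is a 9-column tab-separated file modeled on the SemMedDB
``PREDICATION`` table: one row per extracted predication occurrence, carrying the
citation and sentence it came from, the normalized subject and object concepts
(identifier, preferred name, semantic-type code) and the uppercase predicate.

The group configuration bundles the controlled vocabularies used for theme
labeling: semantic-type to semantic-group aggregation, predicate groups, the
allowed metapredication triples, and the generic-concept list used by the
novelty filter. A default configuration ships with the package.
"""

from __future__ import annotations

import csv
import functools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import yaml

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .graph_model import PredicationGraph

REQUIRED_COLUMNS: tuple[str, ...] = (
    "citation_id",
    "sentence_id",
    "subject_id",
    "subject_name",
    "subject_semtype",
    "predicate",
    "object_id",
    "object_name",
    "object_semtype",
)


@dataclass(frozen=True)
class PredicationRecord:
    """One predication occurrence extracted from one sentence of one citation."""

    citation_id: str
    sentence_id: str
    subject_id: str
    subject_name: str
    subject_semtype: str
    predicate: str
    object_id: str
    object_name: str
    object_semtype: str

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity of the distinct predication this occurrence instantiates."""
        return (self.subject_id, self.predicate, self.object_id)


@dataclass
class ReadResult:
    """Records read from a corpus plus counters for rejected rows."""

    records: list[PredicationRecord]
    n_malformed: int = 0
    n_self_loops: int = 0
    n_unknown_predicate: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_predications(path: str | Path, vocabulary: set[str] | None = None) -> ReadResult:
    """Read a 9-column TSV predication corpus.

    Rows with empty required fields are counted as malformed and skipped.
    Self-predications (subject == object) are rejected with a warning count,
    since downstream centrality and cliques are defined on simple graphs.
    Duplicate occurrence rows are retained; deduplication to distinct
    predications happens at graph-building time via the citation-frequency
    rule. Records whose predicate is outside ``vocabulary`` (when given) are
    kept but counted as unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"predication file not found: {path}")
    result = ReadResult(records=[])
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"empty predication file: {path}")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"missing required columns {missing} in {path}")
        for row in reader:
            values = {c: (row.get(c) or "").strip() for c in REQUIRED_COLUMNS}
            if any(not values[c] for c in REQUIRED_COLUMNS):
                result.n_malformed += 1
                continue
            if values["subject_id"] == values["object_id"]:
                result.n_self_loops += 1
                continue
            values["predicate"] = values["predicate"].upper()
            if vocabulary is not None and values["predicate"] not in vocabulary:
                result.n_unknown_predicate += 1
            result.records.append(PredicationRecord(**values))
    if not result.records and not (result.n_malformed or result.n_self_loops):
        raise ValueError(f"predication file has no data rows: {path}")
    return result


def write_predications(records: Iterable[PredicationRecord], path: str | Path) -> None:
    """Write records back to the 9-column TSV format (inverse of read)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow([getattr(r, c) for c in REQUIRED_COLUMNS])


class AllowedTriple(NamedTuple):
    """An allowed metapredication: a semantic-group / predicate-group / semantic-group
    triple with the display name of the family it belongs to (e.g. "Drug treatment")."""

    subject_group: str
    predicate_group: str
    object_group: str
    display_name: str

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_group, self.predicate_group, self.object_group)


@dataclass(frozen=True)
class GroupConfig:
    """Vocabularies for condensation and theme labeling.

    ``allowed_metapredications`` preserves file order, which doubles as the
    canonical tie-break order when two metapredications label a cluster with
    the same support.
    """

    semtype_to_group: dict[str, str]
    predicate_to_pgroup: dict[str, str]
    allowed_metapredications: tuple[AllowedTriple, ...]
    generic_concepts: frozenset[str]
    hierarchy: frozenset[tuple[str, str]] | None = None
    generic_depth: int | None = None
    _triple_index: dict[tuple[str, str, str], AllowedTriple] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        object.__setattr__(
            self,
            "_triple_index",
            {t.triple: t for t in self.allowed_metapredications},
        )

    @property
    def predicate_vocabulary(self) -> frozenset[str]:
        return frozenset(self.predicate_to_pgroup)

    @property
    def semantic_groups(self) -> frozenset[str]:
        return frozenset(self.semtype_to_group.values())

    @property
    def predicate_groups(self) -> frozenset[str]:
        return frozenset(self.predicate_to_pgroup.values())

    @property
    def metapredication_families(self) -> tuple[str, ...]:
        """Display names in file order, deduplicated."""
        seen: dict[str, None] = {}
        for t in self.allowed_metapredications:
            seen.setdefault(t.display_name, None)
        return tuple(seen)

    def lookup_triple(self, subject_group: str, predicate_group: str, object_group: str):
        return self._triple_index.get((subject_group, predicate_group, object_group))

    def triple_order(self, triple: AllowedTriple) -> int:
        return self.allowed_metapredications.index(triple)


def _parse_group_config(doc: dict, source: str) -> GroupConfig:
    for key in ("semantic_types", "predicate_groups", "metapredications", "generic_concepts"):
        if key not in doc:
            raise ValueError(f"group config {source} is missing the '{key}' table")
    semtype_to_group = {str(k): str(v) for k, v in doc["semantic_types"].items()}
    declared_groups = set(semtype_to_group.values())
    predicate_to_pgroup: dict[str, str] = {}
    for pgroup, preds in doc["predicate_groups"].items():
        for p in preds:
            predicate_to_pgroup[str(p).upper()] = str(pgroup)
    declared_pgroups = set(predicate_to_pgroup.values())
    triples: list[AllowedTriple] = []
    for family in doc["metapredications"]:
        name = str(family["display_name"])
        for s, p, o in family["triples"]:
            t = AllowedTriple(str(s), str(p), str(o), name)
            if t.triple in {x.triple for x in triples}:
                raise ValueError(f"duplicate metapredication triple {t.triple} in {source}")
            if t.subject_group not in declared_groups or t.object_group not in declared_groups:
                raise ValueError(
                    f"metapredication {t.triple} references an undeclared semantic group"
                )
            if t.predicate_group not in declared_pgroups:
                raise ValueError(
                    f"metapredication {t.triple} references an undeclared predicate group"
                )
            triples.append(t)
    hierarchy = None
    if doc.get("hierarchy"):
        hierarchy = frozenset((str(c), str(p)) for c, p in doc["hierarchy"])
    generic_depth = doc.get("generic_depth")
    return GroupConfig(
        semtype_to_group=semtype_to_group,
        predicate_to_pgroup=predicate_to_pgroup,
        allowed_metapredications=tuple(triples),
        generic_concepts=frozenset(str(c) for c in doc["generic_concepts"] or []),
        hierarchy=hierarchy,
        generic_depth=int(generic_depth) if generic_depth is not None else None,
    )


def read_group_config(path: str | Path | None = None) -> GroupConfig:
    """Read a YAML/JSON group configuration; ``None`` loads the bundled default."""
    if path is None:
        return default_group_config()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"group config not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    return _parse_group_config(doc, str(path))


@functools.lru_cache(maxsize=1)
def default_group_config() -> GroupConfig:
    """The bundled default: 7 predicate groups and 8 metapredication families."""
    text = resources.files("cliquesum.data").joinpath("default_groups.yaml").read_text("utf-8")
    return _parse_group_config(yaml.safe_load(text), "bundled default")


def _ordered_nodes(graph: "PredicationGraph") -> list[str]:
    """Deterministic node order: lexicographic by concept name, id as tie-break."""
    return sorted(graph.node_ids(), key=lambda n: (graph.node_name(n), n))


def write_pajek(graph: "PredicationGraph", path: str | Path) -> None:
    """Write the graph in the Pajek ``.net`` dialect.

    One vertex line per concept (1-based ids, quoted labels) and one edge line
    per arc; multiple predications between a pair collapse to a single edge
    whose weight is the summed citation frequency.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot export an empty graph")
    nodes = _ordered_nodes(graph)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    for n in nodes:
        label = graph.node_name(n).replace('"', "'")
        lines.append(f'{index[n]} "{label}"')
    lines.append("*Edges")
    edges = []
    for u, v, preds in graph.arcs():
        i, j = sorted((index[u], index[v]))
        weight = sum(p.frequency for p in preds)
        edges.append((i, j, weight))
    for i, j, w in sorted(edges):
        lines.append(f"{i} {j} {w}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(graph: "PredicationGraph", path: str | Path) -> None:
    """Write the graph as GraphML (same collapsed-edge view as the Pajek writer)."""
    import networkx as nx

    if graph.n_nodes == 0:
        raise ValueError("cannot export an empty graph")
    g = nx.Graph()
    for n in _ordered_nodes(graph):
        g.add_node(n, name=graph.node_name(n), semtypes=";".join(graph.node_semtypes(n)))
    for u, v, preds in graph.arcs():
        g.add_edge(
            u,
            v,
            weight=sum(p.frequency for p in preds),
            predicates=";".join(sorted(p.predicate for p in preds)),
        )
    nx.write_graphml(g, str(path))


def read_pajek_vertex_count(path: str | Path) -> int:
    """Parse the vertex count back out of a Pajek file (round-trip checks)."""
    first = Path(path).read_text(encoding="utf-8").splitlines()[0]
    if not first.lower().startswith("*vertices"):
        raise ValueError(f"not a Pajek file: {path}")
    return int(first.split()[1])


def write_json(document: dict, path: str | Path) -> None:
    """Write a JSON document deterministically (sorted keys, stable separators)."""
    Path(path).write_text(
        json.dumps(document, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
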