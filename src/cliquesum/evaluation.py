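"""Cluster validity (cohesion, separation, overall) and MeSH-based label quality.

For a cluster labeled with metapredication L: x is the number of its
predications matching L, y the number not matching, and z the number of
distinct predications in *other* clusters matching L. Then

    cohesion   = x / (x + y)
    separation = x / (x + z)
    overall    = 2 * cohesion * separation / (cohesion + separation)

Corpus-level scores are reported both micro (x, y, z pooled over clusters,
the headline) and macro (mean of per-cluster scores).

The MeSH comparison scores the labeling against human indexing: per cluster,
the major MeSH descriptors of contributing citations are ranked by citation
count and the top k (k = number of cluster concepts) serve as the reference;
concepts are matched to descriptors by name or via a synonym table, and
recall/precision/F are pooled over clusters.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

from .cliques import Clique
from .graph_model import PredicationGraph
from .themes import UNLABELED, ClusterLabel

# -- validity ----------------------------------------------------------------


@dataclass(frozen=True)
class ValidityCounts:
    x: int  # in-cluster predications matching the cluster label
    y: int  # in-cluster predications not matching
    z: int  # matching predications in other clusters


@dataclass(frozen=True)
class ValidityScores:
    cohesion: float | None
    separation: float | None
    overall: float | None


def scores_from_counts(counts: ValidityCounts) -> ValidityScores:
    """Direct evaluation of the cohesion/separation/overall formulas."""
    x, y, z = counts.x, counts.y, counts.z
    cohesion = x / (x + y) if (x + y) > 0 else None
    separation = x / (x + z) if (x + z) > 0 else None
    if cohesion is None or separation is None:
        overall = None
    elif cohesion + separation == 0:
        overall = 0.0
    else:
        overall = 2 * cohesion * separation / (cohesion + separation)
    return ValidityScores(cohesion, separation, overall)


@dataclass
class ValidityReport:
    per_cluster: list[tuple[ValidityCounts, ValidityScores]]
    micro_counts: ValidityCounts
    micro: ValidityScores
    macro: ValidityScores
    excluded_unlabeled: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        def s(v: ValidityScores) -> dict:
            return {"cohesion": v.cohesion, "separation": v.separation, "overall": v.overall}

        return {
            "per_cluster": [
                {"x": c.x, "y": c.y, "z": c.z, **s(v)} for c, v in self.per_cluster
            ],
            "micro": s(self.micro),
            "macro": s(self.macro),
            "excluded_unlabeled": list(self.excluded_unlabeled),
        }


def validity_from_assignments(
    clusters: Sequence[tuple[Hashable, Mapping[Hashable, Hashable | None]]],
) -> ValidityReport:
    """Validity over (label, {predication key -> assigned metapredication}) pairs.

    ``None`` labels mark unlabeled clusters: they are excluded from scoring
    (and from z counting) and reported. z counts each distinct predication
    once, however many other clusters contain it; predications present in
    cluster i itself are never counted into its own z.
    """
    labeled = [
        (i, label, dict(assign))
        for i, (label, assign) in enumerate(clusters)
        if label is not None
    ]
    excluded = [i for i, (label, _) in enumerate(clusters) if label is None]
    per_cluster: list[tuple[ValidityCounts, ValidityScores]] = []
    xs = ys = zs = 0
    for i, label, assign in labeled:
        x = sum(1 for a in assign.values() if a == label)
        y = len(assign) - x
        own_keys = set(assign)
        z_keys = {
            key
            for j, _, other in labeled
            if j != i
            for key, a in other.items()
            if a == label and key not in own_keys
        }
        z = len(z_keys)
        counts = ValidityCounts(x, y, z)
        per_cluster.append((counts, scores_from_counts(counts)))
        xs, ys, zs = xs + x, ys + y, zs + z
    micro_counts = ValidityCounts(xs, ys, zs)

    def mean(vals: list[float]) -> float | None:
        return sum(vals) / len(vals) if vals else None

    macro = ValidityScores(
        cohesion=mean([v.cohesion for _, v in per_cluster if v.cohesion is not None]),
        separation=mean([v.separation for _, v in per_cluster if v.separation is not None]),
        overall=mean([v.overall for _, v in per_cluster if v.overall is not None]),
    )
    return ValidityReport(
        per_cluster=per_cluster,
        micro_counts=micro_counts,
        micro=scores_from_counts(micro_counts),
        macro=macro,
        excluded_unlabeled=excluded,
    )


def validity(cluster_labels: Sequence[ClusterLabel]) -> ValidityReport:
    """Validity of labeled clusters (UNLABELED clusters excluded and reported)."""
    return validity_from_assignments(
        [
            (
                None if cl.label is UNLABELED else cl.label,
                cl.assignments,
            )
            for cl in cluster_labels
        ]
    )


def compare_to_baseline(system: ValidityReport, baseline: ValidityReport) -> dict:
    """Per-metric system-minus-baseline deltas, micro and macro."""

    def delta(a: float | None, b: float | None) -> float | None:
        return None if a is None or b is None else a - b

    out = {}
    for level in ("micro", "macro"):
        s, b = getattr(system, level), getattr(baseline, level)
        out[level] = {
            "cohesion": delta(s.cohesion, b.cohesion),
            "separation": delta(s.separation, b.separation),
            "overall": delta(s.overall, b.overall),
        }
    return out


# -- MeSH comparison ---------------------------------------------------------


def _strip_qualifier(descriptor: str) -> str:
    return descriptor.split("/", 1)[0].strip()


def read_mesh_table(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (citation id, major descriptor); qualifiers after '/' stripped."""
    table: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 2 or not row[0].strip():
                continue
            table.setdefault(row[0].strip(), set()).add(_strip_qualifier(row[1]))
    return table


def read_synonym_table(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (concept id, descriptor string the concept is a synonym of)."""
    table: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 2 or not row[0].strip():
                continue
            table.setdefault(row[0].strip(), set()).add(row[1].strip())
    return table


@dataclass
class ClusterMeshDetail:
    concepts: list[str]  # concept ids
    reference_descriptors: list[str]  # top-k ranked descriptors
    matched: list[tuple[str, str]]  # (concept id, descriptor)
    n_skipped_citations: int


@dataclass
class MeshEvalResult:
    recall: float | None
    precision: float | None
    f_score: float | None
    per_cluster: list[ClusterMeshDetail]
    n_skipped_citations: int


def mesh_evaluate(
    cluster_labels: Sequence[ClusterLabel],
    cliques_by_id: Mapping[int, Clique],
    graph: PredicationGraph,
    citation_mesh: Mapping[str, set[str]],
    synonyms: Mapping[str, set[str]] | None = None,
) -> MeshEvalResult:
    """Compare cluster concepts to ranked major MeSH descriptors.

    Per cluster: descriptors of citations contributing predications, ranked by
    citation count (ties lexicographic), truncated to k = number of distinct
    cluster concepts. Concepts match descriptors by case-insensitive name
    equality or through the synonym table; matching is one-to-one, greedy in
    descriptor rank order. Recall pools matches over reference descriptors
    taken; precision pools matches over cluster concepts.
    """
    synonyms = synonyms or {}
    details: list[ClusterMeshDetail] = []
    matched_sum = ref_sum = concept_sum = 0
    skipped_total = 0
    for cl in cluster_labels:
        concepts = sorted({m for cid in cl.cluster for m in cliques_by_id[cid].members})
        citations = {c for p in cl.predications.values() for c in p.citation_ids}
        known = {c for c in citations if c in citation_mesh}
        skipped = len(citations) - len(known)
        desc_counts: Counter[str] = Counter()
        for c in known:
            for d in citation_mesh[c]:
                desc_counts[_strip_qualifier(d)] += 1
        ranked = sorted(desc_counts, key=lambda d: (-desc_counts[d], d))
        reference = ranked[: len(concepts)]
        # greedy one-to-one matching in descriptor rank order
        matched: list[tuple[str, str]] = []
        free = list(concepts)
        for desc in reference:
            hit = None
            for concept in free:
                name = graph.node_name(concept) if graph.has_node(concept) else concept
                if desc.casefold() == name.casefold() or any(
                    desc.casefold() == s.casefold() for s in synonyms.get(concept, ())
                ):
                    hit = concept
                    break
            if hit is not None:
                free.remove(hit)
                matched.append((hit, desc))
        details.append(
            ClusterMeshDetail(
                concepts=concepts,
                reference_descriptors=reference,
                matched=matched,
                n_skipped_citations=skipped,
            )
        )
        matched_sum += len(matched)
        ref_sum += len(reference)
        concept_sum += len(concepts)
        skipped_total += skipped
    recall = matched_sum / ref_sum if ref_sum else None
    precision = matched_sum / concept_sum if concept_sum else None
    if recall is None or precision is None or recall + precision == 0:
        f_score = None if recall is None or precision is None else 0.0
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return MeshEvalResult(
        recall=recall,
        precision=precision,
        f_score=f_score,
        per_cluster=details,
        n_skipped_citations=skipped_total,
    )
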