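"""Seeded synthetic predication corpora with planted themes.

The generator emulates the structure the summarization pipeline assumes in a
real corpus: a few semantically coherent themes whose predications are
frequent and highly interconnected, over a background of sparse, low-frequency
noise, part of it carried by generic arguments.

Each planted theme is a ring of overlapping cliques: its m concepts sit on a
cycle and every pair within a sliding window of ``clique_window`` consecutive
concepts is connected (a circulant graph). At density 1.0 this yields one
maximal clique per window position, all of one theme overlapping heavily and
degree-regular — so a clean corpus passes the centrality cutoff intact, and
the theme forms a multi-clique cluster the solution selection can recover.
Every pair in a theme uses the theme's predicate and semantic type, so all of
its predications map to one metapredication family.

This module is a test harness: real SemRep output has skewed degree and
frequency distributions, word-sense errors and mixed-type themes that the
generator does not attempt to model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cliques import Clique
from .graph_model import PredicationKey
from .predication_io import GroupConfig, PredicationRecord, default_group_config
from .themes import UNLABELED, ClusterLabel


@dataclass(frozen=True)
class ThemeSpec:
    """Semantic shape of one planted theme."""

    display_name: str  # expected metapredication family label
    predicate: str
    semtype: str
    concept_prefix: str


DEFAULT_THEME_SPECS: tuple[ThemeSpec, ...] = (
    ThemeSpec("Substance interaction", "INTERACTS_WITH", "phsu", "Substance"),
    ThemeSpec("Disease comorbidities", "COEXISTS_WITH", "dsyn", "Disorder"),
    ThemeSpec("Body location", "PART_OF", "bpoc", "Body part"),
    ThemeSpec("Etiology", "CAUSES", "dsyn", "Pathology"),
    ThemeSpec("Affect", "AFFECTS", "dsyn", "Condition"),
)

# generic concepts from the bundled default config, with names and types the
# generator can emit
GENERIC_CONCEPT_DETAILS: tuple[tuple[str, str, str], ...] = (
    ("C0030705", "Patients", "podg"),
    ("C0013227", "Pharmaceutical Preparations", "phsu"),
    ("C0012634", "Disease", "dsyn"),
    ("C0087111", "Therapeutic procedure", "topp"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus. ``seed`` is mandatory."""

    seed: int
    n_themes: int = 2
    concepts_per_theme: int = 7
    clique_window: int = 3
    intra_theme_density: float = 1.0
    bridge_concepts: int = 0
    citation_mean: float = 8.0
    citation_dispersion: float = 0.0
    noise_predications: int = 0
    noise_citation_mean: float = 1.5
    generic_noise_fraction: float = 0.3
    theme_specs: tuple[ThemeSpec, ...] | None = None

    def __post_init__(self):
        if not (0.0 <= self.intra_theme_density <= 1.0):
            raise ValueError("intra_theme_density must be in [0, 1]")
        if not (0.0 <= self.generic_noise_fraction <= 1.0):
            raise ValueError("generic_noise_fraction must be in [0, 1]")
        if self.intra_theme_density == 0.0:
            raise ValueError(
                "infeasible config: density 0 cannot produce cliques of size >= 3"
            )
        if self.n_themes < 1:
            raise ValueError("n_themes must be >= 1")
        if self.concepts_per_theme < self.clique_window:
            raise ValueError("concepts_per_theme must be >= clique_window")
        if self.clique_window < 3:
            raise ValueError("clique_window must be >= 3")

    @property
    def planted_predications_per_theme(self) -> int:
        """Number of circulant pairs per theme (at density 1.0)."""
        m, w = self.concepts_per_theme, self.clique_window
        return len(_circulant_pairs(m, w))


@dataclass(frozen=True)
class GroundTruth:
    """Planted partition, expected theme labels, and noise predication keys."""

    theme_concepts: tuple[frozenset[str], ...]
    expected_labels: tuple[str, ...]
    noise_keys: frozenset[PredicationKey]

    def theme_of(self, concept_id: str) -> int | None:
        for i, members in enumerate(self.theme_concepts):
            if concept_id in members:
                return i
        return None


def _circulant_pairs(m: int, window: int) -> list[tuple[int, int]]:
    """Unordered index pairs of the circulant ring C_m(1, .., window-1)."""
    pairs = set()
    for j in range(m):
        for d in range(1, window):
            k = (j + d) % m
            if j != k:
                pairs.add((min(j, k), max(j, k)))
    return sorted(pairs)


def generate(
    config: SyntheticConfig, group_config: GroupConfig | None = None
) -> tuple[list[PredicationRecord], GroundTruth]:
    """Generate a corpus with planted themes. Deterministic given the seed."""
    group_config = group_config or default_group_config()
    specs = config.theme_specs or DEFAULT_THEME_SPECS
    rng = np.random.default_rng(config.seed)
    records: list[PredicationRecord] = []
    citation_counter = 0

    def next_citation() -> str:
        nonlocal citation_counter
        citation_counter += 1
        return f"PM{100000 + citation_counter}"

    def draw_count(mean: float, dispersion: float) -> int:
        if dispersion <= 0:
            return max(1, round(mean))
        # negative-binomial with variance mean + dispersion * mean^2
        r = 1.0 / dispersion
        p = r / (r + mean)
        return max(1, int(rng.negative_binomial(r, p)))

    def emit(sub, obj, predicate, n_citations):
        # sub/obj are (id, name, semtype) triples; one record per citation
        for _ in range(n_citations):
            records.append(
                PredicationRecord(
                    citation_id=next_citation(),
                    sentence_id="s1",
                    subject_id=sub[0],
                    subject_name=sub[1],
                    subject_semtype=sub[2],
                    predicate=predicate,
                    object_id=obj[0],
                    object_name=obj[1],
                    object_semtype=obj[2],
                )
            )

    theme_concepts: list[frozenset[str]] = []
    expected_labels: list[str] = []
    themes: list[list[tuple[str, str, str]]] = []
    for i in range(config.n_themes):
        spec = specs[i % len(specs)]
        concepts = [
            (
                f"T{i + 1:02d}C{j + 1:02d}",
                f"{spec.concept_prefix} {i + 1}-{j + 1}",
                spec.semtype,
            )
            for j in range(config.concepts_per_theme)
        ]
        themes.append(concepts)
        members = {c[0] for c in concepts}
        expected_labels.append(spec.display_name)
        for j, k in _circulant_pairs(config.concepts_per_theme, config.clique_window):
            if config.intra_theme_density < 1.0 and rng.random() >= config.intra_theme_density:
                continue
            emit(
                concepts[j],
                concepts[k],
                spec.predicate,
                draw_count(config.citation_mean, config.citation_dispersion),
            )
        theme_concepts.append(frozenset(members))

    # bridge concepts join one window clique of each adjacent theme, exercising
    # clique overlap across themes (off by default: bridges break degree
    # regularity, which the clean-corpus centrality cutoff relies on)
    for i in range(config.n_themes - 1):
        spec_a, spec_b = specs[i % len(specs)], specs[(i + 1) % len(specs)]
        for b in range(config.bridge_concepts):
            bridge_id = f"B{i + 1:02d}_{b + 1}"
            bridge_name = f"Bridge {i + 1}-{b + 1}"
            for spec, theme in ((spec_a, themes[i]), (spec_b, themes[i + 1])):
                bridge = (bridge_id, bridge_name, spec.semtype)
                for partner in theme[: config.clique_window]:
                    emit(
                        bridge,
                        partner,
                        spec.predicate,
                        draw_count(config.citation_mean, config.citation_dispersion),
                    )
            theme_concepts[i] = theme_concepts[i] | {bridge_id}

    noise_keys: set[PredicationKey] = set()
    if config.noise_predications > 0:
        pool_size = max(2, math.ceil(1.5 * config.noise_predications))
        noise_semtypes = ["dsyn", "phsu", "bpoc", "gngm", "topp"]
        pool = [
            (
                f"N{j + 1:03d}",
                f"Noise concept {j + 1}",
                noise_semtypes[int(rng.integers(len(noise_semtypes)))],
            )
            for j in range(pool_size)
        ]
        vocabulary = sorted(group_config.predicate_vocabulary)
        for _ in range(config.noise_predications):
            predicate = vocabulary[int(rng.integers(len(vocabulary)))]
            a, b = rng.choice(pool_size, size=2, replace=False)
            sub, obj = pool[int(a)], pool[int(b)]
            if rng.random() < config.generic_noise_fraction:
                g = GENERIC_CONCEPT_DETAILS[
                    int(rng.integers(len(GENERIC_CONCEPT_DETAILS)))
                ]
                sub = g
            n = 1 + int(rng.poisson(max(0.0, config.noise_citation_mean - 1.0)))
            emit(sub, obj, predicate, n)
            noise_keys.add((sub[0], predicate, obj[0]))

    truth = GroundTruth(
        theme_concepts=tuple(theme_concepts),
        expected_labels=tuple(expected_labels),
        noise_keys=frozenset(noise_keys),
    )
    return records, truth


# -- recovery scoring --------------------------------------------------------


def _comb2(n: int) -> float:
    return n * (n - 1) / 2.0


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Adjusted Rand index between two flat labelings of the same items."""
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    n = len(a)
    if n == 0:
        return 1.0
    contingency: dict[tuple[int, int], int] = {}
    row_sums: dict[int, int] = {}
    col_sums: dict[int, int] = {}
    for x, y in zip(a, b):
        contingency[(x, y)] = contingency.get((x, y), 0) + 1
        row_sums[x] = row_sums.get(x, 0) + 1
        col_sums[y] = col_sums.get(y, 0) + 1
    sum_ij = sum(_comb2(v) for v in contingency.values())
    sum_a = sum(_comb2(v) for v in row_sums.values())
    sum_b = sum(_comb2(v) for v in col_sums.values())
    total = _comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


@dataclass
class RecoveryReport:
    n_clusters: int
    n_themes: int
    theme_count_match: bool
    label_accuracy: float
    partition_agreement: float  # adjusted Rand on concept partitions
    cluster_majority_themes: list[int | None] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_themes": self.n_themes,
            "theme_count_match": self.theme_count_match,
            "label_accuracy": self.label_accuracy,
            "partition_agreement": self.partition_agreement,
            "cluster_majority_themes": list(self.cluster_majority_themes),
        }


def score_recovery(
    cluster_labels: Sequence[ClusterLabel],
    cliques_by_id: Mapping[int, Clique],
    truth: GroundTruth,
) -> RecoveryReport:
    """Score a pipeline result against the planted ground truth.

    Concepts appearing in several clusters are assigned to the cluster holding
    the majority of their cliques (ties to the earlier cluster). Label accuracy
    is the fraction of clusters whose metapredication family matches the
    expected label of the planted theme owning most of the cluster's concepts.
    """
    n_clusters = len(cluster_labels)
    n_themes = len(truth.theme_concepts)
    # concept -> cluster by majority clique membership
    votes: dict[str, list[int]] = {}
    for ci, cl in enumerate(cluster_labels):
        for cid in cl.cluster:
            for concept in cliques_by_id[cid].members:
                votes.setdefault(concept, [0] * n_clusters)[ci] += 1
    concept_cluster = {
        c: max(range(n_clusters), key=lambda i: (v[i], -i)) for c, v in votes.items()
    }
    common = [
        c for c in sorted(concept_cluster) if truth.theme_of(c) is not None
    ]
    ari = adjusted_rand_index(
        [concept_cluster[c] for c in common],
        [truth.theme_of(c) for c in common],
    ) if common else 0.0

    majorities: list[int | None] = []
    correct = 0
    for cl in cluster_labels:
        concepts = {m for cid in cl.cluster for m in cliques_by_id[cid].members}
        theme_votes: dict[int, int] = {}
        for c in concepts:
            t = truth.theme_of(c)
            if t is not None:
                theme_votes[t] = theme_votes.get(t, 0) + 1
        if not theme_votes:
            majorities.append(None)
            continue
        majority = min(
            theme_votes, key=lambda t: (-theme_votes[t], t)
        )
        majorities.append(majority)
        if (
            cl.label is not UNLABELED
            and cl.display_name == truth.expected_labels[majority]
        ):
            correct += 1
    label_accuracy = correct / n_clusters if n_clusters else 0.0
    return RecoveryReport(
        n_clusters=n_clusters,
        n_themes=n_themes,
        theme_count_match=(n_clusters == n_themes),
        label_accuracy=label_accuracy,
        partition_agreement=ari,
        cluster_majority_themes=majorities,
    )
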