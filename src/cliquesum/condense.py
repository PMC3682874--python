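"""Graph condensation: novelty, degree-centrality and frequency filters.

The three filters run in a fixed order. First, predications with a generic
argument are removed (novelty). Second, degree centrality is computed on the
resulting graph and only predications whose two arguments both score strictly
above mean + sd/2 survive. Third, the citation frequencies of the surviving
predications set a second mean + sd/2 cutoff and predications strictly below
it are eliminated (equality survives). Standard deviations are population
standard deviations: the value set is the whole population of nodes or
predications, not a sample.

Degenerate populations are handled conservatively: a cutoff computed from
fewer than two values, or from values with zero variance, is skipped (the
filter keeps everything) and a warning is recorded. An empty post-filter graph
is a warning, not an error; the pipeline short-circuits downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph_model import PredicationGraph, degree_centrality
from .predication_io import GroupConfig

_EPS = 1e-12


@dataclass(frozen=True)
class CutoffPolicy:
    """A mean + multiplier * (population sd) cutoff over a value population."""

    kind: str
    mean: float
    sd: float
    sd_multiplier: float
    cutoff: float


@dataclass
class FilterReport:
    """Before/after accounting for one condensation stage."""

    stage: str
    predications_before: int
    predications_after: int
    nodes_before: int
    nodes_after: int
    cutoff: CutoffPolicy | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "predications_before": self.predications_before,
            "predications_after": self.predications_after,
            "nodes_before": self.nodes_before,
            "nodes_after": self.nodes_after,
            "warnings": list(self.warnings),
        }
        if self.cutoff is not None:
            d["cutoff"] = {
                "kind": self.cutoff.kind,
                "mean": self.cutoff.mean,
                "sd": self.cutoff.sd,
                "sd_multiplier": self.cutoff.sd_multiplier,
                "cutoff": self.cutoff.cutoff,
            }
        return d


def compute_cutoff(
    values: Sequence[float], kind: str = "", sd_multiplier: float = 0.5
) -> CutoffPolicy:
    """Arithmetic mean plus ``sd_multiplier`` times the population sd."""
    if len(values) < 2:
        raise ValueError("cutoff requires at least 2 values")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    return CutoffPolicy(
        kind=kind, mean=mean, sd=sd, sd_multiplier=sd_multiplier,
        cutoff=mean + sd_multiplier * sd,
    )


def _generic_ids(config: GroupConfig) -> frozenset[str]:
    generic = set(config.generic_concepts)
    if config.hierarchy is not None:
        if config.generic_depth is None:
            raise ValueError("hierarchy given without generic_depth")
        children: dict[str, set[str]] = {}
        all_children = set()
        all_parents = set()
        for child, parent in config.hierarchy:
            children.setdefault(parent, set()).add(child)
            all_children.add(child)
            all_parents.add(parent)
        roots = all_parents - all_children
        # breadth-first: concepts at depth < generic_depth from any root are generic
        frontier = set(roots)
        depth = 0
        seen: set[str] = set()
        while frontier and depth < config.generic_depth:
            generic |= frontier
            seen |= frontier
            frontier = {
                c for p in frontier for c in children.get(p, ()) if c not in seen
            }
            depth += 1
    return frozenset(generic)


def novelty_filter(
    graph: PredicationGraph, config: GroupConfig
) -> tuple[PredicationGraph, FilterReport]:
    """Remove predications with at least one generic argument.

    Generic concepts are those listed in the configuration, plus (when a
    concept hierarchy and ``generic_depth`` are supplied) every concept at
    depth < ``generic_depth`` from any hierarchy root. Nodes left without arcs
    are dropped.
    """
    generic = _generic_ids(config)
    keep = {
        p.key
        for p in graph.predications()
        if p.subject_id not in generic and p.object_id not in generic
    }
    out = graph.keep_predications(keep)
    report = FilterReport(
        stage="novelty",
        predications_before=graph.n_predications,
        predications_after=out.n_predications,
        nodes_before=graph.n_nodes,
        nodes_after=out.n_nodes,
    )
    if out.n_predications == 0:
        report.warnings.append("graph is empty after the novelty filter")
    return out, report


def centrality_filter(
    graph: PredicationGraph,
    centrality: dict[str, float] | None = None,
    sd_multiplier: float = 0.5,
) -> tuple[PredicationGraph, FilterReport]:
    """Keep predications whose two arguments both score strictly above the cutoff.

    The cutoff is mean + sd/2 over all node centralities of the input graph.
    Populations with fewer than two values or zero variance (e.g. a regular
    graph, where the cutoff would eliminate everything under the strict
    inequality) skip the cutoff with a warning.
    """
    report = FilterReport(
        stage="centrality",
        predications_before=graph.n_predications,
        predications_after=graph.n_predications,
        nodes_before=graph.n_nodes,
        nodes_after=graph.n_nodes,
    )
    if graph.n_nodes < 2:
        report.warnings.append("fewer than 2 nodes; centrality cutoff skipped")
        return graph, report
    if centrality is None:
        centrality = degree_centrality(graph)
    values = list(centrality.values())
    if max(values) - min(values) < _EPS:
        report.cutoff = compute_cutoff(values, kind="centrality", sd_multiplier=sd_multiplier)
        report.warnings.append(
            "uniform degree centrality (zero variance); cutoff skipped"
        )
        return graph, report
    policy = compute_cutoff(values, kind="centrality", sd_multiplier=sd_multiplier)
    keep = {
        p.key
        for p in graph.predications()
        if centrality[p.subject_id] > policy.cutoff
        and centrality[p.object_id] > policy.cutoff
    }
    out = graph.keep_predications(keep)
    report.predications_after = out.n_predications
    report.nodes_after = out.n_nodes
    report.cutoff = policy
    if out.n_predications == 0:
        report.warnings.append("graph is empty after the centrality filter")
    return out, report


def frequency_filter(
    graph: PredicationGraph, sd_multiplier: float = 0.5
) -> tuple[PredicationGraph, FilterReport]:
    """Eliminate predications whose citation frequency is strictly below the cutoff.

    The cutoff is mean + sd/2 over the frequencies of all surviving
    predications; frequencies equal to the cutoff survive. A single-predication
    population passes by convention.
    """
    report = FilterReport(
        stage="frequency",
        predications_before=graph.n_predications,
        predications_after=graph.n_predications,
        nodes_before=graph.n_nodes,
        nodes_after=graph.n_nodes,
    )
    freqs = [p.frequency for p in graph.predications()]
    if len(freqs) < 2:
        report.warnings.append("fewer than 2 predications; frequency cutoff skipped")
        return graph, report
    policy = compute_cutoff(freqs, kind="frequency", sd_multiplier=sd_multiplier)
    keep = {p.key for p in graph.predications() if p.frequency >= policy.cutoff}
    out = graph.keep_predications(keep)
    report.predications_after = out.n_predications
    report.nodes_after = out.n_nodes
    report.cutoff = policy
    if out.n_predications == 0:
        report.warnings.append("graph is empty after the frequency filter")
    return out, report


def condense(
    graph: PredicationGraph, config: GroupConfig, sd_multiplier: float = 0.5
) -> tuple[PredicationGraph, list[FilterReport]]:
    """Run novelty, centrality and frequency filters in order.

    If a stage empties the graph the remaining stages are skipped.
    """
    reports: list[FilterReport] = []
    graph, rep = novelty_filter(graph, config)
    reports.append(rep)
    if graph.n_predications == 0:
        return graph, reports
    graph, rep = centrality_filter(graph, sd_multiplier=sd_multiplier)
    reports.append(rep)
    if graph.n_predications == 0:
        return graph, reports
    graph, rep = frequency_filter(graph, sd_multiplier=sd_multiplier)
    reports.append(rep)
    return graph, reports
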