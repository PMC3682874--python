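"""Metapredication assignment, cluster labeling, solution selection, dynamic cut."""

from __future__ import annotations

import pytest

from cliquesum import (
    UNLABELED,
    Clique,
    assign_metapredication,
    build_graph,
    dynamic_merge,
    label_cluster,
    select_solution,
)
from cliquesum.clustering import MergeEvent, SolutionSet

from .conftest import make_record


def fs(*items):
    return frozenset(items)


class TestAssignMetapredication:
    def assign(self, config, predicate, subject_types, object_types):
        g = build_graph(
            [
                make_record(
                    predicate=predicate,
                    subject_semtype=subject_types[0],
                    object_semtype=object_types[0],
                )
            ]
        )
        pred = next(g.predications())
        return assign_metapredication(pred, subject_types, object_types, config)

    def test_drug_treats_disorder_maps_to_drug_treatment(self, config):
        t = self.assign(config, "TREATS", ("phsu",), ("dsyn",))
        assert t.triple == ("Chemicals & Drugs", "Therapy", "Disorders")
        assert t.display_name == "Drug treatment"

    def test_procedure_treats_disorder_maps_to_procedure_treatment(self, config):
        t = self.assign(config, "TREATS", ("topp",), ("dsyn",))
        assert t.triple == ("Procedures", "Therapy", "Disorders")
        assert t.display_name == "Procedure treatment"

    def test_predicate_outside_the_groups_is_unmapped(self, config):
        assert self.assign(config, "PROCESS_OF", ("dsyn",), ("podg",)) is None

    def test_first_type_yielding_an_allowed_triple_wins(self, config):
        # subject carries a conceptual and a pharmacologic semantic type; only
        # the Chemicals & Drugs reading yields an allowed Therapy triple
        t = self.assign(config, "TREATS", ("idcn", "phsu"), ("dsyn",))
        assert t.display_name == "Drug treatment"

    def test_disallowed_group_combination_is_unmapped(self, config):
        # Anatomy TREATS Disorders is not an allowed metapredication
        assert self.assign(config, "TREATS", ("bpoc",), ("dsyn",)) is None


class TestLabelCluster:
    def build(self, rows):
        records = []
        for i, (s, st, p, o, ot, freq) in enumerate(rows):
            for c in range(freq):
                records.append(
                    make_record(
                        subject=s, obj=o, predicate=p, citation=f"PM{i}_{c}",
                        subject_semtype=st, object_semtype=ot,
                    )
                )
        return build_graph(records)

    def test_majority_metapredication_labels_the_cluster(self, config):
        g = self.build(
            [
                ("D1", "phsu", "TREATS", "X1", "dsyn", 1),
                ("D2", "phsu", "TREATS", "X1", "dsyn", 1),
                ("D1", "phsu", "TREATS", "X2", "dsyn", 1),
                ("X1", "dsyn", "COEXISTS_WITH", "X2", "dsyn", 1),
            ]
        )
        cliques = {1: Clique(1, fs("D1", "D2", "X1", "X2"))}
        cl = label_cluster(fs(1), cliques, g, config)
        assert cl.display_name == "Drug treatment"
        assert len(cl.predications) == 4  # non-matching predication retained
        assert cl.counts[cl.label] == 3

    def test_all_unknown_predicates_give_unlabeled(self, config):
        g = self.build([("A", "dsyn", "PROCESS_OF", "B", "podg", 1)])
        cliques = {1: Clique(1, fs("A", "B"))}
        cl = label_cluster(fs(1), cliques, g, config)
        assert cl.label is UNLABELED
        assert len(cl.predications) == 1

    def test_count_tie_breaks_by_summed_citation_frequency(self, config):
        g = self.build(
            [
                ("D1", "phsu", "TREATS", "X1", "dsyn", 1),
                ("X1", "dsyn", "COEXISTS_WITH", "X2", "dsyn", 5),
            ]
        )
        cliques = {1: Clique(1, fs("D1", "X1", "X2"))}
        cl = label_cluster(fs(1), cliques, g, config)
        assert cl.display_name == "Disease comorbidities"

    def test_predication_needs_both_arguments_in_one_clique(self, config):
        g = self.build(
            [
                ("D1", "phsu", "TREATS", "X1", "dsyn", 1),
                ("D2", "phsu", "TREATS", "X2", "dsyn", 1),
            ]
        )
        cliques = {1: Clique(1, fs("D1", "X1")), 2: Clique(2, fs("D2", "X2"))}
        cl = label_cluster(fs(1), cliques, g, config)
        assert set(cl.predications) == {("D1", "TREATS", "X1")}


def icicle_fixture():
    """An 8-clique solution set shaped like a labeled icicle walk.

    Row 2 is the first row with at most three singleton clusters; rows 3 and 4
    merge only clusters labeled "Body location"; row 5 merges two clusters
    with different labels, so row 4 is the optimal solution.
    """
    rows = [
        tuple(fs(i) for i in range(1, 9)),
        (fs(1, 2), fs(3), fs(4), fs(5, 6), fs(7), fs(8)),
        (fs(1, 2), fs(3, 4), fs(5, 6), fs(7), fs(8)),
        (fs(1, 2), fs(3, 4), fs(5, 6), fs(7, 8)),
        (fs(1, 2), fs(3, 4), fs(5, 6, 7, 8)),
        (fs(1, 2, 3, 4), fs(5, 6, 7, 8)),
        (fs(1, 2, 3, 4, 5, 6, 7, 8),),
    ]
    labels = {
        fs(1): "Drug treatment", fs(2): "Drug treatment", fs(1, 2): "Drug treatment",
        fs(3): "Etiology", fs(4): "Etiology", fs(3, 4): "Etiology",
        fs(5): "Body location", fs(6): "Body location", fs(5, 6): "Body location",
        fs(7): "Body location", fs(8): "Body location", fs(7, 8): "Body location",
        fs(5, 6, 7, 8): "Body location",
        fs(1, 2, 3, 4): "Drug treatment",
        fs(1, 2, 3, 4, 5, 6, 7, 8): "Drug treatment",
    }
    solution_set = SolutionSet(
        solutions=rows, heights=[None, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
    )
    return solution_set, labels.__getitem__


class TestSelectSolution:
    def test_walk_stops_at_the_first_differently_labeled_merge(self):
        sols, label_of = icicle_fixture()
        assert select_solution(sols, label_of) == 4

    def test_no_consistent_merge_returns_the_starting_row(self):
        sols, _ = icicle_fixture()
        assert select_solution(sols, lambda c: f"L{sorted(c)}") == 2

    def test_all_same_label_runs_to_the_coarsest_row(self):
        sols, _ = icicle_fixture()
        assert select_solution(sols, lambda c: "Etiology") == len(sols.solutions) - 1

    def test_unlabeled_clusters_never_license_an_advance(self):
        sols, label_of = icicle_fixture()

        def label(c):
            return UNLABELED if c in (fs(7), fs(8)) else label_of(c)

        assert select_solution(sols, label) == 2

    def test_no_qualifying_row_falls_back_to_the_coarsest(self):
        rows = [
            tuple(fs(i) for i in range(1, 6)),
            (fs(1, 2), fs(3), fs(4), fs(5)),  # 3+ singletons at every level
            (fs(1, 2), fs(3, 4), fs(5)),
            (fs(1, 2, 3, 4, 5),),
        ]
        sols = SolutionSet(solutions=rows, heights=[None, 3.0, 2.0, 1.0])
        idx = select_solution(sols, lambda c: "X", max_singletons=0)
        # nothing has 0 singletons except the final row
        assert idx == 3

    def test_permissive_mode_advances_on_any_consistent_merge(self):
        # one step carries two merge events: a label-consistent one (1-2 + 3-4)
        # and an inconsistent one (5-6 + 7-8)
        rows = [
            (fs(1, 2), fs(3, 4), fs(5, 6), fs(7, 8)),
            (fs(1, 2, 3, 4), fs(5, 6, 7, 8)),
            (fs(1, 2, 3, 4, 5, 6, 7, 8),),
        ]
        labels = {
            fs(1, 2): "A", fs(3, 4): "A", fs(1, 2, 3, 4): "A",
            fs(5, 6): "B", fs(7, 8): "C", fs(5, 6, 7, 8): "B",
            fs(1, 2, 3, 4, 5, 6, 7, 8): "A",
        }
        sols = SolutionSet(solutions=rows, heights=[None, 2.0, 1.0])
        assert select_solution(sols, labels.__getitem__, mode="conservative") == 0
        assert select_solution(sols, labels.__getitem__, mode="permissive") == 1

    def test_result_never_precedes_the_starting_row(self):
        sols, label_of = icicle_fixture()
        assert select_solution(sols, label_of) >= 2


def dynamic_fixture():
    """An 8-cluster selected row whose tree merges repeat three theme labels."""
    base = tuple(fs(i) for i in range(1, 9))
    labels = {
        fs(1): "Substance interaction", fs(2): "Substance interaction",
        fs(1, 2): "Substance interaction",
        fs(3): "Body location", fs(4): "Body location", fs(3, 4): "Body location",
        fs(5): "Etiology", fs(6): "Drug treatment",
        fs(7): "Etiology", fs(8): "Etiology", fs(7, 8): "Etiology",
    }
    events = [
        MergeEvent((fs(1), fs(2)), fs(1, 2), 5.0, 1),
        MergeEvent((fs(3), fs(4)), fs(3, 4), 4.0, 2),
        MergeEvent((fs(7), fs(8)), fs(7, 8), 3.0, 3),
        MergeEvent((fs(5), fs(6)), fs(5, 6), 2.5, 4),
        MergeEvent((fs(1, 2), fs(3, 4)), fs(1, 2, 3, 4), 2.0, 5),
        MergeEvent(
            (fs(1, 2, 3, 4), fs(5, 6), fs(7, 8)), fs(1, 2, 3, 4, 5, 6, 7, 8), 1.0, 6
        ),
    ]
    rows = [base]
    current = list(base)
    for e in events:
        current = [c for c in current if c not in e.children] + [e.parent]
        rows.append(tuple(sorted(current, key=sorted)))
    sols = SolutionSet(
        solutions=rows,
        heights=[None] + [e.height for e in events],
        merge_events=events,
    )
    return sols, labels


class TestDynamicMerge:
    def test_same_label_branches_merge_into_five_clusters(self):
        sols, labels = dynamic_fixture()
        result = dynamic_merge(sols, 0, labels.__getitem__)
        assert set(result) == {fs(1, 2), fs(3, 4), fs(5), fs(6), fs(7, 8)}

    def test_label_distinct_selection_is_unchanged(self):
        sols, _ = dynamic_fixture()
        distinct = {c: f"L{sorted(c)}" for row in sols.solutions for c in row}
        result = dynamic_merge(sols, 0, distinct.__getitem__)
        assert set(result) == set(sols.solutions[0])

    def test_uniform_label_collapses_to_one_cluster(self):
        sols, _ = dynamic_fixture()
        result = dynamic_merge(sols, 0, lambda c: "Theme")
        assert result == (fs(1, 2, 3, 4, 5, 6, 7, 8),)

    def test_no_cluster_pair_sharing_a_label_survives_a_shared_label_event(self):
        sols, labels = dynamic_fixture()
        result = dynamic_merge(sols, 0, labels.__getitem__)
        for e in sols.merge_events:
            participants = [c for c in result if c & e.parent]
            if len(participants) >= 2:
                got = {labels.get(c, f"merged{sorted(c)}") for c in participants}
                assert len(got) > 1
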