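"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import random

import pytest

from cliquesum import (
    PredicationRecord,
    build_graph,
    default_group_config,
)


def make_record(
    subject="C0001",
    obj="C0002",
    predicate="TREATS",
    citation="PM1",
    sentence="s1",
    subject_name=None,
    object_name=None,
    subject_semtype="phsu",
    object_semtype="dsyn",
) -> PredicationRecord:
    return PredicationRecord(
        citation_id=citation,
        sentence_id=sentence,
        subject_id=subject,
        subject_name=subject_name or f"name of {subject}",
        subject_semtype=subject_semtype,
        predicate=predicate,
        object_id=obj,
        object_name=object_name or f"name of {obj}",
        object_semtype=object_semtype,
    )


@pytest.fixture
def config():
    return default_group_config()


@pytest.fixture
def parkinson_graph():
    """A small hand-built graph in the style of a disease-treatment summary.

    Nine distinct predications over eight concepts; one concept pair carries
    two predicates on one arc; the two hub concepts (the disease and its main
    intervention) are the best-connected nodes.
    """
    rows = [
        # subject, predicate, object, subject type, object type
        ("Deep Brain Stimulation", "TREATS", "Parkinson Disease", "topp", "dsyn"),
        ("Dopamine Agonists", "TREATS", "Parkinson Disease", "phsu", "dsyn"),
        ("Parkinson Disease", "ISA", "Movement Disorders", "dsyn", "dsyn"),
        ("Parkinson Disease", "COEXISTS_WITH", "Movement Disorders", "dsyn", "dsyn"),
        ("Subthalamic Nucleus", "LOCATION_OF", "Deep Brain Stimulation", "bpoc", "topp"),
        ("Deep Brain Stimulation", "TREATS", "Dyskinetic syndrome", "topp", "dsyn"),
        ("Dyskinetic syndrome", "COEXISTS_WITH", "Parkinson Disease", "dsyn", "dsyn"),
        ("Carbidopa", "TREATS", "Parkinson Disease", "phsu", "dsyn"),
        ("Deep Brain Stimulation", "COMPARED_WITH", "Levodopa", "topp", "phsu"),
    ]
    records = []
    for i, (s, p, o, st, ot) in enumerate(rows):
        for c in range(i % 3 + 1):  # varying citation frequency 1..3
            records.append(
                make_record(
                    subject=s.replace(" ", "_"),
                    obj=o.replace(" ", "_"),
                    predicate=p,
                    citation=f"PM{i}_{c}",
                    subject_name=s,
                    object_name=o,
                    subject_semtype=st,
                    object_semtype=ot,
                )
            )
    return build_graph(records)


def random_graph_records(n_nodes: int, p: float, rng: random.Random):
    """Occurrence records realizing a G(n, p) concept graph (frequency 1 arcs)."""
    records = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                records.append(
                    make_record(
                        subject=f"C{i:03d}",
                        obj=f"C{j:03d}",
                        predicate="ASSOCIATED_WITH",
                        citation=f"PM{i}_{j}",
                        subject_semtype="dsyn",
                        object_semtype="dsyn",
                    )
                )
    return records
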