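"""Concept-graph operations against brute-force oracles: subsumption vs
matrix transitive closure, proximal primitive parents vs exhaustive path
walks, disjunction resolution vs exhaustive common-ancestor search, plus
vocabulary attachment and file round-trips."""

from __future__ import annotations

import random

import numpy as np
import pytest

import fdg.fixtures as fx
from fdg.concept_model import (
    Concept,
    ConceptGraph,
    ExternalVocabulary,
    UNMAPPED,
    attach_vocabulary,
    evaluate_selection_criteria,
    is_subsumed_by,
    proximal_primitive_parent,
    read_graph,
    read_registry,
    resolve_disjunction,
    write_graph,
    write_registry,
)
from fdg.errors import (
    CycleError,
    DuplicateVocabularyError,
    GraphFormatError,
    MalformedIdError,
    UnknownConceptError,
)

from conftest import random_dag_graph


# -- oracles ---------------------------------------------------------------


def closure_matrix(graph: ConceptGraph, ids: list[str]) -> np.ndarray:
    """Reflexive-transitive closure of the is-a relation by boolean matrix
    squaring; entry [i, j] == child i subsumed by ancestor j."""
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    reach = np.eye(n, dtype=bool)
    for cid in ids:
        for p in graph.concepts[cid].parents:
            reach[index[cid], index[p]] = True
    while True:
        new = reach | (reach @ reach)
        if (new == reach).all():
            return reach
        reach = new


def ppp_oracle(graph: ConceptGraph, node: str) -> frozenset[str]:
    """All primitive ancestors reachable through exclusively fully defined
    intermediate concepts, by exhaustive upward path walking."""
    if graph.is_primitive(node):
        return frozenset({node})
    out: set[str] = set()

    def walk(v: str) -> None:
        for p in graph.parents_of(v):
            if graph.is_primitive(p):
                out.add(p)
            else:
                walk(p)

    walk(node)
    return frozenset(out)


def depth_oracle(graph: ConceptGraph, node: str) -> int:
    parents = graph.parents_of(node)
    if not parents:
        return 0
    return 1 + max(depth_oracle(graph, p) for p in parents)


def disjunction_oracle(graph, a, b, max_depth_gap):
    common = graph.ancestors_or_self(a) & graph.ancestors_or_self(b)
    best = max(depth_oracle(graph, c) for c in common)
    gap = min(depth_oracle(graph, a), depth_oracle(graph, b)) - best
    if gap > max_depth_gap:
        return UNMAPPED
    deepest = [c for c in common if depth_oracle(graph, c) == best]
    return min(deepest, key=lambda c: (0, int(c)) if c.isdigit() else (1, c))


# -- subsumption -----------------------------------------------------------


def test_subsumption_matches_transitive_closure_on_random_dags():
    """On random DAGs the implementation agrees with the matrix closure on
    every ordered pair of concepts."""
    rng = random.Random(42)
    for _ in range(8):
        graph, ids = random_dag_graph(rng, rng.randrange(20, 120))
        reach = closure_matrix(graph, ids)
        for i, cid in enumerate(ids):
            ancestors = graph.ancestors_or_self(cid)
            oracle = {ids[j] for j in np.flatnonzero(reach[i])}
            assert ancestors == oracle


def test_subsumption_reflexive_and_transitive(graph):
    rng = random.Random(3)
    nodes = sorted(n for n in graph if not n.startswith("~"))
    for x in rng.sample(nodes, 25):
        assert is_subsumed_by(x, x, graph)
    # transitivity along parent chains
    for x in rng.sample(nodes, 25):
        for p in graph.parents_of(x):
            assert is_subsumed_by(x, p, graph)
            for gp in graph.parents_of(p):
                assert is_subsumed_by(x, gp, graph)


def test_disjoint_hierarchies_never_subsume(graph):
    """Concepts of distinct top-level hierarchies share only the root."""
    finding_nodes = graph.descendants_or_self(fx.CLINICAL_FINDING)
    body_nodes = graph.descendants_or_self(fx.BODY_STRUCTURE)
    overlap = finding_nodes & body_nodes
    assert not overlap
    f = sorted(finding_nodes)[0]
    b = sorted(body_nodes)[0]
    assert not is_subsumed_by(f, b, graph) and not is_subsumed_by(b, f, graph)


def test_unknown_concept_raises(graph):
    with pytest.raises(UnknownConceptError):
        is_subsumed_by("999999999999", fx.ROOT, graph)


# -- vocabulary attachment -------------------------------------------------


def _lineage_vocab(parent: str) -> ExternalVocabulary:
    return ExternalVocabulary(
        key="Lineage",
        attachment_parent=parent,
        concepts={"B": (), "B.1": ("B",), "B.1.1.7": ("B.1",)},
    )


def test_attach_places_external_concepts_under_parent(graph):
    # the session fixture already has Pango attached
    assert is_subsumed_by("~Pango~B.1.1.7~", fx.VIRUS_STRAIN_PARENT, graph)
    assert is_subsumed_by("~Pango~B.1.1.7~", fx.ORGANISM, graph)
    # local hierarchy is preserved beneath the attachment parent
    assert is_subsumed_by("~Pango~B.1.1.7~", "~Pango~B~", graph)
    assert not is_subsumed_by("~Pango~B~", "~Pango~B.1.1.7~", graph)


def test_attach_is_conservative():
    """Attaching a vocabulary never changes subsumption between
    pre-existing host concepts."""
    rng = random.Random(9)
    graph, ids = random_dag_graph(rng, 40)
    before = closure_matrix(graph, ids)
    attach_vocabulary(_lineage_vocab(ids[5]), graph)
    after = closure_matrix(graph, ids)  # host concepts only
    assert (before == after).all()
    assert is_subsumed_by("~Lineage~B.1.1.7~", ids[5], graph)


def test_attach_errors():
    rng = random.Random(10)
    graph, ids = random_dag_graph(rng, 10)
    with pytest.raises(UnknownConceptError):
        attach_vocabulary(
            ExternalVocabulary(key="X", attachment_parent="999999999999",
                               concepts={"a": ()}),
            graph,
        )
    attach_vocabulary(_lineage_vocab(ids[0]), graph)
    with pytest.raises(DuplicateVocabularyError):
        attach_vocabulary(_lineage_vocab(ids[0]), graph)


# -- proximal primitive parents --------------------------------------------


def test_ppp_primitive_is_its_own(graph):
    assert proximal_primitive_parent(fx.CLINICAL_FINDING, graph) == {
        fx.CLINICAL_FINDING
    }


def test_ppp_chain_and_diamond():
    r, a, b, c, p1, p2 = (
        "138875005", "404684003", "71388002", "123037004", "410607006",
        "363787002",
    )
    concepts = [
        Concept(r, "root", "primitive"),
        Concept(p1, "P1", "primitive", frozenset({r})),
        Concept(p2, "P2", "primitive", frozenset({r})),
        Concept(a, "A defined", "fully_defined", frozenset({p1})),
        Concept(b, "B defined", "fully_defined", frozenset({p2})),
        Concept(c, "C defined", "fully_defined", frozenset({a, b})),
    ]
    g = ConceptGraph(concepts)
    # chain: first primitive ancestor wins
    assert proximal_primitive_parent(a, g) == {p1}
    # diamond through two defined parents reaches two distinct primitives
    assert proximal_primitive_parent(c, g) == {p1, p2}


def test_ppp_matches_path_oracle_on_random_dags():
    rng = random.Random(17)
    for _ in range(10):
        graph, ids = random_dag_graph(rng, 30, primitive_fraction=0.35)
        for cid in ids:
            result = proximal_primitive_parent(cid, graph)
            assert result == ppp_oracle(graph, cid)
            # invariant: results are primitive ancestors-or-self
            for p in result:
                assert graph.is_primitive(p)
                assert is_subsumed_by(cid, p, graph)


# -- disjunction resolution --------------------------------------------------


def test_disjunction_identical_inputs(graph):
    assert resolve_disjunction(fx.SARS_COV_2, fx.SARS_COV_2, graph, 0) == fx.SARS_COV_2


def test_disjunction_siblings():
    r, p, x, y = "138875005", "404684003", "71388002", "123037004"
    g = ConceptGraph(
        [
            Concept(r, "root", "primitive"),
            Concept(p, "parent", "primitive", frozenset({r})),
            Concept(x, "x", "primitive", frozenset({p})),
            Concept(y, "y", "primitive", frozenset({p})),
        ]
    )
    assert resolve_disjunction(x, y, g, max_depth_gap=1) == p
    assert resolve_disjunction(x, y, g, max_depth_gap=0) == UNMAPPED


def test_disjunction_root_only_common_ancestor(graph):
    """Concepts whose only shared ancestor is the root stay unmapped when
    the gap budget is smaller than their depth."""
    a, b = fx.CLINICAL_FINDING, fx.BODY_STRUCTURE  # depth 1 siblings at root
    assert resolve_disjunction(a, b, graph, 0) == UNMAPPED
    assert resolve_disjunction(a, b, graph, 1) == fx.ROOT


def test_disjunction_matches_bruteforce_and_is_symmetric():
    rng = random.Random(23)
    for _ in range(6):
        graph, ids = random_dag_graph(rng, 25)
        for _ in range(40):
            a, b = rng.choice(ids), rng.choice(ids)
            gap = rng.randrange(4)
            res = resolve_disjunction(a, b, graph, gap)
            assert res == disjunction_oracle(graph, a, b, gap)
            assert res == resolve_disjunction(b, a, graph, gap)


# -- selection criteria ------------------------------------------------------


def test_selection_criteria_reports():
    accepted = evaluate_selection_criteria(
        gap_covered=True, concept_based=True, hierarchical=True,
        versioned=True, recognized_standard=True,
    )
    assert accepted.accepted and not accepted.failed_criteria

    thesaurus = evaluate_selection_criteria(
        gap_covered=True, concept_based=False, hierarchical=True,
        versioned=True, recognized_standard=True,
        notes={"concept_based": "a thesaurus, not concept-based"},
    )
    assert not thesaurus.accepted
    assert thesaurus.failed_criteria == ("concept_based",)

    unversioned = evaluate_selection_criteria(
        gap_covered=True, concept_based=True, hierarchical=True,
        versioned=False, recognized_standard=True,
    )
    assert not unversioned.accepted


# -- I/O ---------------------------------------------------------------------


def test_graph_roundtrip(tmp_path, graph):
    path = tmp_path / "graph.tsv"
    write_graph(graph, path)
    again = read_graph(path)
    assert again.concepts == graph.concepts
    write_graph(again, tmp_path / "again.tsv")
    assert (tmp_path / "again.tsv").read_text() == path.read_text()


def test_graph_read_rejects_cycle(tmp_path):
    a, b = "404684003", "71388002"
    path = tmp_path / "cyclic.tsv"
    path.write_text(
        "id\tterm\tdefinition_status\tparents\n"
        f"138875005\troot\tprimitive\t\n"
        f"{a}\tA\tprimitive\t{b}|138875005\n"
        f"{b}\tB\tprimitive\t{a}|138875005\n"
    )
    with pytest.raises(CycleError):
        read_graph(path)


def test_graph_read_rejects_dangling_parent_and_bad_id(tmp_path):
    path = tmp_path / "dangling.tsv"
    path.write_text("138875005\troot\tprimitive\t\n404684004\tA\tprimitive\t138875005\n")
    with pytest.raises(MalformedIdError):
        read_graph(path)  # 404684004 has a wrong check digit
    path.write_text(
        "138875005\troot\tprimitive\t\n404684003\tA\tprimitive\t71388002\n"
    )
    with pytest.raises(GraphFormatError):
        read_graph(path)  # parent 71388002 is not in the file


def test_registry_roundtrip(tmp_path):
    vocab = fx.pango_vocabulary()
    path = tmp_path / "registry.json"
    write_registry([vocab], path)
    again = read_registry(path)
    assert again == {"Pango": vocab}
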