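"""Shared fixtures: the default fixture ontology (with the Pango
vocabulary attached) and its rule sets, plus small random-DAG builders used
by the hierarchy oracles."""

from __future__ import annotations

import random

import pytest

from fdg.concept_model import Concept, ConceptGraph, synthetic_sctid
from fdg.synthetic_data import FixtureContext, GeneratorParams, make_default_context


@pytest.fixture(scope="session")
def ctx() -> FixtureContext:
    """Default fixture context, seed 1: graph + base and extended rules."""
    return make_default_context(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def graph(ctx):
    return ctx.graph


def random_dag_graph(rng: random.Random, n_nodes: int, primitive_fraction: float = 0.5):
    """A random single-rooted DAG as a ConceptGraph; node i draws 1-3
    parents among nodes 0..i-1.  Returns (graph, ids in creation order)."""
    ids = []
    used = set()
    while len(ids) < n_nodes:
        cid = synthetic_sctid(rng.randrange(10**6, 10**9))
        if cid not in used:
            used.add(cid)
            ids.append(cid)
    concepts = [Concept(ids[0], "root", "primitive")]
    for i in range(1, n_nodes):
        k = min(i, rng.choice((1, 1, 2, 3)))
        parents = frozenset(rng.sample(ids[:i], k))
        status = "primitive" if rng.random() < primitive_fraction else "fully_defined"
        concepts.append(Concept(ids[i], f"node {i}", status, parents))
    return ConceptGraph(concepts), ids
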