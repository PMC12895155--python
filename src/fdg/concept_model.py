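"""Concept identifiers, the is-a concept graph, and hierarchy operations.

The native vocabulary is SNOMED CT-like: concepts carry numeric identifiers
terminated by a Verhoeff check digit and sit in an acyclic is-a hierarchy
with a single root.  Each concept is either *primitive* (its stated
relationships do not fully define it) or *fully defined*.  On top of the
hierarchy this module provides:

* subsumption (``is_subsumed_by`` -- the reflexive-transitive is-a closure,
  the semantics behind ``<<`` descendant-or-self constraints),
* attachment of external vocabularies (e.g. the Pango lineage nomenclature)
  beneath a host concept, after which tilde-delimited external references
  participate in subsumption like native concepts,
* proximal-primitive-parent attribution (the nearest primitive ancestors of
  a concept, used when deciding where an external code cluster belongs),
* disjunction resolution ("A or B" labels map to the deepest sufficiently
  close common ancestor, or stay unmapped),
* the five-point checklist used to decide whether an external terminology
  qualifies for integration at all.

Graphs are stored as flat TSV (one concept per row, parents pipe-separated)
and vocabulary registries as JSON; both formats round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import networkx as nx

from .errors import (
    CycleError,
    DuplicateVocabularyError,
    ExternalRefError,
    GraphFormatError,
    MalformedIdError,
    UnknownConceptError,
    UnknownVocabularyError,
)

__all__ = [
    "validate_sctid",
    "verhoeff_check_digit",
    "synthetic_sctid",
    "Concept",
    "ConceptGraph",
    "ExternalConceptRef",
    "ExternalVocabulary",
    "SelectionCriteriaReport",
    "UNMAPPED",
    "is_subsumed_by",
    "attach_vocabulary",
    "proximal_primitive_parent",
    "resolve_disjunction",
    "evaluate_selection_criteria",
    "read_graph",
    "write_graph",
    "read_registry",
    "write_registry",
]

PRIMITIVE = "primitive"
FULLY_DEFINED = "fully_defined"
UNMAPPED = "unmapped"

# ---------------------------------------------------------------------------
# Verhoeff check digits
# ---------------------------------------------------------------------------
# Multiplication and permutation tables of the dihedral group D5; the scheme
# detects all single-digit and adjacent-transposition errors.

_D = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 2, 3, 4, 0, 6, 7, 8, 9, 5),
    (2, 3, 4, 0, 1, 7, 8, 9, 5, 6),
    (3, 4, 0, 1, 2, 8, 9, 5, 6, 7),
    (4, 0, 1, 2, 3, 9, 5, 6, 7, 8),
    (5, 9, 8, 7, 6, 0, 4, 3, 2, 1),
    (6, 5, 9, 8, 7, 1, 0, 4, 3, 2),
    (7, 6, 5, 9, 8, 2, 1, 0, 4, 3),
    (8, 7, 6, 5, 9, 3, 2, 1, 0, 4),
    (9, 8, 7, 6, 5, 4, 3, 2, 1, 0),
)
_P = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 5, 7, 6, 2, 8, 3, 0, 9, 4),
    (5, 8, 0, 3, 7, 9, 6, 1, 4, 2),
    (8, 9, 1, 6, 0, 4, 3, 5, 2, 7),
    (9, 4, 5, 3, 1, 2, 6, 8, 7, 0),
    (4, 2, 8, 6, 5, 7, 3, 9, 0, 1),
    (2, 7, 9, 3, 8, 0, 6, 4, 1, 5),
    (7, 0, 4, 6, 9, 1, 3, 2, 5, 8),
)
_INV = (0, 4, 3, 2, 1, 5, 6, 7, 8, 9)


def _verhoeff_checksum(digits: str) -> int:
    c = 0
    for i, ch in enumerate(reversed(digits)):
        c = _D[c][_P[i % 8][int(ch)]]
    return c


def verhoeff_check_digit(body: str) -> str:
    """Check digit that makes ``body + digit`` Verhoeff-valid."""
    if not body.isdigit():
        raise MalformedIdError(f"identifier body must be decimal digits: {body!r}")
    return str(_INV[_verhoeff_checksum(body + "0")])


def validate_sctid(candidate: str) -> bool:
    """True iff *candidate* is a well-formed SNOMED-style identifier.

    6-18 decimal digits, no leading zero, valid Verhoeff check digit.
    Malformed input returns False rather than raising.
    """
    if not isinstance(candidate, str) or not candidate.isdigit():
        return False
    if not 6 <= len(candidate) <= 18:
        return False
    if candidate[0] == "0":
        return False
    return _verhoeff_checksum(candidate) == 0


def synthetic_sctid(body: Union[int, str]) -> str:
    """Build a valid identifier from a digit body by appending its check
    digit.  Used for synthetic fixture concepts that have no real-world id."""
    body = str(body)
    if not body.isdigit() or body[0] == "0" or not 5 <= len(body) <= 17:
        raise MalformedIdError(f"invalid identifier body: {body!r}")
    return body + verhoeff_check_digit(body)


# ---------------------------------------------------------------------------
# External references and vocabularies
# ---------------------------------------------------------------------------

# Characters that may not appear inside a tilde segment.  Besides the
# delimiters themselves and whitespace, the grammar's structural characters
# are excluded so external references can be recognised without backtracking.
_SEG_FORBIDDEN = set('~|=:{}()+,"')


def _check_segment(value: str, what: str) -> None:
    if not value:
        raise ExternalRefError(f"empty {what} segment in external reference", 0)
    for ch in value:
        if ch in _SEG_FORBIDDEN or ch.isspace() or not (0x21 <= ord(ch) <= 0x7E):
            raise ExternalRefError(
                f"forbidden character {ch!r} in external-reference {what}", 0
            )


@dataclass(frozen=True)
class ExternalConceptRef:
    """A tilde-delimited reference to a concept of an external vocabulary,
    e.g. ``~Pango~B.1.1.7~`` or the versioned ``~CTCAE~v5.0~4028512~``."""

    vocabulary_key: str
    local_id: str
    version: str | None = None

    def __post_init__(self) -> None:
        _check_segment(self.vocabulary_key, "vocabulary key")
        _check_segment(self.local_id, "local id")
        if self.version is not None:
            _check_segment(self.version, "version")

    @property
    def token(self) -> str:
        """Serialized token, including the version segment if present."""
        if self.version is None:
            return f"~{self.vocabulary_key}~{self.local_id}~"
        return f"~{self.vocabulary_key}~{self.version}~{self.local_id}~"

    @property
    def node_key(self) -> str:
        """Graph node key; resolution ignores the version label."""
        return f"~{self.vocabulary_key}~{self.local_id}~"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


@dataclass(frozen=True)
class ExternalVocabulary:
    """An external terminology prepared for attachment to the host graph.

    ``concepts`` maps local ids to tuples of local parent ids; concepts with
    no local parents become direct children of ``attachment_parent``.
    """

    key: str
    attachment_parent: str
    concepts: Mapping[str, tuple[str, ...]]
    version: str | None = None

    def __post_init__(self) -> None:
        _check_segment(self.key, "vocabulary key")
        for local_id, parents in self.concepts.items():
            _check_segment(local_id, "local id")
            for p in parents:
                if p not in self.concepts:
                    raise GraphFormatError(
                        f"vocabulary {self.key!r}: local parent {p!r} of "
                        f"{local_id!r} is not a vocabulary concept"
                    )


# ---------------------------------------------------------------------------
# Concepts and the graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Concept:
    id: str
    term: str
    definition_status: str = PRIMITIVE
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not validate_sctid(self.id):
            raise MalformedIdError(f"invalid concept identifier: {self.id!r}")
        if self.definition_status not in (PRIMITIVE, FULLY_DEFINED):
            raise GraphFormatError(
                f"concept {self.id}: bad definition status "
                f"{self.definition_status!r}"
            )
        object.__setattr__(self, "parents", frozenset(self.parents))

    @property
    def primitive(self) -> bool:
        return self.definition_status == PRIMITIVE


ConceptRef = Union[str, ExternalConceptRef, "object"]


class ConceptGraph:
    """Acyclic is-a hierarchy with exactly one root.

    Internally a directed graph with child->parent edges; external concepts
    attached via :meth:`attach` live in the same graph under node keys of the
    form ``~key~local_id~`` and take part in subsumption and depth exactly
    like native concepts.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        self.vocabularies: dict[str, ExternalVocabulary] = {}
        self._g = nx.DiGraph()
        for c in concepts:
            if c.id in self.concepts:
                raise GraphFormatError(f"duplicate concept id {c.id}")
            self.concepts[c.id] = c
        roots = [c.id for c in self.concepts.values() if not c.parents]
        if len(roots) != 1:
            raise GraphFormatError(
                f"graph must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        for c in self.concepts.values():
            self._g.add_node(c.id)
            for p in c.parents:
                if p not in self.concepts:
                    raise GraphFormatError(
                        f"concept {c.id}: dangling parent {p}"
                    )
                self._g.add_edge(c.id, p)
        if not nx.is_directed_acyclic_graph(self._g):
            cyc = nx.find_cycle(self._g)
            raise CycleError(f"is-a relation contains a cycle: {cyc}")
        self._depth_cache: dict[str, int] = {}

    # -- resolution ---------------------------------------------------------

    def resolve(self, ref: ConceptRef) -> str:
        """Map a reference (id string, external ref, tilde token, or concept
        token) to its node key, raising if unresolvable."""
        key = _node_key(ref)
        if key in self._g:
            return key
        if key.startswith("~"):
            vkey = key[1:].split("~", 1)[0]
            if vkey not in self.vocabularies:
                raise UnknownVocabularyError(
                    f"vocabulary {vkey!r} is not attached to the graph"
                )
            raise UnknownConceptError(f"unknown external concept {key}")
        raise UnknownConceptError(f"unknown concept {key}")

    def __contains__(self, ref: ConceptRef) -> bool:
        try:
            self.resolve(ref)
            return True
        except (UnknownConceptError, UnknownVocabularyError):
            return False

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConceptGraph)
            and self.concepts == other.concepts
            and self.vocabularies == other.vocabularies
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def concept(self, ref: ConceptRef) -> Concept:
        key = self.resolve(ref)
        if key not in self.concepts:
            raise UnknownConceptError(f"{key} is an external concept")
        return self.concepts[key]

    def is_primitive(self, ref: ConceptRef) -> bool:
        # External concepts carry no logical definition: treat as primitive.
        key = self.resolve(ref)
        c = self.concepts.get(key)
        return True if c is None else c.primitive

    # -- hierarchy queries --------------------------------------------------

    def parents_of(self, ref: ConceptRef) -> frozenset[str]:
        return frozenset(self._g.successors(self.resolve(ref)))

    def children_of(self, ref: ConceptRef) -> frozenset[str]:
        return frozenset(self._g.predecessors(self.resolve(ref)))

    def ancestors_or_self(self, ref: ConceptRef) -> frozenset[str]:
        key = self.resolve(ref)
        return frozenset(nx.descendants(self._g, key)) | {key}

    def descendants_or_self(self, ref: ConceptRef) -> frozenset[str]:
        key = self.resolve(ref)
        return frozenset(nx.ancestors(self._g, key)) | {key}

    def depth(self, ref: ConceptRef) -> int:
        """Length of the longest is-a chain from the root to *ref*."""
        key = self.resolve(ref)
        cached = self._depth_cache.get(key)
        if cached is not None:
            return cached
        for node in reversed(list(nx.topological_sort(self._g))):
            # topological order of child->parent edges puts the root first
            # when reversed, so parents are always computed before children
            parents = list(self._g.successors(node))
            self._depth_cache[node] = (
                0 if not parents else 1 + max(self._depth_cache[p] for p in parents)
            )
        return self._depth_cache[key]

    # -- vocabulary attachment ---------------------------------------------

    def attach(self, vocab: ExternalVocabulary) -> "ConceptGraph":
        """Attach an external vocabulary beneath its attachment parent.

        Local roots become children of the attachment parent; local parent
        links are preserved beneath it.  Host concepts are never modified.
        Returns the graph to allow chaining.
        """
        if vocab.key in self.vocabularies:
            raise DuplicateVocabularyError(
                f"vocabulary {vocab.key!r} already attached"
            )
        if vocab.attachment_parent not in self.concepts:
            raise UnknownConceptError(
                f"attachment parent {vocab.attachment_parent} not in graph"
            )
        self.vocabularies[vocab.key] = vocab
        for local_id, parents in vocab.concepts.items():
            node = f"~{vocab.key}~{local_id}~"
            self._g.add_node(node)
            if parents:
                for p in parents:
                    self._g.add_edge(node, f"~{vocab.key}~{p}~")
            else:
                self._g.add_edge(node, vocab.attachment_parent)
        self._depth_cache.clear()
        return self


def _node_key(ref: ConceptRef) -> str:
    if isinstance(ref, ExternalConceptRef):
        return ref.node_key
    if isinstance(ref, str):
        if ref.startswith("~"):
            return parse_ref_token(ref).node_key
        return ref
    # duck-typed grammar ConceptToken (avoids a circular import)
    sct = getattr(ref, "sctid", None)
    if sct is not None:
        return sct
    ext = getattr(ref, "external", None)
    if ext is not None:
        return ext.node_key
    raise UnknownConceptError(f"cannot interpret concept reference {ref!r}")


def parse_ref_token(token: str) -> ExternalConceptRef:
    """Parse a standalone tilde token into an :class:`ExternalConceptRef`.

    Two interior segments give (key, id); three give (key, version, id).
    """
    if len(token) < 2 or not token.startswith("~") or not token.endswith("~"):
        raise ExternalRefError(
            f"external reference must start and end with '~': {token!r}", 0
        )
    parts = token[1:-1].split("~")
    if len(parts) == 2:
        return ExternalConceptRef(parts[0], parts[1])
    if len(parts) == 3:
        return ExternalConceptRef(parts[0], parts[2], version=parts[1])
    raise ExternalRefError(
        f"external reference needs 2 or 3 segments, got {len(parts)}: {token!r}",
        0,
    )


# ---------------------------------------------------------------------------
# Hierarchy operations
# ---------------------------------------------------------------------------


def is_subsumed_by(child: ConceptRef, ancestor: ConceptRef, graph: ConceptGraph) -> bool:
    """Reflexive-transitive subsumption: ancestor reachable from child via
    zero or more is-a edges."""
    c = graph.resolve(child)
    a = graph.resolve(ancestor)
    return c == a or nx.has_path(graph._g, c, a)


def attach_vocabulary(vocab: ExternalVocabulary, graph: ConceptGraph) -> ConceptGraph:
    """Functional spelling of :meth:`ConceptGraph.attach`."""
    return graph.attach(vocab)


def proximal_primitive_parent(
    concept: ConceptRef, graph: ConceptGraph
) -> frozenset[str]:
    """Nearest primitive ancestors-or-self of *concept*.

    A primitive concept is its own proximal primitive parent.  For a fully
    defined concept, each upward path is walked until its first primitive
    ancestor; the set of those ancestors is returned (a concept with several
    fully defined parents can have several).
    """
    start = graph.resolve(concept)
    memo: dict[str, frozenset[str]] = {}

    def walk(node: str) -> frozenset[str]:
        if node in memo:
            return memo[node]
        if graph.is_primitive(node):
            memo[node] = frozenset({node})
        else:
            out: set[str] = set()
            for p in graph.parents_of(node):
                out |= walk(p)
            memo[node] = frozenset(out)
        return memo[node]

    return walk(start)


def _id_sort_key(node: str) -> tuple:
    return (0, int(node)) if node.isdigit() else (1, node)


def resolve_disjunction(
    a: ConceptRef,
    b: ConceptRef,
    graph: ConceptGraph,
    max_depth_gap: int = 2,
) -> str:
    """Map an "A or B" label to a shared ancestor, or declare it unmapped.

    The deepest common ancestors of *a* and *b* are computed (depth = longest
    chain from the root).  If the nearer of the two concepts is within
    ``max_depth_gap`` is-a levels of that ancestor, the ancestor is returned
    (ties broken by smallest identifier); otherwise the label is considered
    too semantically broad and ``"unmapped"`` is returned.
    """
    if max_depth_gap < 0:
        raise ValueError("max_depth_gap must be >= 0")
    ka, kb = graph.resolve(a), graph.resolve(b)
    common = graph.ancestors_or_self(ka) & graph.ancestors_or_self(kb)
    if not common:
        return UNMAPPED
    best_depth = max(graph.depth(c) for c in common)
    gap = min(graph.depth(ka), graph.depth(kb)) - best_depth
    if gap > max_depth_gap:
        return UNMAPPED
    deepest = [c for c in common if graph.depth(c) == best_depth]
    return min(deepest, key=_id_sort_key)


# ---------------------------------------------------------------------------
# Selection criteria for external terminologies
# ---------------------------------------------------------------------------

CRITERIA = (
    "gap_covered",
    "concept_based",
    "hierarchical",
    "versioned",
    "recognized_standard",
)


@dataclass(frozen=True)
class SelectionCriteriaReport:
    """Outcome of the five-point eligibility checklist for integrating an
    external terminology: it must cover an identified gap, be concept-based
    (not a thesaurus), be hierarchical, be versioned, and be a recognized
    standard.  A terminology is accepted only if all five hold."""

    verdicts: Mapping[str, bool]
    notes: Mapping[str, str] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return all(self.verdicts[c] for c in CRITERIA)

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        return tuple(c for c in CRITERIA if not self.verdicts[c])


def evaluate_selection_criteria(
    *,
    gap_covered: bool,
    concept_based: bool,
    hierarchical: bool,
    versioned: bool,
    recognized_standard: bool,
    notes: Mapping[str, str] | None = None,
) -> SelectionCriteriaReport:
    verdicts = {
        "gap_covered": gap_covered,
        "concept_based": concept_based,
        "hierarchical": hierarchical,
        "versioned": versioned,
        "recognized_standard": recognized_standard,
    }
    return SelectionCriteriaReport(verdicts=verdicts, notes=dict(notes or {}))


# ---------------------------------------------------------------------------
# I/O: graph TSV and vocabulary registry JSON
# ---------------------------------------------------------------------------

_GRAPH_HEADER = "id\tterm\tdefinition_status\tparents"


def read_graph(path: Union[str, Path]) -> ConceptGraph:
    """Read a concept graph from flat TSV:
    ``id<TAB>term<TAB>definition_status<TAB>parent1|parent2|...``"""
    concepts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line == _GRAPH_HEADER):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cid, term, status, parents = fields
            if not validate_sctid(cid):
                raise MalformedIdError(f"{path}:{lineno}: invalid id {cid!r}")
            concepts.append(
                Concept(
                    id=cid,
                    term=term,
                    definition_status=status,
                    parents=frozenset(p for p in parents.split("|") if p),
                )
            )
    return ConceptGraph(concepts)


def write_graph(graph: ConceptGraph, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_GRAPH_HEADER + "\n")
        for cid in sorted(graph.concepts, key=int):
            c = graph.concepts[cid]
            fh.write(
                f"{c.id}\t{c.term}\t{c.definition_status}\t"
                f"{'|'.join(sorted(c.parents, key=int))}\n"
            )


def _vocab_to_doc(vocab: ExternalVocabulary) -> dict:
    return {
        "key": vocab.key,
        "version": vocab.version,
        "attachment_parent": vocab.attachment_parent,
        "concepts": [
            {"id": lid, "parents": sorted(parents)}
            for lid, parents in sorted(vocab.concepts.items())
        ],
    }


def _vocab_from_doc(doc: Mapping) -> ExternalVocabulary:
    return ExternalVocabulary(
        key=doc["key"],
        version=doc.get("version"),
        attachment_parent=doc["attachment_parent"],
        concepts={
            c["id"]: tuple(c.get("parents", ())) for c in doc["concepts"]
        },
    )


def read_registry(path: Union[str, Path]) -> dict[str, ExternalVocabulary]:
    """Read a vocabulary registry (a JSON object or list of objects with
    keys ``key``, ``version``, ``attachment_parent``, ``concepts``)."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    docs = data if isinstance(data, list) else [data]
    registry: dict[str, ExternalVocabulary] = {}
    for doc in docs:
        vocab = _vocab_from_doc(doc)
        if vocab.key in registry:
            raise DuplicateVocabularyError(
                f"duplicate vocabulary key {vocab.key!r} in registry"
            )
        registry[vocab.key] = vocab
    return registry


def write_registry(
    vocabularies: Iterable[ExternalVocabulary], path: Union[str, Path]
) -> None:
    docs = [_vocab_to_doc(v) for v in vocabularies]
    payload = docs[0] if len(docs) == 1 else docs
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
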