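"""Deterministic, seedable generators for fixture ontologies, expressions
and corpora.

Everything every other module consumes can be generated here with no
download and no licensed content: a fixture concept graph shaped like the
real terminology, expression strings guaranteed valid under a given rule
set, corpora whose per-source profile emulates a large hospital
data-warehouse (the shipped default profile reproduces the per-source
element/instance counts of the reference corpus this package's statistics
module is modelled on), and mutated expressions with known expected error
classes for negative testing.

Generation is fully deterministic under ``(params, seed)``; each source of
a corpus draws from its own sub-seed so sources are independent.

Two corpus modes exist:

* ``exact`` — extension flags and instance totals are assigned by
  deterministic quota, so configured counts (and hence summary
  percentages) are reproduced bit-exactly;
* ``sampled`` — extension flags are Bernoulli draws and instance counts
  log-uniform, for statistical properties (the extended count is then
  Binomial(n, p)).
"""

from __future__ import annotations

import datetime as _dt
import math
import random
import re
from dataclasses import dataclass, field, replace

from . import fixtures
from .concept_model import Concept, ConceptGraph, PRIMITIVE, FULLY_DEFINED, synthetic_sctid
from .corpus import CorpusRecord
from .errors import FdgError
from .grammar import parse, serialize
from .mrcm import (
    ConcreteType,
    Descendant,
    DescendantOrSelf,
    ExternalCluster,
    MrcmRuleSet,
    SelfConcept,
    Union_,
    extend,
    validate,
)

__all__ = [
    "SourceSpec",
    "REFERENCE_SOURCE_PROFILE",
    "GeneratorParams",
    "FixtureContext",
    "make_fixture_graph",
    "make_default_context",
    "make_expressions",
    "make_corpus",
    "make_mutations",
]


@dataclass(frozen=True)
class SourceSpec:
    """Per-source corpus shape: how many data elements, how many of them
    use grammar extensions, and the instance totals they cover."""

    name: str
    n_elements: int
    n_extended: int
    total_instances: int
    extended_instances: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_extended <= self.n_elements:
            raise ValueError(f"{self.name}: n_extended out of range")
        if min(self.total_instances, self.extended_instances) < 0:
            raise ValueError(f"{self.name}: negative instance totals")

    @property
    def extension_fraction(self) -> float:
        return self.n_extended / self.n_elements if self.n_elements else 0.0


#: Default per-source profile: the published per-source element and
#: instance counts of the reference corpus (a decade of semantic
#: representation over a hospital data lake) that the summary statistics
#: emulate.
REFERENCE_SOURCE_PROFILE: tuple[SourceSpec, ...] = (
    SourceSpec("Administrative stay", 1172, 2, 78_020_550, 131_832),
    SourceSpec("Anesthesiology", 2139, 11, 117_419_522, 1_275_337),
    SourceSpec("Medical devices", 699, 235, 4_926_815, 1_140_820),
    SourceSpec("Formularies", 51_322, 3925, 1_641_633_208, 119_941_273),
    SourceSpec("ICU", 6934, 157, 6_656_119_500, 367_548),
    SourceSpec("Laboratory", 7231, 72, 935_678_204, 250_617_656),
    SourceSpec("Observations", 2784, 1, 2_440_891_370, 1003),
    SourceSpec("Patient problems", 25_233, 72, 1_587_507, 976),
    SourceSpec("Prescription", 9837, 0, 26_805_381, 0),
    SourceSpec("Radiology", 2586, 2, 8_562_371, 2),
    SourceSpec("Procedures", 8001, 23, 1_452_038_108, 8_934_163),
)

#: Hierarchies that receive generated content concepts.
_CONTENT_HIERARCHIES = (
    "Clinical finding",
    "Procedure",
    "Body structure",
    "Organism",
    "Observable entity",
    "Physical object",
    "Qualifier value",
    "Situation with explicit context",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the generators.

    Defaults mirror the reference corpus: just under half of all unique
    expressions are postcoordinated (``pce_fraction`` 0.469 = 18370/39168)
    and 3.75% of data elements use extensions (``extension_fraction``
    4500/119941); the per-source profile is the published one.
    """

    seed: int = 0
    n_concepts: int = 24  # generated concepts per content hierarchy
    primitive_fraction: float = 0.5
    max_parents: int = 2
    pce_fraction: float = 18370 / 39168
    extension_fraction: float = 4500 / 119_941
    sources: tuple[SourceSpec, ...] = REFERENCE_SOURCE_PROFILE
    instance_count_bounds: tuple[int, int] = (1, 1_000_000)  # log-uniform

    def __post_init__(self) -> None:
        for name in ("primitive_fraction", "pce_fraction", "extension_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_concepts < 0 or self.max_parents < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.instance_count_bounds
        if not 1 <= lo <= hi:
            raise ValueError("instance_count_bounds must satisfy 1 <= lo <= hi")


def _sub_rng(seed: int, label: str) -> random.Random:
    return random.Random(f"{seed}:{label}")


# ---------------------------------------------------------------------------
# Fixture graph
# ---------------------------------------------------------------------------


def make_fixture_graph(params: GeneratorParams | None = None) -> ConceptGraph:
    """Fixture ontology: the fixed skeleton (root, top-level hierarchies,
    extension attributes with their published identifiers, named demo
    concepts) plus ``n_concepts`` generated concepts per content hierarchy.

    Generated concepts draw up to ``max_parents`` parents from earlier
    concepts of the same hierarchy and are primitive with probability
    ``primitive_fraction``.  All identifiers carry computed check digits;
    identical params and seed give identical graphs.
    """
    params = params or GeneratorParams()
    concepts = fixtures.skeleton_concepts()
    used = {c.id for c in concepts}
    rng = _sub_rng(params.seed, "graph")
    for hierarchy in _CONTENT_HIERARCHIES:
        root_id = fixtures.HIERARCHIES[hierarchy]
        pool = [root_id]
        for i in range(params.n_concepts):
            cid = _fresh_id(rng, used)
            n_parents = min(len(pool), 1 + rng.randrange(params.max_parents))
            parents = frozenset(rng.sample(pool, n_parents))
            status = (
                PRIMITIVE
                if rng.random() < params.primitive_fraction
                else FULLY_DEFINED
            )
            concepts.append(
                Concept(cid, f"Synthetic {hierarchy.lower()} {i}", status, parents)
            )
            pool.append(cid)
            used.add(cid)
    return ConceptGraph(concepts)


def _fresh_id(rng: random.Random, used: set[str]) -> str:
    while True:
        body = str(rng.randrange(10**6, 10**9))  # 7-9 digits incl. check digit
        cid = synthetic_sctid(body)
        if cid not in used:
            return cid


@dataclass(frozen=True)
class FixtureContext:
    """Everything the other modules need, wired together: the fixture graph
    with the Pango vocabulary attached, and the base / extended rule sets
    (the extended set includes the external-strain rule)."""

    graph: ConceptGraph
    base_rules: MrcmRuleSet
    rules: MrcmRuleSet


def make_default_context(params: GeneratorParams | None = None) -> FixtureContext:
    params = params or GeneratorParams()
    graph = make_fixture_graph(params)
    graph.attach(fixtures.pango_vocabulary())
    rules = extend(
        fixtures.extended_rules(),
        [fixtures.strain_rule_delta()],
        name="extended+strain",
    )
    return FixtureContext(graph=graph, base_rules=fixtures.base_rules(), rules=rules)


# ---------------------------------------------------------------------------
# Expression sampling
# ---------------------------------------------------------------------------


class _ExpressionSampler:
    """Samples expression strings guaranteed valid under a rule set.

    Sampling inverts validation: a rule is drawn first, then a focus from
    its domain and a value from its range, so every emitted expression
    validates by construction (self-checked in tests, not at run time).
    """

    def __init__(
        self,
        graph: ConceptGraph,
        rules: MrcmRuleSet,
        extension_attributes: frozenset[str] = fixtures.EXTENSION_ATTRIBUTE_IDS,
    ):
        self.graph = graph
        self.rules = rules
        self.extension_attributes = extension_attributes
        self._native = [n for n in graph if not n.startswith("~")]
        self._domain_cache: dict = {}
        self._range_cache: dict = {}
        self.core_rules = []
        self.extension_rules = []
        for rule in rules.rules:
            if not self._domain_concepts(rule.domain):
                continue
            if rule.attribute in extension_attributes or self._has_external(
                rule.range
            ):
                self.extension_rules.append(rule)
            elif self._range_options(rule.range, allow_external=False) is not None:
                self.core_rules.append(rule)
        self._content_pool = [
            n
            for n in self._native
            if n
            not in (fixtures.ROOT, fixtures.ATTRIBUTE)
            and fixtures.ATTRIBUTE not in self.graph.ancestors_or_self(n)
        ]

    @staticmethod
    def _branches(constraint):
        return constraint.branches if isinstance(constraint, Union_) else (constraint,)

    def _has_external(self, constraint) -> bool:
        return any(isinstance(b, ExternalCluster) for b in self._branches(constraint))

    def _domain_concepts(self, constraint) -> list[str]:
        key = constraint
        if key not in self._domain_cache:
            out: list[str] = []
            for b in self._branches(constraint):
                if isinstance(b, DescendantOrSelf):
                    out += sorted(
                        n
                        for n in self.graph.descendants_or_self(b.concept_id)
                        if not n.startswith("~")
                    )
                elif isinstance(b, Descendant):
                    out += sorted(
                        n
                        for n in self.graph.descendants_or_self(b.concept_id)
                        if n != b.concept_id and not n.startswith("~")
                    )
                elif isinstance(b, SelfConcept):
                    out.append(b.concept_id)
            self._domain_cache[key] = out
        return self._domain_cache[key]

    def _range_options(self, constraint, allow_external: bool):
        """List of (kind, payload) value options, or None if empty.

        kind is 'concept', 'external', 'number' or 'date'."""
        key = (constraint, allow_external)
        if key not in self._range_cache:
            out = []
            for b in self._branches(constraint):
                if isinstance(b, (DescendantOrSelf, Descendant, SelfConcept)):
                    for n in self._domain_concepts(b):
                        out.append(("concept", n))
                elif isinstance(b, ExternalCluster):
                    if allow_external and b.vocabulary_key in self.graph.vocabularies:
                        vocab = self.graph.vocabularies[b.vocabulary_key]
                        for lid in sorted(vocab.concepts):
                            out.append(
                                ("external", f"~{b.vocabulary_key}~{lid}~")
                            )
                elif isinstance(b, ConcreteType):
                    if b.kind == "number":
                        out.append(("number", None))
                    elif b.kind == "date":
                        out.append(("date", None))
                    # free-text string ranges are not sampled
            self._range_cache[key] = out or None
        return self._range_cache[key]

    def _sample_value(self, rule, rng: random.Random, allow_external: bool) -> str:
        options = self._range_options(rule.range, allow_external)
        kind, payload = rng.choice(options)
        if kind == "concept" or kind == "external":
            return payload
        if kind == "number":
            return f"#{rng.randrange(1, 500)}"
        day = _dt.date(2015, 1, 1) + _dt.timedelta(days=rng.randrange(4000))
        return f'"{day.isoformat()}"'

    def sample(self, kind: str, rng: random.Random) -> str:
        """One expression string of the requested class:
        'precoordinated', 'pce', or 'extended'."""
        if kind == "precoordinated":
            return rng.choice(self._content_pool)
        pool = self.extension_rules if kind == "extended" else self.core_rules
        if not pool:
            raise FdgError(f"no rules available to sample {kind} expressions")
        allow_external = kind == "extended"
        rule = rng.choice(pool)
        focus = rng.choice(self._domain_concepts(rule.domain))
        refinements = [(rule, self._sample_value(rule, rng, allow_external))]
        # occasionally add a second, compatible refinement
        if rng.random() < 0.3:
            compatible = [
                r
                for r in (self.core_rules + (pool if allow_external else []))
                if focus in self._domain_concepts(r.domain)
                and r.attribute != rule.attribute
                and self._range_options(r.range, allow_external)
            ]
            if compatible:
                extra = rng.choice(compatible)
                refinements.append(
                    (extra, self._sample_value(extra, rng, allow_external))
                )
        parts, groups = [], []
        for r, value in refinements:
            text = f"{r.attribute} = {value}"
            if r.groupable and rng.random() < 0.2:
                groups.append(f"{{ {text} }}")
            else:
                parts.append(text)
        body = ", ".join(parts)
        tail = " ".join(filter(None, [body] + groups))
        return f"{focus} : {tail}"


def make_expressions(
    graph: ConceptGraph,
    rules: MrcmRuleSet,
    n: int,
    params: GeneratorParams | None = None,
    extension_attributes: frozenset[str] = fixtures.EXTENSION_ATTRIBUTE_IDS,
) -> list[str]:
    """Generate *n* expression strings, each valid under *rules*.

    ``pce_fraction`` is the expected share of postcoordinated expressions
    and ``extension_fraction`` the expected share using extensions; since
    extended expressions are themselves postcoordinated, the extension
    share is capped by the postcoordinated share (so ``pce_fraction=0``
    yields only precoordinated expressions and ``extension_fraction=1``
    yields only extended ones).
    """
    params = params or GeneratorParams()
    sampler = _ExpressionSampler(graph, rules, extension_attributes)
    rng = _sub_rng(params.seed, "expressions")
    p_ext = params.extension_fraction
    p_pce = max(params.pce_fraction, p_ext)
    if not sampler.extension_rules:
        p_ext = 0.0
    if not sampler.core_rules:
        p_pce = p_ext
    out = []
    for _ in range(n):
        u = rng.random()
        if u < p_ext:
            kind = "extended"
        elif u < p_pce:
            kind = "pce"
        else:
            kind = "precoordinated"
        out.append(sampler.sample(kind, rng))
    return out


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _quota_split(total: int, n: int) -> list[int]:
    """Deterministically split *total* into *n* non-negative parts whose sum
    is exactly *total* (first ``total % n`` parts get one extra)."""
    if n == 0:
        return []
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


def make_corpus(
    graph: ConceptGraph,
    rules: MrcmRuleSet,
    params: GeneratorParams | None = None,
    mode: str = "exact",
    extension_attributes: frozenset[str] = fixtures.EXTENSION_ATTRIBUTE_IDS,
) -> list[CorpusRecord]:
    """Generate an annotated corpus following ``params.sources``.

    ``exact`` mode reproduces each source's configured element, extension
    and instance counts bit-exactly (quota assignment); ``sampled`` mode
    draws extension flags Bernoulli(extension_fraction of the source) and
    instance counts log-uniformly within ``params.instance_count_bounds``.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError(f"mode must be 'exact' or 'sampled', got {mode!r}")
    params = params or GeneratorParams()
    sampler = _ExpressionSampler(graph, rules, extension_attributes)
    records: list[CorpusRecord] = []
    for spec in params.sources:
        if spec.n_elements == 0:
            continue
        rng = _sub_rng(params.seed, f"corpus:{spec.name}")
        n = spec.n_elements
        if mode == "exact":
            extended_idx = set(rng.sample(range(n), spec.n_extended))
        else:
            p = spec.extension_fraction
            extended_idx = {i for i in range(n) if rng.random() < p}
        n_ext = len(extended_idx)
        ext_counts = iter(_quota_split(spec.extended_instances, n_ext))
        other_counts = iter(
            _quota_split(spec.total_instances - spec.extended_instances, n - n_ext)
        )
        lo, hi = params.instance_count_bounds
        for i in range(n):
            extended = i in extended_idx
            if extended:
                expr = sampler.sample("extended", rng)
            elif rng.random() < params.pce_fraction and sampler.core_rules:
                expr = sampler.sample("pce", rng)
            else:
                expr = sampler.sample("precoordinated", rng)
            if mode == "exact":
                count = next(ext_counts) if extended else next(other_counts)
            else:
                count = int(
                    math.exp(rng.uniform(math.log(lo), math.log(hi)))
                )
            records.append(
                CorpusRecord(
                    source=spec.name,
                    element_id=f"{spec.name[:3].upper().replace(' ', '_')}-{i:06d}",
                    expression=expr,
                    instance_count=count,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Mutation generator (negative tests)
# ---------------------------------------------------------------------------

_SCTID_RUN = re.compile(r"\d{6,18}")


def _outside_quotes(text: str, span: tuple[int, int]) -> bool:
    return text.count('"', 0, span[0]) % 2 == 0


def _mutate_drop_tilde(expr: str, rng: random.Random):
    if "~" not in expr:
        return None
    i = expr.rindex("~")
    return expr[:i] + expr[i + 1:], "syntax"


def _mutate_check_digit(expr: str, rng: random.Random):
    runs = [
        m
        for m in _SCTID_RUN.finditer(expr)
        if _outside_quotes(expr, m.span())
        and (m.start() == 0 or expr[m.start() - 1] not in "#.~")
    ]
    if not runs:
        return None
    m = rng.choice(runs)
    last = m.group()[-1]
    bumped = str((int(last) + 1) % 10)
    return expr[: m.end() - 1] + bumped + expr[m.end():], "malformed_id"


def _mutate_drop_equals(expr: str, rng: random.Random):
    if "=" not in expr:
        return None
    i = expr.index("=")
    return expr[:i] + expr[i + 1:], "syntax"


def _mutate_empty_group(expr: str, rng: random.Random):
    open_ = expr.find("{")
    if open_ < 0:
        return None
    close = expr.find("}", open_)
    if close < 0:
        return None
    return expr[: open_ + 1] + " " + expr[close:], "syntax"


_MUTATORS = (
    _mutate_drop_tilde,
    _mutate_check_digit,
    _mutate_drop_equals,
    _mutate_empty_group,
)


def make_mutations(
    expr_strings: list[str], n: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Produce *n* corrupted expressions with their expected error class.

    Each mutant applies exactly one corruption — dropping the closing tilde
    of an external reference, bumping an identifier's check digit, deleting
    an ``=``, or emptying a group — and is paired with the error class a
    parser must raise: ``"syntax"`` or ``"malformed_id"``.
    """
    for s in expr_strings:
        parse(s)  # inputs must themselves be well-formed
    rng = random.Random(f"{seed}:mutations")
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        expr = rng.choice(expr_strings)
        mutator = rng.choice(_MUTATORS)
        result = mutator(expr, rng)
        if result is not None:
            out.append(result)
    if len(out) < n:
        raise FdgError("input expressions admit none of the mutation kinds")
    return out
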