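"""The machine-readable concept model (MRCM): constraints, rules, and the
expression validation engine.

An MRCM rule set is a whitelist: each rule states that a given *attribute*
may refine concepts satisfying its *domain* constraint with values
satisfying its *range* constraint, with a cardinality and a groupability
flag.  An attribute with no applicable rule is not permitted at all.
Extension of the model is strictly permissive: domains and ranges are
widened by taking unions with new constraints, and new attribute rules are
added, so every expression valid before an extension stays valid after it.

Constraints are written in a small textual language::

    << 404684003              descendant-or-self
    <  71388002               strict descendant
    404684003                 the concept itself
    ext:Pango                 any external reference of that vocabulary
    num | str | date          concrete-value types
    << 404684003 OR << 71388002   union

The `date` type matches both explicit date values and quoted strings that
parse under ISO 8601 — whether a quoted literal is a date is decided here,
by the rule that constrains the attribute, not by the expression lexer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from .concept_model import (
    ConceptGraph,
    ExternalConceptRef,
    is_subsumed_by,
    validate_sctid,
)
from .errors import (
    ConstraintSyntaxError,
    RuleError,
    UnknownConceptError,
    UnknownVocabularyError,
)
from .grammar import (
    AttributeValue,
    ConceptToken,
    ConcreteValue,
    Expression,
    Refinement,
    parse_iso_date,
)

__all__ = [
    "ConstraintExpr",
    "DescendantOrSelf",
    "Descendant",
    "SelfConcept",
    "ExternalCluster",
    "ConcreteType",
    "Union_",
    "parse_constraint",
    "AttributeRule",
    "MrcmRuleSet",
    "Violation",
    "ValidationReport",
    "evaluate_constraint",
    "validate",
    "extend",
    "AddRule",
    "WidenDomain",
    "WidenRange",
    "read_rules",
    "write_rules",
]

OPTIONAL_MANY = "optional-many"
OPTIONAL_ONE = "optional-one"
REQUIRED_ONE = "required-one"
_CARDINALITIES = (OPTIONAL_MANY, OPTIONAL_ONE, REQUIRED_ONE)


# ---------------------------------------------------------------------------
# Constraint expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescendantOrSelf:
    concept_id: str

    def to_text(self) -> str:
        return f"<< {self.concept_id}"


@dataclass(frozen=True)
class Descendant:
    concept_id: str

    def to_text(self) -> str:
        return f"< {self.concept_id}"


@dataclass(frozen=True)
class SelfConcept:
    concept_id: str

    def to_text(self) -> str:
        return self.concept_id


@dataclass(frozen=True)
class ExternalCluster:
    vocabulary_key: str

    def to_text(self) -> str:
        return f"ext:{self.vocabulary_key}"


@dataclass(frozen=True)
class ConcreteType:
    kind: str  # number | string | date

    def to_text(self) -> str:
        return {"number": "num", "string": "str", "date": "date"}[self.kind]


@dataclass(frozen=True)
class Union_:
    branches: tuple["ConstraintExpr", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        if len(self.branches) < 2:
            raise ConstraintSyntaxError("a union needs at least two branches")

    def to_text(self) -> str:
        return " OR ".join(b.to_text() for b in self.branches)


ConstraintExpr = Union[
    DescendantOrSelf, Descendant, SelfConcept, ExternalCluster, ConcreteType, Union_
]

_TYPE_TOKENS = {"num": "number", "str": "string", "date": "date"}


def _parse_branch(token: str) -> ConstraintExpr:
    token = token.strip()
    if token.startswith("<<"):
        cid = token[2:].strip()
        if not validate_sctid(cid):
            raise ConstraintSyntaxError(f"bad concept id in constraint: {token!r}")
        return DescendantOrSelf(cid)
    if token.startswith("<"):
        cid = token[1:].strip()
        if not validate_sctid(cid):
            raise ConstraintSyntaxError(f"bad concept id in constraint: {token!r}")
        return Descendant(cid)
    if token.startswith("ext:"):
        key = token[4:].strip()
        if not key:
            raise ConstraintSyntaxError("ext: constraint needs a vocabulary key")
        return ExternalCluster(key)
    if token in _TYPE_TOKENS:
        return ConcreteType(_TYPE_TOKENS[token])
    if validate_sctid(token):
        return SelfConcept(token)
    raise ConstraintSyntaxError(f"cannot parse constraint token {token!r}")


def parse_constraint(text: str) -> ConstraintExpr:
    """Parse the textual constraint language (see module docstring)."""
    parts = [p for p in text.split(" OR ")]
    if not text.strip():
        raise ConstraintSyntaxError("empty constraint")
    branches = [_parse_branch(p) for p in parts]
    return branches[0] if len(branches) == 1 else Union_(tuple(branches))


def union_of(a: ConstraintExpr, b: ConstraintExpr) -> ConstraintExpr:
    """Union of two constraints, flattening nested unions and dropping
    duplicate branches while preserving order."""
    def flat(c: ConstraintExpr) -> tuple:
        return c.branches if isinstance(c, Union_) else (c,)

    seen: list[ConstraintExpr] = []
    for branch in flat(a) + flat(b):
        if branch not in seen:
            seen.append(branch)
    return seen[0] if len(seen) == 1 else Union_(tuple(seen))


def _concept_refs_of(value) -> list:
    """Concept references a constraint should be checked against: a nested
    expression stands for its focus concepts."""
    if isinstance(value, Expression):
        return [t.ref for t in value.focus]
    if isinstance(value, ConceptToken):
        return [value.ref]
    if isinstance(value, (str, ExternalConceptRef)):
        return [value]
    return []  # concrete values have no concept reading


def evaluate_constraint(
    constraint: ConstraintExpr,
    value: Union[AttributeValue, str, ExternalConceptRef],
    graph: ConceptGraph,
) -> bool:
    """Does *value* satisfy *constraint* over *graph*?

    Concept constraints are evaluated by subsumption (a nested expression
    must satisfy them through every focus concept); ``ext:`` matches any
    reference of that vocabulary; concrete-type constraints match literal
    values (``date`` also matches strings parsing under ISO 8601).
    Unresolvable references raise UnknownConceptError /
    UnknownVocabularyError.
    """
    if isinstance(constraint, Union_):
        return any(evaluate_constraint(b, value, graph) for b in constraint.branches)
    if isinstance(constraint, ConcreteType):
        if not isinstance(value, ConcreteValue):
            return False
        if constraint.kind == value.kind:
            return True
        if constraint.kind == "date" and value.kind == "string":
            return parse_iso_date(value.value) is not None
        return False
    refs = _concept_refs_of(value)
    if not refs:
        return False
    if isinstance(constraint, ExternalCluster):
        if any(
            isinstance(r, ExternalConceptRef)
            and r.vocabulary_key == constraint.vocabulary_key
            for r in refs
        ):
            if constraint.vocabulary_key not in graph.vocabularies:
                raise UnknownVocabularyError(
                    f"vocabulary {constraint.vocabulary_key!r} not attached"
                )
            return all(
                isinstance(r, ExternalConceptRef)
                and r.vocabulary_key == constraint.vocabulary_key
                for r in refs
            )
        return False
    if isinstance(constraint, DescendantOrSelf):
        return all(is_subsumed_by(r, constraint.concept_id, graph) for r in refs)
    if isinstance(constraint, Descendant):
        return all(
            graph.resolve(r) != constraint.concept_id
            and is_subsumed_by(r, constraint.concept_id, graph)
            for r in refs
        )
    if isinstance(constraint, SelfConcept):
        return all(graph.resolve(r) == constraint.concept_id for r in refs)
    raise TypeError(f"unknown constraint {constraint!r}")


# ---------------------------------------------------------------------------
# Rules and rule sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttributeRule:
    attribute: str  # attribute concept id (or an external-ref token)
    domain: ConstraintExpr
    range: ConstraintExpr
    cardinality: str = OPTIONAL_MANY
    groupable: bool = True

    def __post_init__(self) -> None:
        if self.cardinality not in _CARDINALITIES:
            raise RuleError(f"bad cardinality {self.cardinality!r}")


@dataclass(frozen=True)
class MrcmRuleSet:
    name: str
    version: str
    rules: tuple[AttributeRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        seen = set()
        for r in self.rules:
            key = (r.attribute, r.domain)
            if key in seen:
                raise RuleError(
                    f"duplicate rule for attribute {r.attribute} with the "
                    "same domain"
                )
            seen.add(key)

    def rules_for(self, attribute_id: str) -> tuple[AttributeRule, ...]:
        return tuple(r for r in self.rules if r.attribute == attribute_id)

    @property
    def attribute_ids(self) -> frozenset[str]:
        return frozenset(r.attribute for r in self.rules)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

UNKNOWN_CONCEPT = "UNKNOWN_CONCEPT"
ATTRIBUTE_NOT_PERMITTED = "ATTRIBUTE_NOT_PERMITTED"
DOMAIN_MISMATCH = "DOMAIN_MISMATCH"
RANGE_MISMATCH = "RANGE_MISMATCH"
BAD_CONCRETE_TYPE = "BAD_CONCRETE_TYPE"
CARDINALITY = "CARDINALITY"
UNKNOWN_VOCABULARY = "UNKNOWN_VOCABULARY"


@dataclass(frozen=True)
class Violation:
    code: str
    path: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def verdict(self) -> str:
        return "valid" if not self.violations else "invalid"

    @property
    def valid(self) -> bool:
        return not self.violations

    def codes(self) -> frozenset[str]:
        return frozenset(v.code for v in self.violations)


def _attr_key(token: ConceptToken) -> str:
    return token.sctid if token.sctid is not None else token.external.node_key


def _check_token(token: ConceptToken, graph: ConceptGraph, path: str, out: list) -> bool:
    try:
        graph.resolve(token.ref)
        return True
    except UnknownVocabularyError as exc:
        out.append(Violation(UNKNOWN_VOCABULARY, path, str(exc)))
    except UnknownConceptError as exc:
        out.append(Violation(UNKNOWN_CONCEPT, path, str(exc)))
    return False


def validate(
    expr: Expression, rules: MrcmRuleSet, graph: ConceptGraph
) -> ValidationReport:
    """Validate an expression against a rule set over a concept graph.

    Every refinement (grouped or not) must be licensed by some rule for its
    attribute whose domain is satisfied by *every* focus concept and whose
    range is satisfied by the value.  Nested expressions are validated
    recursively against their own focus.  Cardinality is checked per
    attribute per scope (the ungrouped refinements form one scope, each
    group its own).  All violations are reported, not only the first.
    """
    out: list[Violation] = []
    _validate_into(expr, rules, graph, "", out)
    return ValidationReport(tuple(out))


def _validate_into(
    expr: Expression,
    rules: MrcmRuleSet,
    graph: ConceptGraph,
    prefix: str,
    out: list[Violation],
) -> None:
    focus_ok = True
    for i, token in enumerate(expr.focus):
        focus_ok &= _check_token(token, graph, f"{prefix}focus[{i}]", out)

    def check_refinement(r: Refinement, path: str, grouped: bool) -> None:
        if not _check_token(r.attribute, graph, f"{path}.attribute", out):
            return
        value = r.value
        if isinstance(value, Expression):
            _validate_into(value, rules, graph, f"{path}.value.", out)
            if any(v.path.startswith(f"{path}.value.") for v in out):
                return
        elif isinstance(value, ConceptToken):
            if not _check_token(value, graph, f"{path}.value", out):
                return
        attr_id = _attr_key(r.attribute)
        candidates = [
            rule for rule in rules.rules_for(attr_id) if rule.groupable or not grouped
        ]
        if not candidates:
            where = " inside a group" if grouped else ""
            out.append(
                Violation(
                    ATTRIBUTE_NOT_PERMITTED,
                    path,
                    f"no rule permits attribute {attr_id}{where}",
                )
            )
            return
        if not focus_ok:
            return  # domain cannot be judged against unresolved focus
        applicable = []
        for rule in candidates:
            try:
                if all(
                    evaluate_constraint(rule.domain, t.ref, graph)
                    for t in expr.focus
                ):
                    applicable.append(rule)
            except (UnknownConceptError, UnknownVocabularyError):
                continue
        if not applicable:
            out.append(
                Violation(
                    DOMAIN_MISMATCH,
                    path,
                    f"attribute {attr_id}: no rule domain covers every "
                    "focus concept",
                )
            )
            return
        for rule in applicable:
            try:
                if evaluate_constraint(rule.range, value, graph):
                    return
            except UnknownVocabularyError as exc:
                out.append(Violation(UNKNOWN_VOCABULARY, f"{path}.value", str(exc)))
                return
            except UnknownConceptError as exc:
                out.append(Violation(UNKNOWN_CONCEPT, f"{path}.value", str(exc)))
                return
        if isinstance(value, ConcreteValue):
            out.append(
                Violation(
                    BAD_CONCRETE_TYPE,
                    f"{path}.value",
                    f"attribute {attr_id}: literal of kind {value.kind} not "
                    "in range",
                )
            )
        else:
            out.append(
                Violation(
                    RANGE_MISMATCH,
                    f"{path}.value",
                    f"attribute {attr_id}: value outside permitted range",
                )
            )

    for i, r in enumerate(expr.ungrouped):
        check_refinement(r, f"{prefix}ungrouped[{i}]", grouped=False)
    for gi, group in enumerate(expr.groups):
        for ri, r in enumerate(group):
            check_refinement(r, f"{prefix}groups[{gi}][{ri}]", grouped=True)

    _check_cardinality(expr, rules, graph, prefix, focus_ok, out)


def _check_cardinality(
    expr: Expression,
    rules: MrcmRuleSet,
    graph: ConceptGraph,
    prefix: str,
    focus_ok: bool,
    out: list[Violation],
) -> None:
    scopes: list[tuple[list[str], Sequence[Refinement]]] = [
        ([f"{prefix}ungrouped[{i}]" for i in range(len(expr.ungrouped))],
         expr.ungrouped)
    ]
    scopes += [
        ([f"{prefix}groups[{gi}][{i}]" for i in range(len(g))], g)
        for gi, g in enumerate(expr.groups)
    ]
    seen_attrs: set[str] = set()
    for paths, refinements in scopes:
        occurrences: dict[str, list[str]] = {}
        for path, r in zip(paths, refinements):
            key = _attr_key(r.attribute)
            occurrences.setdefault(key, []).append(path)
            seen_attrs.add(key)
        for attr_id, where in occurrences.items():
            for rule in rules.rules_for(attr_id):
                if rule.cardinality in (OPTIONAL_ONE, REQUIRED_ONE) and len(where) > 1:
                    out.append(
                        Violation(
                            CARDINALITY,
                            where[1],
                            f"attribute {attr_id} appears {len(where)} times "
                            "in one scope but is limited to one",
                        )
                    )
                    break
    if not focus_ok:
        return
    # a required attribute must appear somewhere when the focus falls in
    # its domain
    for rule in rules.rules:
        if rule.cardinality != REQUIRED_ONE or rule.attribute in seen_attrs:
            continue
        try:
            in_domain = all(
                evaluate_constraint(rule.domain, t.ref, graph) for t in expr.focus
            )
        except (UnknownConceptError, UnknownVocabularyError):
            continue
        if in_domain:
            out.append(
                Violation(
                    CARDINALITY,
                    f"{prefix}focus[0]" if prefix else "focus[0]",
                    f"attribute {rule.attribute} is required for this focus "
                    "but absent",
                )
            )


# ---------------------------------------------------------------------------
# Extension (strictly permissive deltas)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AddRule:
    rule: AttributeRule


@dataclass(frozen=True)
class WidenDomain:
    attribute: str
    constraint: ConstraintExpr


@dataclass(frozen=True)
class WidenRange:
    attribute: str
    constraint: ConstraintExpr


Delta = Union[AddRule, WidenDomain, WidenRange]


def extend(
    base: MrcmRuleSet,
    deltas: Iterable[Delta],
    *,
    name: str | None = None,
    version: str | None = None,
) -> MrcmRuleSet:
    """Apply permissive deltas to a rule set.

    Widenings replace the targeted constraint by the union of old and new;
    ``AddRule`` appends a complete rule.  Widening an attribute with no
    existing rule raises :class:`~fdg.errors.RuleError`.  Because every
    delta only enlarges what is permitted, any expression valid under
    *base* remains valid under the result.
    """
    rules = list(base.rules)
    for delta in deltas:
        if isinstance(delta, AddRule):
            rules.append(delta.rule)
            continue
        hits = [i for i, r in enumerate(rules) if r.attribute == delta.attribute]
        if not hits:
            raise RuleError(
                f"cannot widen attribute {delta.attribute}: no existing rule"
            )
        for i in hits:
            r = rules[i]
            if isinstance(delta, WidenDomain):
                rules[i] = replace(r, domain=union_of(r.domain, delta.constraint))
            else:
                rules[i] = replace(r, range=union_of(r.range, delta.constraint))
    return MrcmRuleSet(
        name=name if name is not None else f"{base.name}+extensions",
        version=version if version is not None else base.version,
        rules=tuple(rules),
    )


# ---------------------------------------------------------------------------
# Rules I/O (TSV)
# ---------------------------------------------------------------------------

_RULES_HEADER = "attributeId\tdomain\trange\tcardinality\tgroupable"


def read_rules(
    path: Union[str, Path], *, name: str | None = None, version: str = ""
) -> MrcmRuleSet:
    """Read a rule set from TSV:
    ``attributeId<TAB>domain<TAB>range<TAB>cardinality<TAB>groupable``
    with constraints in the textual language.  Syntax errors carry the row
    number."""
    rules = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line == _RULES_HEADER):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ConstraintSyntaxError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
                )
            attr, domain, rng, card, groupable = fields
            if groupable not in ("true", "false"):
                raise ConstraintSyntaxError(
                    f"{path}:{lineno}: groupable must be true/false"
                )
            try:
                rule = AttributeRule(
                    attribute=attr,
                    domain=parse_constraint(domain),
                    range=parse_constraint(rng),
                    cardinality=card,
                    groupable=groupable == "true",
                )
            except (ConstraintSyntaxError, RuleError) as exc:
                raise ConstraintSyntaxError(f"{path}:{lineno}: {exc}") from exc
            rules.append(rule)
    return MrcmRuleSet(
        name=name if name is not None else path.stem, version=version, rules=tuple(rules)
    )


def write_rules(rules: MrcmRuleSet, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_RULES_HEADER + "\n")
        for r in rules.rules:
            fh.write(
                f"{r.attribute}\t{r.domain.to_text()}\t{r.range.to_text()}\t"
                f"{r.cardinality}\t{'true' if r.groupable else 'false'}\n"
            )
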