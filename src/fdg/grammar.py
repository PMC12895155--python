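"""Tokenizer, parser, AST and canonical serializer for the extended
compositional grammar.

The grammar is the classic SNOMED CT compositional-grammar shape — focus
concepts, optionally refined by attribute=value pairs that may be grouped —
extended in two directions:

* **external references**: tilde-delimited tokens embedding a concept of a
  registered non-native vocabulary, ``~Pango~B.1.1.7~`` or, with a version
  label, ``~CTCAE~v5.0~4028512~``.  They may appear anywhere a concept may:
  as focus, attribute, value, or alone.
* **concrete values**: numbers prefixed with ``#`` (``#150``) and quoted
  strings (ISO 8601 dates travel as quoted strings; whether a string is a
  date is decided by the concept-model rule that constrains the attribute,
  not by the lexer).

ABNF profile implemented here::

    expression   = ws subExpr ws
    subExpr      = focus [ws ":" ws refinements]
    focus        = cref *(ws "+" ws cref)
    refinements  = (attrSet / group) *(ws (attrSet / group))
    group        = "{" ws attrSet ws "}"
    attrSet      = attr *(ws "," ws attr)
    attr         = cref ws "=" ws value
    value        = cref / ("(" ws subExpr ws ")") / concrete
    concrete     = ("#" number) / quotedString
    cref         = (sctId / externalRef) [ws "|" term "|"]
    externalRef  = "~" seg "~" [seg "~"] seg "~"
    sctId        = 6*18 DIGIT

Tilde segments exclude the grammar's structural characters
(``= : { } ( ) + , "`` and whitespace) in addition to ``~`` and ``|``, so an
external reference is always recognisable without backtracking.  The
definition-status prefixes ``===`` and ``<<<`` of the official grammar are
accepted and ignored with a warning.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Union

from .concept_model import ExternalConceptRef, validate_sctid
from .errors import ExpressionSyntaxError, ExternalRefError, MalformedIdError

__all__ = [
    "ConceptToken",
    "ConcreteValue",
    "Refinement",
    "Expression",
    "Features",
    "parse",
    "serialize",
    "parse_external_ref",
    "features_used",
    "GrammarWarning",
]


class GrammarWarning(UserWarning):
    """Non-fatal oddity met while parsing (e.g. an ignored ``===`` prefix)."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConceptToken:
    """A concept occurrence: either a native identifier or an external
    reference, with an optional display term that is kept for echoing but
    carries no semantics."""

    sctid: str | None = None
    external: ExternalConceptRef | None = None
    term: str | None = None

    def __post_init__(self) -> None:
        if (self.sctid is None) == (self.external is None):
            raise ValueError(
                "ConceptToken needs exactly one of sctid / external"
            )
        if self.sctid is not None and not validate_sctid(self.sctid):
            raise MalformedIdError(f"invalid concept identifier {self.sctid!r}")

    @property
    def ref(self) -> Union[str, ExternalConceptRef]:
        return self.sctid if self.sctid is not None else self.external

    def sort_key(self) -> tuple:
        # native ids numerically first, external refs lexically after
        if self.sctid is not None:
            return (0, int(self.sctid), "")
        return (1, 0, self.external.token)

    def __str__(self) -> str:
        return self.sctid if self.sctid is not None else self.external.token


@dataclass(frozen=True)
class ConcreteValue:
    """A literal attribute value.

    kind ``number``: decimal literal, serialized with a ``#`` prefix.
    kind ``string``: arbitrary text, serialized in double quotes.
    kind ``date``: an ISO 8601 calendar date or datetime, serialized as a
    quoted string (the parser yields ``string``; ``date`` marks values
    constructed programmatically from date objects).
    """

    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("number", "string", "date"):
            raise ValueError(f"bad concrete kind {self.kind!r}")
        if self.kind == "number":
            Decimal(self.value)  # raises on a malformed literal
        if self.kind == "date":
            parse_iso_date(self.value)

    @classmethod
    def number(cls, value: Union[str, int, float, Decimal]) -> "ConcreteValue":
        return cls("number", str(value))

    @classmethod
    def string(cls, value: str) -> "ConcreteValue":
        return cls("string", value)

    @classmethod
    def date(cls, value: Union[str, _dt.date, _dt.datetime]) -> "ConcreteValue":
        if isinstance(value, (_dt.date, _dt.datetime)):
            value = value.isoformat()
        return cls("date", value)

    @property
    def as_decimal(self) -> Decimal:
        if self.kind != "number":
            raise ValueError(f"{self.kind} value has no numeric reading")
        return Decimal(self.value)


def parse_iso_date(text: str) -> Union[_dt.date, _dt.datetime, None]:
    """Return the ISO 8601 reading of *text*, or None if it has none."""
    for parser in (_dt.date.fromisoformat, _dt.datetime.fromisoformat):
        try:
            return parser(text)
        except ValueError:
            continue
    return None


AttributeValue = Union[ConceptToken, "Expression", ConcreteValue]


@dataclass(frozen=True)
class Refinement:
    attribute: ConceptToken
    value: AttributeValue

    def __post_init__(self) -> None:
        if isinstance(self.attribute, ConcreteValue):
            raise ValueError("a refinement attribute cannot be a literal")


@dataclass(frozen=True)
class Expression:
    """Focus concepts plus ungrouped and grouped attribute refinements."""

    focus: tuple[ConceptToken, ...]
    ungrouped: tuple[Refinement, ...] = ()
    groups: tuple[tuple[Refinement, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "focus", tuple(self.focus))
        object.__setattr__(self, "ungrouped", tuple(self.ungrouped))
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))
        if not self.focus:
            raise ValueError("an expression needs at least one focus concept")
        if any(not g for g in self.groups):
            raise ValueError("attribute groups must be non-empty")

    @property
    def has_refinements(self) -> bool:
        return bool(self.ungrouped or self.groups)

    def canonical(self) -> "Expression":
        """Structurally equal copy in canonical order with display terms
        stripped: focus sorted (native ids numerically, external refs
        lexically after), refinements by (attribute, serialized value),
        groups by their serialized form."""
        return _canonicalize(self)


def _strip(token: ConceptToken) -> ConceptToken:
    return ConceptToken(sctid=token.sctid, external=token.external)


def _canonicalize(expr: Expression) -> Expression:
    def canon_value(v: AttributeValue) -> AttributeValue:
        if isinstance(v, Expression):
            return _canonicalize(v)
        if isinstance(v, ConceptToken):
            return _strip(v)
        if v.kind == "date":
            # dates travel as quoted strings; the canonical AST matches
            # what re-parsing the serialized form yields
            return ConcreteValue("string", v.value)
        return v

    def canon_refinement(r: Refinement) -> Refinement:
        return Refinement(_strip(r.attribute), canon_value(r.value))

    def ref_key(r: Refinement) -> tuple:
        return (r.attribute.sort_key(), _serialize_value(r.value, True))

    focus = tuple(sorted((_strip(t) for t in expr.focus), key=ConceptToken.sort_key))
    ungrouped = tuple(sorted(map(canon_refinement, expr.ungrouped), key=ref_key))
    groups = tuple(
        sorted(
            (tuple(sorted(map(canon_refinement, g), key=ref_key)) for g in expr.groups),
            key=lambda g: tuple(map(ref_key, g)),
        )
    )
    return Expression(focus=focus, ungrouped=ungrouped, groups=groups)


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------


def _serialize_token(t: ConceptToken, canonical: bool) -> str:
    base = str(t)
    if not canonical and t.term is not None:
        return f"{base} |{t.term}|"
    return base


def _serialize_value(v: AttributeValue, canonical: bool) -> str:
    if isinstance(v, ConceptToken):
        return _serialize_token(v, canonical)
    if isinstance(v, Expression):
        return f"( {_serialize_expr(v, canonical)} )"
    if v.kind == "number":
        return f"#{v.value}"
    return f'"{v.value}"'


def _serialize_refinement(r: Refinement, canonical: bool) -> str:
    return (
        f"{_serialize_token(r.attribute, canonical)} = "
        f"{_serialize_value(r.value, canonical)}"
    )


def _serialize_expr(expr: Expression, canonical: bool) -> str:
    out = " + ".join(_serialize_token(t, canonical) for t in expr.focus)
    if expr.has_refinements:
        parts = []
        if expr.ungrouped:
            parts.append(
                ", ".join(_serialize_refinement(r, canonical) for r in expr.ungrouped)
            )
        for g in expr.groups:
            inner = ", ".join(_serialize_refinement(r, canonical) for r in g)
            parts.append(f"{{ {inner} }}")
        out += " : " + " ".join(parts)
    return out


def serialize(expr: Expression, canonical: bool = True) -> str:
    """Render an expression as text.

    With ``canonical=True`` the unique canonical form is produced (sorted,
    single-spaced, display terms dropped); serializing twice is a fixed
    point.  With ``canonical=False`` stored order and display terms are
    preserved.
    """
    if canonical:
        expr = expr.canonical()
    return _serialize_expr(expr, canonical)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_WS = " \t\r\n"
_NUMBER_RE = re.compile(r"[+-]?[0-9]+(?:\.[0-9]+)?")


def _is_seg_char(ch: str) -> bool:
    return (
        0x21 <= ord(ch) <= 0x7E
        and ch not in '~|=:{}()+,"'
    )


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    # -- low-level helpers --------------------------------------------------

    def error(self, message: str, expected: tuple = ()) -> ExpressionSyntaxError:
        return ExpressionSyntaxError(message, self.pos, expected)

    def ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in _WS:
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, literal: str) -> None:
        if self.text.startswith(literal, self.pos):
            self.pos += len(literal)
        else:
            raise self.error(
                f"unexpected {self.peek()!r}" if self.peek() else "unexpected end of input",
                expected=(repr(literal),),
            )

    # -- grammar ------------------------------------------------------------

    def parse_expression(self) -> Expression:
        self.ws()
        self._skip_definition_status()
        expr = self.parse_subexpression()
        self.ws()
        if self.pos != len(self.text):
            raise self.error(f"trailing input {self.text[self.pos:]!r}")
        return expr

    def _skip_definition_status(self) -> None:
        for prefix in ("===", "<<<"):
            if self.text.startswith(prefix, self.pos):
                warnings.warn(
                    f"definition-status prefix {prefix!r} accepted but ignored",
                    GrammarWarning,
                    stacklevel=4,
                )
                self.pos += len(prefix)
                self.ws()
                return

    def parse_subexpression(self) -> Expression:
        focus = [self.parse_cref()]
        while True:
            mark = self.pos
            self.ws()
            if self.peek() == "+":
                self.pos += 1
                self.ws()
                focus.append(self.parse_cref())
            else:
                self.pos = mark
                break
        ungrouped: list[Refinement] = []
        groups: list[tuple[Refinement, ...]] = []
        mark = self.pos
        self.ws()
        if self.peek() == ":":
            self.pos += 1
            self.ws()
            self.parse_refinements(ungrouped, groups)
        else:
            self.pos = mark
        return Expression(tuple(focus), tuple(ungrouped), tuple(groups))

    def parse_refinements(
        self,
        ungrouped: list[Refinement],
        groups: list[tuple[Refinement, ...]],
    ) -> None:
        first = True
        while True:
            if not first:
                mark = self.pos
                self.ws()
                if not (self.peek() == "{" or self._at_cref()):
                    self.pos = mark
                    return
            if self.peek() == "{":
                groups.append(self.parse_group())
            elif self._at_cref():
                ungrouped.extend(self.parse_attr_set())
            elif first:
                raise self.error(
                    "expected a refinement",
                    expected=("concept identifier", "external reference", "'{'"),
                )
            first = False

    def _at_cref(self) -> bool:
        ch = self.peek()
        return ch.isdigit() or ch == "~"

    def parse_group(self) -> tuple[Refinement, ...]:
        self.expect("{")
        self.ws()
        if self.peek() == "}":
            raise self.error(
                "attribute group may not be empty",
                expected=("concept identifier", "external reference"),
            )
        attrs = self.parse_attr_set()
        self.ws()
        self.expect("}")
        return tuple(attrs)

    def parse_attr_set(self) -> list[Refinement]:
        attrs = [self.parse_attr()]
        while True:
            mark = self.pos
            self.ws()
            if self.peek() == ",":
                self.pos += 1
                self.ws()
                attrs.append(self.parse_attr())
            else:
                self.pos = mark
                return attrs

    def parse_attr(self) -> Refinement:
        attribute = self.parse_cref()
        self.ws()
        self.expect("=")
        self.ws()
        return Refinement(attribute, self.parse_value())

    def parse_value(self) -> AttributeValue:
        ch = self.peek()
        if ch == "(":
            self.pos += 1
            self.ws()
            sub = self.parse_subexpression()
            self.ws()
            self.expect(")")
            return sub
        if ch == "#":
            self.pos += 1
            m = _NUMBER_RE.match(self.text, self.pos)
            if not m:
                raise self.error("expected a number after '#'", ("number",))
            self.pos = m.end()
            return ConcreteValue.number(m.group())
        if ch == '"':
            return self.parse_quoted_string()
        if self._at_cref():
            return self.parse_cref()
        raise self.error(
            "expected an attribute value",
            expected=("concept", "'('", "'#'", '"'),
        )

    def parse_quoted_string(self) -> ConcreteValue:
        self.expect('"')
        start = self.pos
        end = self.text.find('"', self.pos)
        if end < 0:
            raise self.error("unterminated string literal", ('"',))
        self.pos = end + 1
        return ConcreteValue.string(self.text[start:end])

    def parse_cref(self) -> ConceptToken:
        ch = self.peek()
        if ch.isdigit():
            token = ConceptToken(sctid=self.parse_sctid())
        elif ch == "~":
            token = ConceptToken(external=self.parse_external_ref())
        else:
            raise self.error(
                f"unexpected {ch!r}" if ch else "unexpected end of input",
                expected=("concept identifier", "external reference"),
            )
        mark = self.pos
        self.ws()
        if self.peek() == "|":
            self.pos += 1
            end = self.text.find("|", self.pos)
            if end < 0:
                raise self.error("unterminated display term", ("|",))
            term = self.text[self.pos:end].strip()
            self.pos = end + 1
            return ConceptToken(
                sctid=token.sctid, external=token.external, term=term
            )
        self.pos = mark
        return token

    def parse_sctid(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos].isdigit():
            self.pos += 1
        candidate = self.text[start:self.pos]
        if not validate_sctid(candidate):
            self.pos = start
            raise MalformedIdError(
                f"invalid concept identifier {candidate!r} at position {start}"
            )
        return candidate

    def parse_external_ref(self) -> ExternalConceptRef:
        self.expect("~")
        segments: list[str] = []
        while True:
            seg_start = self.pos
            while self.pos < len(self.text) and _is_seg_char(self.text[self.pos]):
                self.pos += 1
            seg = self.text[seg_start:self.pos]
            if not seg:
                raise ExternalRefError(
                    "empty segment in external reference", self.pos, ("segment",)
                )
            if self.peek() != "~":
                raise ExternalRefError(
                    "unterminated external reference", self.pos, ("'~'",)
                )
            self.pos += 1
            segments.append(seg)
            if len(segments) == 3:
                break
            if len(segments) == 2 and not self._third_segment_follows():
                break
        if len(segments) == 2:
            return ExternalConceptRef(segments[0], segments[1])
        return ExternalConceptRef(segments[0], segments[2], version=segments[1])

    def _third_segment_follows(self) -> bool:
        # a third segment is taken only when seg-chars immediately followed
        # by '~' are ahead; whitespace or a structural char ends the token
        i = self.pos
        while i < len(self.text) and _is_seg_char(self.text[i]):
            i += 1
        return i > self.pos and i < len(self.text) and self.text[i] == "~"


def parse(text: str) -> Expression:
    """Parse an expression in the extended compositional grammar.

    Whitespace between tokens is insignificant; display terms are captured
    on the AST but ignored semantically.  Raises
    :class:`~fdg.errors.ExpressionSyntaxError` (with position and expected
    tokens) or :class:`~fdg.errors.MalformedIdError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    return _Parser(text).parse_expression()


def parse_external_ref(token: str) -> ExternalConceptRef:
    """Parse one standalone tilde token (``~key~id~`` or
    ``~key~version~id~``)."""
    token = token.strip()
    if not token.startswith("~"):
        raise ExternalRefError(
            f"external reference must start with '~': {token!r}", 0
        )
    p = _Parser(token)
    ref = p.parse_external_ref()
    if p.pos != len(token):
        raise ExternalRefError(
            f"trailing characters after external reference: {token[p.pos:]!r}",
            p.pos,
        )
    return ref


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Features:
    """Which parts of the extended grammar an expression exercises."""

    has_refinements: bool = False
    uses_external_ref: bool = False
    uses_concrete_value: bool = False
    uses_extension_attribute: bool = False


def features_used(
    expr: Expression, extension_attributes: frozenset[str] | set[str] = frozenset()
) -> Features:
    """Walk an expression (including nested sub-expressions) and report the
    extended-grammar features it uses.  ``extension_attributes`` is the set
    of attribute identifiers counted as grammar extensions (typically the
    shipped extension-attribute fixture set)."""
    ext = set(extension_attributes)
    state = {"ref": False, "concrete": False, "ext_attr": False, "refined": False}

    def visit_token(t: ConceptToken) -> None:
        if t.external is not None:
            state["ref"] = True

    def visit_expr(e: Expression) -> None:
        if e.has_refinements:
            state["refined"] = True
        for t in e.focus:
            visit_token(t)
        for r in list(e.ungrouped) + [r for g in e.groups for r in g]:
            visit_token(r.attribute)
            if r.attribute.sctid in ext:
                state["ext_attr"] = True
            v = r.value
            if isinstance(v, Expression):
                visit_expr(v)
            elif isinstance(v, ConceptToken):
                visit_token(v)
            else:
                state["concrete"] = True

    visit_expr(expr)
    return Features(
        has_refinements=state["refined"],
        uses_external_ref=state["ref"],
        uses_concrete_value=state["concrete"],
        uses_extension_attribute=state["ext_attr"],
    )
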