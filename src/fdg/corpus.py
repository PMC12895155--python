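"""Annotated-corpus storage, expression classification and usage statistics.

A corpus row binds a data element of some source category (laboratory,
formularies, medical devices, ...) to the expression that represents it and
the number of data instances it covers.  Each expression falls in exactly
one class:

* ``precoordinated`` — a single native concept, no refinements;
* ``pce`` — a postcoordinated expression using only core grammar;
* ``extended_pce`` — an expression using the grammar extensions: an
  external-vocabulary reference anywhere, or a refinement through one of
  the extension attributes.

``summarize`` aggregates a corpus into a per-source table of element and
instance counts with extension percentages plus a total row (the total row
is the column-wise sum of the source rows).  Percentages follow two
conventions: table cells use two decimals with half-up rounding
(``percent``), prose-style integer figures use flooring (``floor_percent``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .concept_model import ConceptGraph, is_subsumed_by
from .errors import CorpusFormatError, FdgError
from .grammar import (
    ConcreteValue,
    Expression,
    Refinement,
    features_used,
    parse,
)

__all__ = [
    "CorpusRecord",
    "SummaryRow",
    "CorpusSummary",
    "percent",
    "floor_percent",
    "classify",
    "summarize",
    "query_numeric",
    "read_corpus",
    "write_corpus",
    "write_summary",
    "render_cell",
]

PRECOORDINATED = "precoordinated"
PCE = "pce"
EXTENDED_PCE = "extended_pce"


@dataclass(frozen=True)
class CorpusRecord:
    source: str
    element_id: str
    expression: str
    instance_count: int

    def __post_init__(self) -> None:
        if self.instance_count < 0:
            raise CorpusFormatError(
                f"element {self.element_id!r}: negative instance count"
            )


def percent(numerator: int, denominator: int) -> float:
    """Percentage at two decimals, half-up (table-cell convention); 0.0 for
    an empty denominator."""
    if denominator == 0:
        return 0.0
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def floor_percent(numerator: int, denominator: int) -> int:
    """Integer percentage, floored (prose convention: 28.8% reads "28%")."""
    if denominator == 0:
        return 0
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("1"), rounding=ROUND_FLOOR
    )
    return int(q)


def classify(
    record: CorpusRecord, extension_attributes: frozenset[str] | set[str]
) -> str:
    """Class of a record's expression (see module docstring).

    A lone external reference counts as ``extended_pce``: it already uses
    the extended syntax.  Parse failures are re-raised with the element id
    for context.
    """
    try:
        expr = parse(record.expression)
    except FdgError as exc:
        raise CorpusFormatError(
            f"element {record.element_id!r} ({record.source}): {exc}"
        ) from exc
    return _classify_expr(expr, frozenset(extension_attributes))


def _classify_expr(expr: Expression, extension_attributes: frozenset[str]) -> str:
    feats = features_used(expr, extension_attributes)
    if feats.uses_external_ref or feats.uses_extension_attribute:
        return EXTENDED_PCE
    if len(expr.focus) == 1 and not expr.has_refinements:
        return PRECOORDINATED
    return PCE


@dataclass(frozen=True)
class SummaryRow:
    source: str
    ids_encoded: int
    extensions_used: int
    pct_extensions: float
    instances_encoded: int
    extension_instances: int
    pct_extension_instances: float


@dataclass(frozen=True)
class CorpusSummary:
    rows: tuple[SummaryRow, ...]
    total: SummaryRow
    unparseable: int = 0  # only populated in lenient mode

    def row(self, source: str) -> SummaryRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        records = [vars(r) for r in self.rows] + [vars(self.total)]
        return pd.DataFrame.from_records(records).set_index("source")


def _make_row(source, ids, ext, inst, ext_inst) -> SummaryRow:
    return SummaryRow(
        source=source,
        ids_encoded=ids,
        extensions_used=ext,
        pct_extensions=percent(ext, ids),
        instances_encoded=inst,
        extension_instances=ext_inst,
        pct_extension_instances=percent(ext_inst, inst),
    )


def summarize(
    corpus: Iterable[CorpusRecord],
    extension_attributes: frozenset[str] | set[str],
    *,
    strict: bool = True,
) -> CorpusSummary:
    """Aggregate a corpus into the per-source extension-usage table.

    Strict mode (default) propagates the first parse failure; lenient mode
    excludes unparseable records from every count and reports how many were
    excluded.  The result is invariant under permutation of the records
    (sources are sorted alphabetically).
    """
    ext_attrs = frozenset(extension_attributes)
    per_source: dict[str, list[int]] = {}
    skipped = 0
    for record in corpus:
        try:
            cls = classify(record, ext_attrs)
        except CorpusFormatError:
            if strict:
                raise
            skipped += 1
            continue
        acc = per_source.setdefault(record.source, [0, 0, 0, 0])
        extended = cls == EXTENDED_PCE
        acc[0] += 1
        acc[1] += int(extended)
        acc[2] += record.instance_count
        acc[3] += record.instance_count if extended else 0
    rows = tuple(
        _make_row(source, *per_source[source]) for source in sorted(per_source)
    )
    total = _make_row(
        "Total",
        sum(r.ids_encoded for r in rows),
        sum(r.extensions_used for r in rows),
        sum(r.instances_encoded for r in rows),
        sum(r.extension_instances for r in rows),
    )
    return CorpusSummary(rows=rows, total=total, unparseable=skipped)


# ---------------------------------------------------------------------------
# Numeric querying
# ---------------------------------------------------------------------------

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "=": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


def _numeric_refinements(expr: Expression):
    for r in list(expr.ungrouped) + [r for g in expr.groups for r in g]:
        if isinstance(r.value, ConcreteValue) and r.value.kind == "number":
            yield r
        elif isinstance(r.value, Expression):
            yield from _numeric_refinements(r.value)


def query_numeric(
    corpus: Iterable[CorpusRecord],
    attribute: str,
    op: str,
    threshold: Union[int, float, str, Decimal],
    graph: ConceptGraph | None = None,
    subsume_attribute: bool = False,
) -> list[CorpusRecord]:
    """Records whose expression carries a numeric refinement through
    *attribute* (or any attribute subsumed by it, with
    ``subsume_attribute=True``, which then requires *graph*) whose value
    satisfies ``value op threshold``.

    This is the query style the scalar extension exists for: e.g. all heart
    rates with a value above 150.
    """
    if op not in _OPS:
        raise ValueError(f"op must be one of {sorted(_OPS)}, got {op!r}")
    if subsume_attribute and graph is None:
        raise ValueError("subsume_attribute=True requires a concept graph")
    if graph is not None:
        graph.resolve(attribute)  # unknown attribute -> error
    compare = _OPS[op]
    bound = Decimal(str(threshold))
    hits = []
    for record in corpus:
        try:
            expr = parse(record.expression)
        except FdgError as exc:
            raise CorpusFormatError(
                f"element {record.element_id!r} ({record.source}): {exc}"
            ) from exc
        for r in _numeric_refinements(expr):
            attr = r.attribute.sctid
            if attr is None:
                continue
            if subsume_attribute:
                matches = is_subsumed_by(attr, attribute, graph)
            else:
                matches = attr == attribute
            if matches and compare(r.value.as_decimal, bound):
                hits.append(record)
                break
    return hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CORPUS_HEADER = "source\telement_id\texpression\tinstance_count"


def read_corpus(path: Union[str, Path]) -> list[CorpusRecord]:
    """Read a corpus from TSV:
    ``source<TAB>element_id<TAB>expression<TAB>instance_count``."""
    records = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line == _CORPUS_HEADER):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            source, element_id, expression, count = fields
            try:
                n = int(count)
            except ValueError:
                raise CorpusFormatError(
                    f"{path}:{lineno}: bad instance count {count!r}"
                ) from None
            if n < 0:
                raise CorpusFormatError(
                    f"{path}:{lineno}: negative instance count {n}"
                )
            key = (source, element_id)
            if key in seen:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate element id {element_id!r} "
                    f"within source {source!r}"
                )
            seen.add(key)
            records.append(CorpusRecord(source, element_id, expression, n))
    return records


def write_corpus(corpus: Sequence[CorpusRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_CORPUS_HEADER + "\n")
        for r in corpus:
            fh.write(
                f"{r.source}\t{r.element_id}\t{r.expression}\t{r.instance_count}\n"
            )


def render_cell(count: int, pct: float) -> str:
    """Render an ``n (%)`` table cell, e.g. ``235 (33.62)``."""
    return f"{count} ({pct:.2f})"


def _summary_lines(summary: CorpusSummary) -> list[list[str]]:
    header = [
        "Source",
        "IDs encoded, n",
        "Extensions used, n (%)",
        "Instances encoded",
        "Extension instances, n (%)",
    ]
    lines = [header]
    for r in list(summary.rows) + [summary.total]:
        lines.append(
            [
                r.source,
                f"{r.ids_encoded}",
                render_cell(r.extensions_used, r.pct_extensions),
                f"{r.instances_encoded}",
                render_cell(r.extension_instances, r.pct_extension_instances),
            ]
        )
    return lines


def write_summary(
    summary: CorpusSummary, path: Union[str, Path], style: str = "tsv"
) -> None:
    """Write a summary as machine-readable TSV (``style="tsv"``) or as an
    aligned text table with ``n (%)`` cells (``style="text"``)."""
    if style == "tsv":
        summary.to_frame().to_csv(path, sep="\t")
        return
    if style != "text":
        raise ValueError(f"style must be 'tsv' or 'text', got {style!r}")
    lines = _summary_lines(summary)
    widths = [max(len(row[i]) for row in lines) for i in range(len(lines[0]))]
    with open(path, "w", encoding="utf-8") as fh:
        for row in lines:
            fh.write(
                "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
                + "\n"
            )


def format_summary(summary: CorpusSummary) -> str:
    """Aligned text rendering of a summary (what ``style="text"`` writes)."""
    lines = _summary_lines(summary)
    widths = [max(len(row[i]) for row in lines) for i in range(len(lines[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in lines
    )
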