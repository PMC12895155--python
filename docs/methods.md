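# Methods

This note records the model implemented by `fdg`, the design choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish about real terminology content.

## Concept model and hierarchy operations

Concepts carry SNOMED-style identifiers: 6–18 decimal digits, no leading
zero, terminated by a Verhoeff check digit (dihedral-group D5 checksum;
detects all single-digit and adjacent-transposition errors). Identifiers
are otherwise opaque — partition digits are not modelled, because the
grammar treats identifiers purely as tokens.

The concept graph is a single-rooted DAG of is-a edges with a
primitive/fully-defined flag per concept. Operations:

* **Subsumption** is reflexive-transitive reachability (child → ancestor),
  delegated to `networkx` path queries. ECL-style constraints map onto it:
  `<<` descendant-or-self, `<` strict descendant, a bare id is self-only.
* **Proximal primitive parents.** A primitive concept is its own PPP. For
  a fully defined concept, each upward path is walked to its first
  primitive ancestor and the set of those ancestors is returned. The
  single-path description in authoring practice assumes one parent; real
  DAGs can reach several primitives, so the operation returns a set and
  callers needing one concept reduce by smallest identifier (the package's
  universal tie-break, chosen for determinism).
* **Disjunction resolution** ("A or B" labels). Depth is the length of the
  *longest* is-a chain from the root — the most refined reading of a
  concept's position, so that "deepest common ancestor" rewards specific
  shared parents. The deepest common ancestors of the two concepts are
  computed; if the nearer concept is within `max_depth_gap` levels of that
  depth the smallest-id deepest ancestor is returned, else `"unmapped"`.
  `max_depth_gap` defaults to 2: one level catches siblings, two catches
  near cousins, while anything further shares too little meaning to stand
  for both disjuncts. "Sufficiently close" has no published numeric value,
  so the threshold is an explicit parameter rather than a constant.
* **External vocabulary attachment** adds the foreign concepts as graph
  nodes keyed `~key~local_id~`: local roots become children of the
  attachment parent, local parent links are kept beneath it, and host
  concepts are untouched (attachment is conservative by construction —
  only nodes and edges *into* the host are added). Resolution of an
  external reference ignores the version label; the version is preserved
  on the token and in serialization. External concepts count as primitive
  (they carry no logical definition) and their depth continues from the
  attachment parent as if local roots were its direct children.

## Grammar

The parser is a hand-written recursive-descent parser over a small ABNF
profile (see `fdg.grammar`). Choices that were open:

* **External-reference segments** exclude the grammar's own structural
  characters (`= : { } ( ) + , "` and whitespace) in addition to `~`, `|`.
  Without this, `~A~B~=~C~D~` is ambiguous between a two-segment and a
  three-segment reading; with it, every reference is recognisable without
  backtracking. Two interior segments read (key, id); three read
  (key, version, id); more are rejected, and there is no escaping of `~`.
* **Dates are not a lexical category.** A date travels as a quoted string;
  whether a string *is* a date is decided by the rule range that constrains
  the attribute (ISO 8601 via `datetime.fromisoformat`). This keeps the
  token grammar unambiguous. Consequently canonicalization folds the
  programmatic `date` literal kind into `string`.
* **Numbers**: optional sign, optional decimal fraction, no exponent —
  clinical scalars need no more.
* **Canonical form**: focus concepts sorted (native ids numerically,
  external references lexically after them), refinements by (attribute,
  serialized value), groups by serialized form; display terms dropped;
  single spaces. Canonical serialization is a fixed point, and parsing is
  whitespace-invariant between tokens.
* Definition-status prefixes (`===`, `<<<`) are accepted with a warning
  and ignored; vocabulary keys are case-sensitive; groups do not nest but
  values may be parenthesized sub-expressions.

## MRCM validation

Rules are a whitelist; an attribute with no applicable rule yields
`ATTRIBUTE_NOT_PERMITTED`. With several focus concepts the domain must
hold for **every** focus (the conjunctive reading — the safe choice where
practice is silent). Nested expression values are validated recursively
against their own focus, and satisfy a concept range through every focus
concept. A literal failing its range reports `BAD_CONCRETE_TYPE`; a
concept value failing reports `RANGE_MISMATCH`. Grouped refinements are
validated with the same domains as ungrouped ones, but only against rules
flagged groupable. Cardinality is per attribute per scope (the ungrouped
refinements are one scope, each group its own); `required-one` further
demands the attribute appear when the focus falls in its domain. All
violations are reported, each with a path naming a real AST node.

Extension is strictly permissive: `WidenDomain`/`WidenRange` replace a
constraint by the union of old and new, `AddRule` appends. Monotonicity
(previously valid expressions stay valid) is therefore structural, and the
test suite checks it at scale.

**Shipped rule fixtures.** The base set stands in for the official model:
context attributes confined to the situation hierarchy plus a few core
clinical attributes (finding site, associated morphology, method). The
extension set covers the 13 extension attributes: context-attribute
domains widened to clinical findings and procedures; negation attributes
(Without, Except for) ranging over physical objects, findings and
procedures; scalar attributes ranging over numbers (Date: dates);
temporality attributes ranging over findings, procedures and dates. Only
the context-attribute widenings are fixed by published prose; the rest is
a documented reconstruction, deliberately stored in editable TSV files
(`src/fdg/data/`) so the whole set can be replaced wholesale. Default
cardinality is `optional-many` (no published rule states cardinalities).
Whether "Without" and "Except for" differ semantically is unspecified;
they ship with identical constraints.

## Corpus statistics

Expressions classify as *precoordinated* (single native focus, no
refinements), *extended PCE* (any external reference, or any refinement
through an extension attribute), else *PCE*. A lone external focus counts
as extended — it already uses the extended syntax. Two percent conventions
coexist because published tables and prose do: table cells use two
decimals, half-up; prose-style integers use flooring (so 28.8% reads
"28"). Unparseable records abort `summarize` by default; a lenient mode
excludes and counts them instead, because silently dropping rows would
bias the percentages. The total row is the column-wise sum of the source
rows.

## Synthetic data

The generators make every module testable without licensed content.

* The fixture graph keeps a fixed skeleton (root, the familiar top-level
  hierarchies, the extension attributes under an attribute hierarchy, a
  handful of named demo concepts) and adds `n_concepts` generated concepts
  per content hierarchy (default 24 — a few hundred concepts keep every
  hierarchy non-trivially populated while all-pairs oracles stay instant),
  with up to `max_parents` parents and `primitive_fraction` 0.5.
* Expression sampling inverts validation — draw a rule, a focus from its
  domain, a value from its range — so generated expressions are valid by
  construction; the suite re-checks this rather than trusting it.
  `pce_fraction` defaults to 18 370/39 168 ≈ 0.469 and
  `extension_fraction` to 4 500/119 941 ≈ 0.0375, the composition of the
  reference corpus the statistics module emulates; since extended
  expressions are themselves postcoordinated, the extension share is
  capped by the postcoordinated share.
* The default per-source profile *is* the reference corpus's published
  per-source element/extension/instance counts. `exact` mode assigns
  extension flags and instance totals by deterministic quota so configured
  counts (hence percentages) reproduce bit-exactly; `sampled` mode draws
  Bernoulli flags and log-uniform instance counts (bounds 1–10⁶) so the
  extended count is Binomial(n, p) for statistical tests.
* The mutation generator produces negative cases with a promised error
  class: dropping the closing tilde of an external reference, bumping a
  check digit (Verhoeff guarantees detection), deleting `=`, emptying a
  group.

**What passing tests do not show.** The fixture ontology reproduces shape,
not content: real terminology releases are orders of magnitude larger,
have much deeper hierarchies, attribute relationships beyond is-a, and
description-logic definitions none of which are modelled. Generated
expressions exercise the grammar and rule engine, not clinical plausibility.
Corpus reconstructions fix marginal counts only; the underlying expressions
are synthetic, so agreement with published percentage cells validates the
summary arithmetic, not the annotation work that produced the originals.

## Problem sizes and numerics

The test suite and the acceptance script use: 10 000 expressions for
grammar round-trips, 50 random DAGs of 20–200 nodes (all ordered pairs)
for the subsumption oracle, 1 000 expressions for extension monotonicity,
and 6–8 seeds of n = 699 for sampled-mode recovery — sizes at which every
check is exhaustive rather than sampled wherever an oracle exists.
Percent arithmetic uses `decimal.Decimal` (no binary-float rounding);
ties break half-up for table cells. Wherever a single concept must be
chosen from a set, the numerically smallest identifier wins.

## Known limitations

No description-logic classification or consistency checking (the grammar
can express combinations a reasoner would reject); no role chains,
attribute hierarchies or lateralization rules; no expression-constraint
query language beyond the `<<`/`<`/self/`ext:`/type constraint subset; no
URI-based versioning of vocabulary releases (the version segment is
carried, not resolved); real RF2 release loading is out of scope.
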