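"""Shipped fixture content: a synthetic reference ontology skeleton, the
base and extended MRCM rule sets, and a small Pango-like vocabulary.

The fixture ontology is **synthetic**: it mirrors the shape of the real
terminology (a single root over the familiar top-level hierarchies —
Clinical finding, Procedure, Body structure, Organism, Observable entity,
Physical object, Qualifier value, Situation — plus an attribute hierarchy)
and reuses the published identifiers of those well-known concepts and of
the extension attributes, but contains none of the licensed content.
Concepts that do not exist in the real terminology (the proposed
"Microbiological strain" attribute, the virus-strain attachment parent, and
every generated leaf) carry deterministically synthesized identifiers.

The extension rule set covers four recurring representation gaps:

* **negation** — "Without" / "Except for", plus widened "Finding context" /
  "Procedure context" domains;
* **scalar values** — "With size", "Quantity", "Score", "Resulting in"
  (numbers), "Date" (ISO 8601 dates);
* **uncertainty** — the same context attributes applied directly to
  findings and procedures;
* **temporality** — "After" / "Before" / "During" / "Duration".

Only the domain/range widenings spelled out in prose anywhere are fixed;
the remaining domains and ranges of the extension attributes are a
documented reconstruction and can be replaced wholesale through the rules
TSV files.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .concept_model import (
    Concept,
    ConceptGraph,
    ExternalVocabulary,
    FULLY_DEFINED,
    PRIMITIVE,
    synthetic_sctid,
)
from .mrcm import (
    AddRule,
    AttributeRule,
    Delta,
    MrcmRuleSet,
    WidenDomain,
    extend,
    parse_constraint,
)

__all__ = [
    "ROOT",
    "HIERARCHIES",
    "ATTRIBUTES",
    "EXTENSION_ATTRIBUTE_IDS",
    "MICROBIOLOGICAL_STRAIN",
    "VIRUS_STRAIN_PARENT",
    "skeleton_concepts",
    "skeleton_graph",
    "base_rules",
    "extension_deltas",
    "extended_rules",
    "strain_rule_delta",
    "pango_vocabulary",
    "data_path",
]


def data_path(name: str) -> Path:
    """Path of a shipped data file (rule-set TSVs, the skeleton graph, the
    Pango registry)."""
    return Path(str(files("fdg").joinpath("data", name)))

# -- well-known identifiers (published, Verhoeff-valid) ---------------------

ROOT = "138875005"  # terminology root

HIERARCHIES = {
    "Clinical finding": "404684003",
    "Procedure": "71388002",
    "Body structure": "123037004",
    "Organism": "410607006",
    "Observable entity": "363787002",
    "Physical object": "260787004",
    "Qualifier value": "362981000",
    "Situation with explicit context": "243796009",
    "Attribute": "246061005",
}

CLINICAL_FINDING = HIERARCHIES["Clinical finding"]
PROCEDURE = HIERARCHIES["Procedure"]
BODY_STRUCTURE = HIERARCHIES["Body structure"]
ORGANISM = HIERARCHIES["Organism"]
OBSERVABLE_ENTITY = HIERARCHIES["Observable entity"]
PHYSICAL_OBJECT = HIERARCHIES["Physical object"]
QUALIFIER_VALUE = HIERARCHIES["Qualifier value"]
SITUATION = HIERARCHIES["Situation with explicit context"]
ATTRIBUTE = HIERARCHIES["Attribute"]

# core (non-extension) attributes used by the base model
FINDING_SITE = "363698007"
ASSOCIATED_MORPHOLOGY = "116676008"
METHOD = "260686004"

# the extension attributes, by representation gap
ATTRIBUTES = {
    "Without": "45169001",
    "Except for": "5185003",
    "Finding context": "408729009",
    "Procedure context": "408730004",
    "With size": "103373006",
    "Date": "410671006",
    "Resulting in": "79409006",
    "Quantity": "246205007",
    "Score": "246262008",
    "After": "255234002",
    "Before": "288556008",
    "During": "371881003",
    "Duration": "103335007",
}

WITHOUT = ATTRIBUTES["Without"]
EXCEPT_FOR = ATTRIBUTES["Except for"]
FINDING_CONTEXT = ATTRIBUTES["Finding context"]
PROCEDURE_CONTEXT = ATTRIBUTES["Procedure context"]
WITH_SIZE = ATTRIBUTES["With size"]
DATE = ATTRIBUTES["Date"]
RESULTING_IN = ATTRIBUTES["Resulting in"]
QUANTITY = ATTRIBUTES["Quantity"]
SCORE = ATTRIBUTES["Score"]
AFTER = ATTRIBUTES["After"]
BEFORE = ATTRIBUTES["Before"]
DURING = ATTRIBUTES["During"]
DURATION = ATTRIBUTES["Duration"]

EXTENSION_ATTRIBUTE_IDS = frozenset(ATTRIBUTES.values())

KNOWN_POSSIBLE = "410590009"  # qualifier used in uncertainty refinements
SARS_COV_2 = "840533007"

# synthetic identifiers for concepts absent from the real terminology
MICROBIOLOGICAL_STRAIN = synthetic_sctid("9990001")  # proposed attribute
VIRUS_STRAIN_PARENT = synthetic_sctid("9990002")  # attachment parent
VIRUS = synthetic_sctid("9990003")
HERNIA_REPAIR = synthetic_sctid("9990004")  # demo procedure
SURGICAL_MESH = synthetic_sctid("9990005")  # demo physical object
HEART_RATE = synthetic_sctid("9990006")  # demo observable


def skeleton_concepts() -> list[Concept]:
    """The fixed, deterministic part of the fixture ontology."""
    concepts = [Concept(ROOT, "Terminology root concept", PRIMITIVE)]
    for term, cid in HIERARCHIES.items():
        concepts.append(Concept(cid, term, PRIMITIVE, frozenset({ROOT})))
    for term, cid in ATTRIBUTES.items():
        concepts.append(
            Concept(cid, f"{term} (attribute)", PRIMITIVE, frozenset({ATTRIBUTE}))
        )
    for cid, term in (
        (FINDING_SITE, "Finding site (attribute)"),
        (ASSOCIATED_MORPHOLOGY, "Associated morphology (attribute)"),
        (METHOD, "Method (attribute)"),
        (MICROBIOLOGICAL_STRAIN, "Microbiological strain (attribute, synthetic)"),
    ):
        concepts.append(Concept(cid, term, PRIMITIVE, frozenset({ATTRIBUTE})))
    concepts += [
        Concept(KNOWN_POSSIBLE, "Known possible (qualifier value)", PRIMITIVE,
                frozenset({QUALIFIER_VALUE})),
        Concept(VIRUS, "Virus (synthetic)", PRIMITIVE, frozenset({ORGANISM})),
        Concept(VIRUS_STRAIN_PARENT, "Virus strain (synthetic)", PRIMITIVE,
                frozenset({VIRUS})),
        Concept(SARS_COV_2, "SARS-CoV-2", FULLY_DEFINED, frozenset({VIRUS})),
        Concept(HERNIA_REPAIR, "Hernia repair (synthetic)", FULLY_DEFINED,
                frozenset({PROCEDURE})),
        Concept(SURGICAL_MESH, "Surgical mesh (synthetic)", PRIMITIVE,
                frozenset({PHYSICAL_OBJECT})),
        Concept(HEART_RATE, "Heart rate (synthetic)", PRIMITIVE,
                frozenset({OBSERVABLE_ENTITY})),
    ]
    return concepts


def skeleton_graph() -> ConceptGraph:
    return ConceptGraph(skeleton_concepts())


# ---------------------------------------------------------------------------
# Rule sets
# ---------------------------------------------------------------------------


def _rule(attribute: str, domain: str, range_: str, **kw) -> AttributeRule:
    return AttributeRule(
        attribute=attribute,
        domain=parse_constraint(domain),
        range=parse_constraint(range_),
        **kw,
    )


def base_rules() -> MrcmRuleSet:
    """A small stand-in for the official concept model: context attributes
    confined to the Situation hierarchy, plus a few core clinical
    attributes."""
    return MrcmRuleSet(
        name="base",
        version="fixture-1",
        rules=(
            _rule(FINDING_CONTEXT, f"<< {SITUATION}", f"<< {QUALIFIER_VALUE}"),
            _rule(PROCEDURE_CONTEXT, f"<< {SITUATION}", f"<< {QUALIFIER_VALUE}"),
            _rule(FINDING_SITE, f"<< {CLINICAL_FINDING}", f"<< {BODY_STRUCTURE}"),
            _rule(
                ASSOCIATED_MORPHOLOGY,
                f"<< {CLINICAL_FINDING}",
                f"<< {QUALIFIER_VALUE}",
            ),
            _rule(METHOD, f"<< {PROCEDURE}", f"<< {QUALIFIER_VALUE}"),
        ),
    )


# negation values: absent physical objects, findings, or procedures
_NEGATION_RANGE = (
    f"<< {PHYSICAL_OBJECT} OR << {CLINICAL_FINDING} OR << {PROCEDURE}"
)
_TEMPORAL_DOMAIN = f"<< {CLINICAL_FINDING} OR << {PROCEDURE}"
_TEMPORAL_RANGE = f"<< {CLINICAL_FINDING} OR << {PROCEDURE} OR date"
_SCALAR_DOMAIN = (
    f"<< {CLINICAL_FINDING} OR << {PROCEDURE} OR << {OBSERVABLE_ENTITY} "
    f"OR << {PHYSICAL_OBJECT}"
)


def extension_deltas() -> list[Delta]:
    """The permissive deltas turning the base model into the extended one:
    domain widenings for the context attributes (uncertainty and negation
    applied directly to findings/procedures) and new rules for the
    negation, scalar and temporality attributes.  Where the exact published
    domains/ranges are not fixed in prose, the values here are a
    reconstruction (see module docstring)."""
    deltas: list[Delta] = [
        WidenDomain(FINDING_CONTEXT, parse_constraint(f"<< {CLINICAL_FINDING}")),
        WidenDomain(PROCEDURE_CONTEXT, parse_constraint(f"<< {PROCEDURE}")),
        AddRule(_rule(WITHOUT, _TEMPORAL_DOMAIN, _NEGATION_RANGE)),
        AddRule(_rule(EXCEPT_FOR, _TEMPORAL_DOMAIN, _NEGATION_RANGE)),
        AddRule(_rule(WITH_SIZE, _SCALAR_DOMAIN, "num")),
        AddRule(_rule(QUANTITY, _SCALAR_DOMAIN, "num")),
        AddRule(_rule(SCORE, _SCALAR_DOMAIN, "num")),
        AddRule(_rule(RESULTING_IN, _SCALAR_DOMAIN, "num")),
        AddRule(_rule(DATE, _SCALAR_DOMAIN, "date")),
        AddRule(_rule(AFTER, _TEMPORAL_DOMAIN, _TEMPORAL_RANGE)),
        AddRule(_rule(BEFORE, _TEMPORAL_DOMAIN, _TEMPORAL_RANGE)),
        AddRule(_rule(DURING, _TEMPORAL_DOMAIN, _TEMPORAL_RANGE)),
        AddRule(_rule(DURATION, _TEMPORAL_DOMAIN, "num")),
    ]
    return deltas


def extended_rules() -> MrcmRuleSet:
    """Base model plus every extension delta."""
    return extend(
        base_rules(), extension_deltas(), name="extended", version="fixture-1"
    )


def strain_rule_delta() -> Delta:
    """The new rule licensing organism refinement by an external
    strain nomenclature: ``Organism : Microbiological strain = ext:Pango``."""
    return AddRule(
        _rule(MICROBIOLOGICAL_STRAIN, f"<< {ORGANISM}", "ext:Pango")
    )


def extension_rules_only() -> MrcmRuleSet:
    """Just the rules governing the extension attributes (one per attribute,
    contexts with their widened domains) — the shape shipped in
    ``data/mrcm_extension.tsv``."""
    ext = extended_rules()
    return MrcmRuleSet(
        name="extension",
        version="fixture-1",
        rules=tuple(r for r in ext.rules if r.attribute in EXTENSION_ATTRIBUTE_IDS),
    )


def pango_vocabulary() -> ExternalVocabulary:
    """A three-lineage synthetic slice of the Pango SARS-CoV-2 nomenclature
    (B -> B.1 -> B.1.1.7), attached beneath the virus-strain parent."""
    return ExternalVocabulary(
        key="Pango",
        version="v4.3",
        attachment_parent=VIRUS_STRAIN_PARENT,
        concepts={"B": (), "B.1": ("B",), "B.1.1.7": ("B.1",)},
    )
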