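"""Concept-model validation: constraint semantics, the validation engine
against a brute-force rule enumerator, permissive extension monotonicity,
and rule-set round-trips."""

from __future__ import annotations

import itertools
import random

import pytest

import fdg.fixtures as fx
from fdg.errors import ConstraintSyntaxError, RuleError, UnknownVocabularyError
from fdg.grammar import (
    ConceptToken,
    ConcreteValue,
    Expression,
    parse,
    serialize,
)
from fdg.mrcm import (
    ATTRIBUTE_NOT_PERMITTED,
    BAD_CONCRETE_TYPE,
    CARDINALITY,
    DOMAIN_MISMATCH,
    RANGE_MISMATCH,
    UNKNOWN_CONCEPT,
    AddRule,
    AttributeRule,
    MrcmRuleSet,
    WidenDomain,
    WidenRange,
    evaluate_constraint,
    extend,
    parse_constraint,
    read_rules,
    validate,
    write_rules,
)
from fdg.synthetic_data import GeneratorParams, make_expressions


# -- constraint evaluation ---------------------------------------------------


def test_descendant_or_self_is_reflexive(graph):
    c = parse_constraint(f"<< {fx.CLINICAL_FINDING}")
    assert evaluate_constraint(c, fx.CLINICAL_FINDING, graph)


def test_strict_descendant_excludes_self(graph):
    c = parse_constraint(f"< {fx.CLINICAL_FINDING}")
    assert not evaluate_constraint(c, fx.CLINICAL_FINDING, graph)
    child = sorted(graph.children_of(fx.CLINICAL_FINDING))[0]
    assert evaluate_constraint(c, child, graph)


@pytest.mark.parametrize(
    "text,ok",
    [
        ("2021-03-15", True),
        ("2021-03-15T14:30:00", True),
        ("tomorrow", False),
        ("2021-13-01", False),
        ("15/03/2021", False),
    ],
)
def test_date_constraint_uses_iso8601(graph, text, ok):
    c = parse_constraint("date")
    assert evaluate_constraint(c, ConcreteValue.string(text), graph) is ok


def test_concrete_type_constraints(graph):
    num = parse_constraint("num")
    assert evaluate_constraint(num, ConcreteValue.number(150), graph)
    assert not evaluate_constraint(num, ConcreteValue.string("large"), graph)
    assert not evaluate_constraint(num, ConceptToken(sctid=fx.CLINICAL_FINDING), graph)


def test_external_cluster_constraint(graph):
    c = parse_constraint("ext:Pango")
    tok = parse("~Pango~B.1.1.7~").focus[0]
    assert evaluate_constraint(c, tok, graph)
    assert not evaluate_constraint(c, ConceptToken(sctid=fx.SARS_COV_2), graph)


def test_unattached_vocabulary_raises(graph):
    c = parse_constraint("ext:Nextstrain")
    tok = ConceptToken(external=parse("~Nextstrain~21A~").focus[0].external)
    with pytest.raises(UnknownVocabularyError):
        evaluate_constraint(c, tok, graph)


def test_union_constraint(graph):
    c = parse_constraint(f"<< {fx.CLINICAL_FINDING} OR << {fx.PROCEDURE} OR num")
    assert evaluate_constraint(c, fx.HERNIA_REPAIR, graph)
    assert evaluate_constraint(c, ConcreteValue.number(1), graph)
    assert not evaluate_constraint(c, fx.BODY_STRUCTURE, graph)


def test_constraint_text_roundtrip():
    for text in (
        f"<< {fx.CLINICAL_FINDING}",
        f"< {fx.PROCEDURE}",
        fx.QUALIFIER_VALUE,
        "ext:Pango",
        "num",
        "date",
        f"<< {fx.CLINICAL_FINDING} OR num OR ext:Pango",
    ):
        assert parse_constraint(text).to_text() == text


@pytest.mark.parametrize("bad", ["<<<x", "", "ext:", "<< 123", "banana"])
def test_constraint_syntax_errors(bad):
    with pytest.raises(ConstraintSyntaxError):
        parse_constraint(bad)


# -- validation scenarios ----------------------------------------------------


def test_uncertainty_refinement_needs_widened_domain(ctx):
    """'Finding context' applied directly to a clinical finding is only
    licensed once the context attribute's domain is widened beyond the
    situation hierarchy."""
    finding = sorted(ctx.graph.children_of(fx.CLINICAL_FINDING))[0]
    expr = parse(f"{finding} : {fx.FINDING_CONTEXT} = {fx.KNOWN_POSSIBLE}")
    assert validate(expr, ctx.rules, ctx.graph).valid
    base_report = validate(expr, ctx.base_rules, ctx.graph)
    assert base_report.codes() == {DOMAIN_MISMATCH}


def test_pango_strain_refinement(ctx):
    """Refining an organism with an external strain succeeds only once the
    strain rule exists."""
    expr = parse(
        f"{fx.SARS_COV_2} : {fx.MICROBIOLOGICAL_STRAIN} = ~Pango~B.1.1.7~"
    )
    assert validate(expr, ctx.rules, ctx.graph).valid
    without_rule = fx.extended_rules()
    report = validate(expr, without_rule, ctx.graph)
    assert report.codes() == {ATTRIBUTE_NOT_PERMITTED}


def test_scalar_size_value_types(ctx):
    ok = parse(f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = #8")
    assert validate(ok, ctx.rules, ctx.graph).valid
    bad = parse(f'{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = "large"')
    report = validate(bad, ctx.rules, ctx.graph)
    assert report.codes() == {BAD_CONCRETE_TYPE}


def test_negation_refinement(ctx):
    """A procedure performed without a device validates under the negation
    extension (hernia repair without mesh)."""
    expr = parse(f"{fx.HERNIA_REPAIR} : {fx.WITHOUT} = {fx.SURGICAL_MESH}")
    assert validate(expr, ctx.rules, ctx.graph).valid
    report = validate(expr, ctx.base_rules, ctx.graph)
    assert report.codes() == {ATTRIBUTE_NOT_PERMITTED}


def test_unknown_focus_and_value_reported(ctx):
    expr = parse(f"999999999999 : {fx.WITH_SIZE} = #1")
    codes = validate(expr, ctx.rules, ctx.graph).codes()
    assert UNKNOWN_CONCEPT in codes


def test_range_mismatch_for_concept_value(ctx):
    expr = parse(f"{fx.HERNIA_REPAIR} : {fx.WITHOUT} = {fx.KNOWN_POSSIBLE}")
    report = validate(expr, ctx.rules, ctx.graph)
    assert report.codes() == {RANGE_MISMATCH}


def test_no_refinements_always_valid(ctx):
    for node in list(sorted(n for n in ctx.graph if not n.startswith("~")))[:20]:
        assert validate(parse(node), ctx.rules, ctx.graph).valid


def test_multiple_focus_domain_is_conjunctive(ctx):
    """The domain must hold for every focus concept."""
    expr = parse(
        f"{fx.HERNIA_REPAIR} + {fx.SURGICAL_MESH} : {fx.DURATION} = #45"
    )
    report = validate(expr, ctx.rules, ctx.graph)
    assert report.codes() == {DOMAIN_MISMATCH}  # mesh is not a procedure
    both_proc = parse(
        f"{fx.HERNIA_REPAIR} + {fx.PROCEDURE} : {fx.DURATION} = #45"
    )
    assert validate(both_proc, ctx.rules, ctx.graph).valid


def test_nested_expression_validated_recursively(ctx):
    good = parse(
        f"{fx.HERNIA_REPAIR} : {fx.AFTER} = "
        f"( {fx.CLINICAL_FINDING} : {fx.FINDING_CONTEXT} = {fx.KNOWN_POSSIBLE} )"
    )
    assert validate(good, ctx.rules, ctx.graph).valid
    bad_inner = parse(
        f"{fx.HERNIA_REPAIR} : {fx.AFTER} = "
        f'( {fx.CLINICAL_FINDING} : {fx.WITH_SIZE} = "big" )'
    )
    report = validate(bad_inner, ctx.rules, ctx.graph)
    assert not report.valid
    assert all(v.path.startswith("ungrouped[0].value.") for v in report.violations)


def test_cardinality_limited_attributes(ctx):
    rules = MrcmRuleSet(
        name="card",
        version="t",
        rules=(
            AttributeRule(
                attribute=fx.WITH_SIZE,
                domain=parse_constraint(f"<< {fx.PHYSICAL_OBJECT}"),
                range=parse_constraint("num"),
                cardinality="optional-one",
            ),
        ),
    )
    once = parse(f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = #8")
    assert validate(once, rules, ctx.graph).valid
    twice = parse(f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = #8, {fx.WITH_SIZE} = #9")
    assert validate(twice, rules, ctx.graph).codes() == {CARDINALITY}
    # separate groups are separate scopes
    grouped = parse(
        f"{fx.SURGICAL_MESH} : {{ {fx.WITH_SIZE} = #8 }} {{ {fx.WITH_SIZE} = #9 }}"
    )
    assert validate(grouped, rules, ctx.graph).valid


def test_non_groupable_attribute_rejected_in_group(ctx):
    rules = MrcmRuleSet(
        name="ng",
        version="t",
        rules=(
            AttributeRule(
                attribute=fx.WITH_SIZE,
                domain=parse_constraint(f"<< {fx.PHYSICAL_OBJECT}"),
                range=parse_constraint("num"),
                groupable=False,
            ),
        ),
    )
    ungrouped = parse(f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = #8")
    assert validate(ungrouped, rules, ctx.graph).valid
    grouped = parse(f"{fx.SURGICAL_MESH} : {{ {fx.WITH_SIZE} = #8 }}")
    assert validate(grouped, rules, ctx.graph).codes() == {ATTRIBUTE_NOT_PERMITTED}


# -- order independence and oracle equivalence -------------------------------


def _permute(expr: Expression, rng: random.Random) -> Expression:
    focus = list(expr.focus)
    ungrouped = list(expr.ungrouped)
    groups = list(expr.groups)
    rng.shuffle(focus)
    rng.shuffle(ungrouped)
    rng.shuffle(groups)
    return Expression(tuple(focus), tuple(ungrouped), tuple(groups))


def test_validation_is_order_independent(ctx):
    rng = random.Random(5)
    exprs = make_expressions(
        ctx.graph, ctx.rules, 60,
        GeneratorParams(seed=8, extension_fraction=0.5, pce_fraction=1.0),
    )
    for text in exprs:
        expr = parse(text)
        verdict = validate(expr, ctx.rules, ctx.graph).valid
        for _ in range(3):
            assert validate(_permute(expr, rng), ctx.rules, ctx.graph).valid == verdict


def brute_force_valid(expr: Expression, rules, graph) -> bool:
    """Independent verdict: enumerate every (refinement, rule) pair and
    require a licensing rule for each refinement; nested expressions are
    checked the same way against their own focus."""
    try:
        for t in expr.focus:
            graph.resolve(t.ref)
    except Exception:
        return False
    placements = [(r, False) for r in expr.ungrouped] + [
        (r, True) for g in expr.groups for r in g
    ]
    for r, grouped in placements:
        if isinstance(r.value, Expression) and not brute_force_valid(
            r.value, rules, graph
        ):
            return False
        attr = r.attribute.sctid or r.attribute.external.node_key
        licensed = False
        for rule in rules.rules:
            if rule.attribute != attr or (grouped and not rule.groupable):
                continue
            try:
                domain_ok = all(
                    evaluate_constraint(rule.domain, t.ref, graph)
                    for t in expr.focus
                )
                range_ok = evaluate_constraint(rule.range, r.value, graph)
            except Exception:
                continue
            if domain_ok and range_ok:
                licensed = True
                break
        if not licensed:
            return False
    return True


def test_validate_agrees_with_bruteforce_enumeration(ctx):
    """On generated expressions (and corrupted variants) the engine's
    verdict equals exhaustive enumeration of all (refinement, rule)
    pairs."""
    rng = random.Random(13)
    exprs = make_expressions(
        ctx.graph, ctx.rules, 120,
        GeneratorParams(seed=21, extension_fraction=0.4, pce_fraction=0.9),
    )
    pool = [parse(t) for t in exprs]
    # swap first values for an out-of-range concept to exercise invalid
    # verdicts as well
    swap = ConceptToken(sctid=fx.BODY_STRUCTURE)
    for expr in pool[:40]:
        if expr.ungrouped:
            first = expr.ungrouped[0]
            pool.append(
                Expression(
                    expr.focus,
                    (type(first)(first.attribute, swap),) + expr.ungrouped[1:],
                    expr.groups,
                )
            )
    for expr in pool:
        assert (
            validate(expr, ctx.rules, ctx.graph).valid
            == brute_force_valid(expr, ctx.rules, ctx.graph)
        ), serialize(expr)


def _resolve_ast_path(expr, path: str):
    """Follow a violation path like ``groups[0][1].value.ungrouped[0]`` and
    return the AST node it names (raises if the path is dangling)."""
    node = expr
    for step in path.split("."):
        name = step.split("[")[0]
        if name:
            node = getattr(node, name)
        for i in [int(x) for x in step.replace("]", " ").split("[")[1:]]:
            node = node[i]
    return node


def test_violation_paths_point_at_real_nodes(ctx):
    bad = parse(
        f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = \"big\", {fx.WITHOUT} = #2 "
        f"{{ {fx.FINDING_CONTEXT} = #3 }}"
    )
    report = validate(bad, ctx.rules, ctx.graph)
    assert not report.valid
    assert len(report.violations) >= 3
    for v in report.violations:
        assert _resolve_ast_path(bad, v.path) is not None


# -- extension ---------------------------------------------------------------


def test_widening_produces_union(ctx):
    base = fx.base_rules()
    extended = extend(
        base, [WidenDomain(fx.FINDING_CONTEXT, parse_constraint(f"<< {fx.CLINICAL_FINDING}"))]
    )
    rule = extended.rules_for(fx.FINDING_CONTEXT)[0]
    assert f"<< {fx.SITUATION} OR << {fx.CLINICAL_FINDING}" == rule.domain.to_text()


def test_extend_adds_new_rules_and_rejects_missing(ctx):
    base = fx.base_rules()
    out = extend(base, fx.extension_deltas())
    assert fx.DATE in out.attribute_ids
    assert out.rules_for(fx.DATE)[0].range.to_text() == "date"
    with pytest.raises(RuleError):
        extend(base, [WidenRange("999999999999", parse_constraint("num"))])


def test_extend_empty_deltas_is_identity():
    base = fx.base_rules()
    assert extend(base, [], name=base.name).rules == base.rules


def test_extension_is_monotone(ctx):
    """Expressions valid under the base rules stay valid under the extended
    rules: the extensions are strictly permissive."""
    exprs = make_expressions(
        ctx.graph, ctx.base_rules, 300,
        GeneratorParams(seed=31, extension_fraction=0.0, pce_fraction=0.8),
    )
    for text in exprs:
        expr = parse(text)
        assert validate(expr, ctx.base_rules, ctx.graph).valid, text
        assert validate(expr, ctx.rules, ctx.graph).valid, text


# -- rule-set I/O ------------------------------------------------------------


def test_rules_roundtrip(tmp_path):
    for rules in (fx.base_rules(), fx.extended_rules()):
        path = tmp_path / f"{rules.name}.tsv"
        write_rules(rules, path)
        again = read_rules(path, name=rules.name, version=rules.version)
        assert again.rules == rules.rules


def test_shipped_extension_file_has_13_attributes():
    rules = read_rules(fx.data_path("mrcm_extension.tsv"))
    assert len(rules.attribute_ids) == 13
    assert rules.attribute_ids == fx.EXTENSION_ATTRIBUTE_IDS


def test_rules_file_syntax_error_carries_row(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "attributeId\tdomain\trange\tcardinality\tgroupable\n"
        f"{fx.WITH_SIZE}\t<<<x\tnum\toptional-many\ttrue\n"
    )
    with pytest.raises(ConstraintSyntaxError, match=":2"):
        read_rules(path)
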