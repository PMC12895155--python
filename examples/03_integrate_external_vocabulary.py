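"""Integrate an external vocabulary end to end: eligibility checklist,
attachment beneath a proximal primitive parent, grammar support, and the
new concept-model rule.

Run:  python examples/03_integrate_external_vocabulary.py
"""

from fdg import (
    evaluate_selection_criteria,
    is_subsumed_by,
    parse,
    proximal_primitive_parent,
    validate,
)
from fdg import fixtures as fx
from fdg.mrcm import extend
from fdg.synthetic_data import GeneratorParams, make_fixture_graph

# 1. Is the candidate vocabulary eligible at all?  Pango (SARS-CoV-2
#    lineages) covers a genuine gap, is concept-based, hierarchical,
#    versioned and widely recognized.
report = evaluate_selection_criteria(
    gap_covered=True, concept_based=True, hierarchical=True,
    versioned=True, recognized_standard=True,
)
print("Pango eligible:", report.accepted)

# 2. Where does it belong?  The cluster parent's proximal primitive parent
#    decides the attachment point.  SARS-CoV-2 is fully defined here, so
#    the walk climbs to the first primitive ancestor.
graph = make_fixture_graph(GeneratorParams(seed=1))
ppp = proximal_primitive_parent(fx.SARS_COV_2, graph)
print("proximal primitive parent of SARS-CoV-2:",
      {graph.concept(p).term for p in ppp})

# 3. Attach the lineages beneath the virus-strain parent; they now take
#    part in subsumption like native concepts.
graph.attach(fx.pango_vocabulary())
print("B.1.1.7 << Organism:",
      is_subsumed_by("~Pango~B.1.1.7~", fx.ORGANISM, graph))
print("B.1.1.7 << B:",
      is_subsumed_by("~Pango~B.1.1.7~", "~Pango~B~", graph))

# 4. License the refinement with a new rule and validate the expression
#    that motivated the whole exercise.
rules = extend(fx.extended_rules(), [fx.strain_rule_delta()])
expr = parse(f"{fx.SARS_COV_2} : {fx.MICROBIOLOGICAL_STRAIN} = ~Pango~B.1.1.7~")
print("without the strain rule:",
      validate(expr, fx.extended_rules(), graph).verdict)
print("with the strain rule:   ", validate(expr, rules, graph).verdict)
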