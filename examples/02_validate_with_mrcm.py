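"""Validate expressions against the machine-readable concept model and see
how the permissive extensions widen what is sayable.

Run:  python examples/02_validate_with_mrcm.py
"""

from fdg import parse, validate
from fdg import fixtures as fx
from fdg.synthetic_data import GeneratorParams, make_default_context

ctx = make_default_context(GeneratorParams(seed=1))

# Uncertainty: a finding refined directly with "Finding context".  The base
# model confines that attribute to the situation hierarchy; the extended
# model widens its domain to clinical findings.
finding = sorted(ctx.graph.children_of(fx.CLINICAL_FINDING))[0]
uncertain = parse(f"{finding} : {fx.FINDING_CONTEXT} = {fx.KNOWN_POSSIBLE}")
print("uncertainty under base rules:    ",
      validate(uncertain, ctx.base_rules, ctx.graph).verdict)
print("uncertainty under extended rules:",
      validate(uncertain, ctx.rules, ctx.graph).verdict)

# Negation: a hernia repair performed without a mesh.
no_mesh = parse(f"{fx.HERNIA_REPAIR} : {fx.WITHOUT} = {fx.SURGICAL_MESH}")
print("negation under extended rules:   ",
      validate(no_mesh, ctx.rules, ctx.graph).verdict)

# Scalars: sizes must be numbers; a quoted word is the wrong literal type.
good = parse(f"{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = #8")
bad = parse(f'{fx.SURGICAL_MESH} : {fx.WITH_SIZE} = "large"')
print("size #8:", validate(good, ctx.rules, ctx.graph).verdict)
report = validate(bad, ctx.rules, ctx.graph)
print('size "large":', report.verdict, "->",
      [(v.code, v.path) for v in report.violations])
# Every violation names a code and the AST node it concerns.
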