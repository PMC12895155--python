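"""Parse and serialize postcoordinated expressions, including external
references and concrete values.

Run:  python examples/01_parse_expressions.py
"""

from fdg import parse, serialize, features_used, parse_external_ref
from fdg.fixtures import EXTENSION_ATTRIBUTE_IDS

# a procedure refined by a negation attribute, written untidily
messy = "71388002 |Procedure| :45169001|Without|=  260787004"
expr = parse(messy)
print("canonical: ", serialize(expr))
print("as written:", serialize(expr, canonical=False))
# The canonical form is unique: sorted, single-spaced, display terms
# dropped. Whitespace and term noise never change the AST.

# a versioned external reference, usable anywhere a concept may appear
ref = parse_external_ref("~CTCAE~v5.0~4028512~")
print("external ref -> vocabulary=%s version=%s id=%s"
      % (ref.vocabulary_key, ref.version, ref.local_id))

# concrete values: numbers carry a '#', dates travel as quoted strings
scalar = parse('71388002 : 103373006 = #8, 410671006 = "2021-03-15"')
feats = features_used(scalar, EXTENSION_ATTRIBUTE_IDS)
print("scalar expression features:", feats)
# uses_extension_attribute=True because 103373006 (With size) and
# 410671006 (Date) belong to the shipped extension-attribute set.
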