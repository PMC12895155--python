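attributeId	domain	range	cardinality	groupable
408729009	<< 243796009	<< 362981000	optional-many	true
408730004	<< 243796009	<< 362981000	optional-many	true
363698007	<< 404684003	<< 123037004	optional-many	true
116676008	<< 404684003	<< 362981000	optional-many	true
260686004	<< 71388002	<< 362981000	optional-many	true
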