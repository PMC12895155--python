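attributeId	domain	range	cardinality	groupable
408729009	<< 243796009 OR << 404684003	<< 362981000	optional-many	true
408730004	<< 243796009 OR << 71388002	<< 362981000	optional-many	true
45169001	<< 404684003 OR << 71388002	<< 260787004 OR << 404684003 OR << 71388002	optional-many	true
5185003	<< 404684003 OR << 71388002	<< 260787004 OR << 404684003 OR << 71388002	optional-many	true
103373006	<< 404684003 OR << 71388002 OR << 363787002 OR << 260787004	num	optional-many	true
246205007	<< 404684003 OR << 71388002 OR << 363787002 OR << 260787004	num	optional-many	true
246262008	<< 404684003 OR << 71388002 OR << 363787002 OR << 260787004	num	optional-many	true
79409006	<< 404684003 OR << 71388002 OR << 363787002 OR << 260787004	num	optional-many	true
410671006	<< 404684003 OR << 71388002 OR << 363787002 OR << 260787004	date	optional-many	true
255234002	<< 404684003 OR << 71388002	<< 404684003 OR << 71388002 OR date	optional-many	true
288556008	<< 404684003 OR << 71388002	<< 404684003 OR << 71388002 OR date	optional-many	true
371881003	<< 404684003 OR << 71388002	<< 404684003 OR << 71388002 OR date	optional-many	true
103335007	<< 404684003 OR << 71388002	num	optional-many	true
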