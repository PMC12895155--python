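id	term	definition_status	parents
5185003	Except for (attribute)	primitive	246061005
45169001	Without (attribute)	primitive	246061005
71388002	Procedure	primitive	138875005
79409006	Resulting in (attribute)	primitive	246061005
99900013	Microbiological strain (attribute, synthetic)	primitive	246061005
99900021	Virus strain (synthetic)	primitive	99900032
99900032	Virus (synthetic)	primitive	410607006
99900045	Hernia repair (synthetic)	fully_defined	71388002
99900050	Surgical mesh (synthetic)	primitive	260787004
99900066	Heart rate (synthetic)	primitive	363787002
103335007	Duration (attribute)	primitive	246061005
103373006	With size (attribute)	primitive	246061005
116676008	Associated morphology (attribute)	primitive	246061005
123037004	Body structure	primitive	138875005
138875005	Terminology root concept	primitive	
243796009	Situation with explicit context	primitive	138875005
246061005	Attribute	primitive	138875005
246205007	Quantity (attribute)	primitive	246061005
246262008	Score (attribute)	primitive	246061005
255234002	After (attribute)	primitive	246061005
260686004	Method (attribute)	primitive	246061005
260787004	Physical object	primitive	138875005
288556008	Before (attribute)	primitive	246061005
362981000	Qualifier value	primitive	138875005
363698007	Finding site (attribute)	primitive	246061005
363787002	Observable entity	primitive	138875005
371881003	During (attribute)	primitive	246061005
404684003	Clinical finding	primitive	138875005
408729009	Finding context (attribute)	primitive	246061005
408730004	Procedure context (attribute)	primitive	246061005
410590009	Known possible (qualifier value)	primitive	362981000
410607006	Organism	primitive	138875005
410671006	Date (attribute)	primitive	246061005
840533007	SARS-CoV-2	fully_defined	99900032
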