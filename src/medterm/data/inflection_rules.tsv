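rule_id	singular_suffix	plural_suffix
r01	ix	ices
r02	nx	nges
r03	x	ges
r04	y	ies
r05	is	es
r06	ma	mata
r07	um	a
r08	a	ae
r09	us	i
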