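form	kind	combining_forms	meanings	organ_system
pnea	suffix	pnea	breathing	respiratory
itis	suffix	itis	inflammation
dynia	suffix	dynia	pain,discomfort
algia	suffix	algia	pain
ism	suffix	ism	state,of,or,condition
rrhea	suffix	rrhea	flow,excessive,discharge
sclerosis	suffix	sclerosis	hardening
spasm	suffix	spasm	sudden,or,involuntary
lithiasis	suffix	lithiasis	calculus,or,stone
emia	suffix	emia	blood,condition
megaly	suffix	megaly	enlargement
pathy	suffix	pathy	disease
ectomy	suffix	ectomy	surgical,removal
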