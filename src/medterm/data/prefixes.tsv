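form	kind	combining_forms	meanings	organ_system
dys	prefix		painful
hyper	prefix		excessive,or,above
hypo	prefix		deficient,or,below
choledoch	prefix	choledocho	common,bile,duct	digestive
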