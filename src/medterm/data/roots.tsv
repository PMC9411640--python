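form	kind	combining_forms	meanings	organ_system
mast	root	masto	breast	reproductive
prostat	root	prostato	prostate,gland	reproductive
derm	root	dermo	skin	integumentary
dermat	root	dermato	skin	integumentary
arteri	root	arterio	artery	cardiovascular
blephar	root	blepharo	eyelid,or,eyelash	sensory
urethr	root	urethro	urethra	urinary
choledoch	root	choledocho	common,bile,duct	digestive
lip	root	lipo	fat
pneum	root	pneumo	lung	respiratory
cardi	root	cardio	heart	cardiovascular
gastr	root	gastro	stomach	digestive
nephr	root	nephro	kidney	urinary
hepat	root	hepato	liver	digestive
oste	root	osteo	bone	skeletal
my	root	myo	muscle	muscular
neur	root	neuro	nerve	nervous
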