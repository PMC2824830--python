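# Reference crossover geometry for the eight benchmark crystal structures
# (NDB accessions).  One row per reported crossover: entries appearing under
# both a right-handed and a left-handed mode carry two rows.
# Angles in degrees, signed (+ right-handed, - left-handed).
entry_id	mode	space_group	sequence	cation	angle_deg
BD0022	Major-groove/backbone	R3	ACCGGCGCCACA	Mg	79
BD0015	Major-groove/backbone	R3	CCGCCGGCGG	Mg	78
BD0015	Major <> Minor	R3	CCGCCGGCGG		-78
BDJ060	Major-groove/backbone	C121	CTCTCGAGAG	Ca	42
BDJ060	Major <> Major	C121	CTCTCGAGAG		-42
BD0028	Major-groove/backbone	C121	CCGCTAGCGG		50
BD0028	Major <> Major	C121	CCGCTAGCGG		-50
BDJ069	Minor-groove/backbone	C121	CGCAATTGCG		38
BD0047	Major-groove/backbone	P3121	GCAAACGTTTGC		61
BD0084	Minor <> Minor	P31	CCGAGCTCGG		-60
PD0287	Major-groove/backbone	P212121	NCP	Mn	67
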