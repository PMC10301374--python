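domain_kind	positions	expected	meaning
AT	197-200	HAFH	at-motif-malonyl
AT	197-200	YASH	at-motif-methylmalonyl
KR	144	S	kr-triad-ser
KR	157	Y	kr-triad-tyr
KR	161	N	kr-triad-asn
KR	92-94	LDD	kr-b-fingerprint
KR	140	W	kr-a-fingerprint
KR	64	E	kr-epimerization
DH	45	H	dh-catalytic-his
DH	170	D	dh-catalytic-asp
ER	44	Y	er-tyr44
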