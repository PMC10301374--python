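module_index	gene_id	domains	at_specificity	kr_subtype	dh_active	er_stereo	partial_evidence	cluster_id
0	mldA	AT,T	malonyl					OL257848
1	mldA	KS,AT,KR,T	methylmalonyl	C2			true	OL257848
2	mldB	KS,AT,DH,KR,T	methylmalonyl	B1	true			OL257848
3	mldB	KS,AT,DH,KR,T	methylmalonyl	B1	false			OL257848
4	mldB	KS,AT,KR,T	malonyl	B1				OL257848
5	mldC	KS,AT,KR,T	malonyl	A1				OL257848
6	mldC	KS,AT,DH,ER,KR,T	malonyl	B1	true	2S		OL257848
7	mldC	KS,AT,DH,KR,T	methylmalonyl	B1	true			OL257848
8	mldD	KS,AT,KR,T	methylmalonyl	A1				OL257848
9	mldD	KS,AT,DH,ER,KR,T	malonyl	B1	true	2S		OL257848
10	mldE	KS,AT,KR,T	methylmalonyl	A2				OL257848
11	mldE	KS,AT,KR,T	methylmalonyl	A2			true	OL257848
12	mldF	KS,AT,KR,T	malonyl	A1				OL257848
13	mldF	KS,AT,DH,ER,KR,T	malonyl	B1	true	2S		OL257848
14	mldG	KS,AT,KR,T	methylmalonyl	C1				OL257848
15	mldG	KS,AT,DH,KR,T,TE	methylmalonyl	B1	true			OL257848
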