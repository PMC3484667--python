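# Meiotic mutants on the Drosophila X chromosome recovered by the four
# unbiased screens assayable for nondisjunction, in cytological order.
gene	allele	source
mei-38	mei-38^1	EMS screen (1972)
Klp3A	Klp3A^352	EMS screen (1972)
mei-9	mei-9^a	EMS screen (1972)
mei-9	mei-9^j3	EMS screen (2000)
mei-9	mei-9^357	this article
mei-9	mei-9^140	this article
hdm	hdm^g6	EMS screen (2000)
hdm	hdm^g7	EMS screen (2000)
hdm	hdm^g8	EMS screen (2000)
mei-P26	mei-P26^1	P-element screen (2000)
nod	nod^a	EMS screen (1972)
nod	nod^143	this article
mei-41	mei-41^1	EMS screen (1972)
mei-217	mei-217^g10	EMS screen (2000)
mei-217	mei-217^r1	EMS screen (2000)
mei-217	mei-217^1330	this article
mei-218	mei-218^1	EMS screen (1972)
mei-218	mei-218^6-7	EMS screen (1972)
mei-218	mei-218^j1	EMS screen (2000)
mei-218	mei-218^j2	EMS screen (2000)
mei-218	mei-218^g1	EMS screen (2000)
mei-218	mei-218^g4	EMS screen (2000)
mei-218	mei-218^g9	EMS screen (2000)
mei-218	mei-218^1057	this article
mei-218	mei-218^646	this article
mei-218	mei-218^136	this article
mei-218	mei-218^1940	this article
mei-218	mei-218^621	this article
mei-218	mei-218^125	this article
mei-39	mei-39^1	this article
mei-39	mei-39^129	this article
mei-39	mei-39^166	this article
mei-826	mei-826	this article
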