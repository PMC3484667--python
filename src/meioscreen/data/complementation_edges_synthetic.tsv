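# SYNTHETIC reconstruction of the pairwise transheterozygote X-ND tests
# among the 19 recovered mutants (the original pairwise values were not
# published). Percentages and sample sizes are illustrative; the induced
# fail-to-complement graph matches the reported assignment: 9 groups =
# mei-218 x6, mei-39 x3, mei-9 x2, {mei-114, mei-889, mei-105}, and
# singletons mei-217^1330, nod^143, mei-826, mei-175, mei-86.
allele_a	allele_b	x_ndj_pct	n_progeny
mei-218^125	mei-218^136	43.2	359
mei-218^125	mei-218^621	30.5	276
mei-218^125	mei-218^1057	30.2	193
mei-218^125	mei-218^646	39.0	254
mei-218^125	mei-218^1940	43.9	306
mei-218^136	mei-218^621	41.4	299
mei-218^136	mei-218^1057	34.8	280
mei-218^136	mei-218^646	39.7	369
mei-218^136	mei-218^1940	31.6	255
mei-218^621	mei-218^1057	35.8	260
mei-218^621	mei-218^646	29.9	364
mei-218^621	mei-218^1940	32.0	220
mei-218^1057	mei-218^646	43.6	404
mei-218^1057	mei-218^1940	42.5	255
mei-218^646	mei-218^1940	29.3	416
mei-9^357	mei-9^140	23.5	356
mei-39^1	mei-39^129	44.9	405
mei-39^1	mei-39^166	38.4	294
mei-39^129	mei-39^166	41.8	366
mei-114	mei-889	11.8	228
mei-114	mei-105	12.8	181
mei-889	mei-105	13.5	262
mei-217^1330	mei-218^125	0.9	412
nod^143	mei-9^357	1.2	388
mei-826	mei-39^1	0.8	525
mei-175	mei-114	1.5	203
mei-86	mei-114	1.1	262
mei-175	mei-86	0.9	240
mei-826	mei-218^125	0.6	310
mei-39^1	mei-218^125	0.7	450
mei-217^1330	mei-39^1	1.0	371
nod^143	mei-218^125	1.3	295
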