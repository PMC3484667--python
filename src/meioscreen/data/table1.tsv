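# Progeny counts per (maternal ovum class, paternal sperm class) for the
# X^Y, In(1)EN; C(4)RM nondisjunction assay of the control and 9 mutant
# genotypes; 25 females scored per genotype.
genotype	maternal	paternal	count
y w	X;4	XY;44	366
y w	X;4	0;44	442
y w	0;4	XY;44	1
y w	XX;4	0;44	2
y w	X;0	XY;44	1
y w	X;0	0;44	3
y w	X;44	XY;0	2
y w	X;44	0;0	0
y w	0;0	XY;44	0
y w	XX;44	0;0	0
y w	0;44	XY;0	0
y w	XX;0	0;44	0
mei-39^1	X;4	XY;44	62
mei-39^1	X;4	0;44	99
mei-39^1	0;4	XY;44	20
mei-39^1	XX;4	0;44	32
mei-39^1	X;0	XY;44	21
mei-39^1	X;0	0;44	27
mei-39^1	X;44	XY;0	8
mei-39^1	X;44	0;0	13
mei-39^1	0;0	XY;44	17
mei-39^1	XX;44	0;0	8
mei-39^1	0;44	XY;0	3
mei-39^1	XX;0	0;44	4
mei-39^166	X;4	XY;44	95
mei-39^166	X;4	0;44	135
mei-39^166	0;4	XY;44	33
mei-39^166	XX;4	0;44	33
mei-39^166	X;0	XY;44	22
mei-39^166	X;0	0;44	22
mei-39^166	X;44	XY;0	11
mei-39^166	X;44	0;0	16
mei-39^166	0;0	XY;44	45
mei-39^166	XX;44	0;0	18
mei-39^166	0;44	XY;0	0
mei-39^166	XX;0	0;44	8
mei-39^129	X;4	XY;44	121
mei-39^129	X;4	0;44	140
mei-39^129	0;4	XY;44	22
mei-39^129	XX;4	0;44	37
mei-39^129	X;0	XY;44	12
mei-39^129	X;0	0;44	28
mei-39^129	X;44	XY;0	24
mei-39^129	X;44	0;0	18
mei-39^129	0;0	XY;44	30
mei-39^129	XX;44	0;0	11
mei-39^129	0;44	XY;0	1
mei-39^129	XX;0	0;44	6
mei-826	X;4	XY;44	88
mei-826	X;4	0;44	137
mei-826	0;4	XY;44	30
mei-826	XX;4	0;44	45
mei-826	X;0	XY;44	22
mei-826	X;0	0;44	37
mei-826	X;44	XY;0	18
mei-826	X;44	0;0	22
mei-826	0;0	XY;44	14
mei-826	XX;44	0;0	16
mei-826	0;44	XY;0	4
mei-826	XX;0	0;44	4
mei-217^1330	X;4	XY;44	141
mei-217^1330	X;4	0;44	222
mei-217^1330	0;4	XY;44	25
mei-217^1330	XX;4	0;44	48
mei-217^1330	X;0	XY;44	18
mei-217^1330	X;0	0;44	30
mei-217^1330	X;44	XY;0	18
mei-217^1330	X;44	0;0	20
mei-217^1330	0;0	XY;44	15
mei-217^1330	XX;44	0;0	11
mei-217^1330	0;44	XY;0	2
mei-217^1330	XX;0	0;44	6
mei-218^125	X;4	XY;44	52
mei-218^125	X;4	0;44	39
mei-218^125	0;4	XY;44	14
mei-218^125	XX;4	0;44	13
mei-218^125	X;0	XY;44	7
mei-218^125	X;0	0;44	1
mei-218^125	X;44	XY;0	11
mei-218^125	X;44	0;0	2
mei-218^125	0;0	XY;44	6
mei-218^125	XX;44	0;0	2
mei-218^125	0;44	XY;0	5
mei-218^125	XX;0	0;44	0
mei-218^621	X;4	XY;44	44
mei-218^621	X;4	0;44	75
mei-218^621	0;4	XY;44	10
mei-218^621	XX;4	0;44	15
mei-218^621	X;0	XY;44	8
mei-218^621	X;0	0;44	6
mei-218^621	X;44	XY;0	14
mei-218^621	X;44	0;0	8
mei-218^621	0;0	XY;44	2
mei-218^621	XX;44	0;0	2
mei-218^621	0;44	XY;0	0
mei-218^621	XX;0	0;44	1
mei-218^1940	X;4	XY;44	80
mei-218^1940	X;4	0;44	110
mei-218^1940	0;4	XY;44	15
mei-218^1940	XX;4	0;44	26
mei-218^1940	X;0	XY;44	9
mei-218^1940	X;0	0;44	26
mei-218^1940	X;44	XY;0	11
mei-218^1940	X;44	0;0	12
mei-218^1940	0;0	XY;44	22
mei-218^1940	XX;44	0;0	5
mei-218^1940	0;44	XY;0	0
mei-218^1940	XX;0	0;44	7
mei-218^136	X;4	XY;44	78
mei-218^136	X;4	0;44	108
mei-218^136	0;4	XY;44	17
mei-218^136	XX;4	0;44	31
mei-218^136	X;0	XY;44	11
mei-218^136	X;0	0;44	8
mei-218^136	X;44	XY;0	6
mei-218^136	X;44	0;0	10
mei-218^136	0;0	XY;44	17
mei-218^136	XX;44	0;0	14
mei-218^136	0;44	XY;0	3
mei-218^136	XX;0	0;44	4
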