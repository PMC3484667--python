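# meioscreen

Quantitative analysis for *Drosophila melanogaster* meiotic-mutant screens:
viability-adjusted **X and 4th chromosome nondisjunction** estimation from
tester-cross progeny counts, **complementation-group** inference from pairwise
transheterozygote assays, **screen-saturation** estimation under the classical
Poisson model, and a **generative simulator** of the cross and the screen for
validating every estimator against known truth.

It is written for fly geneticists running (or re-analysing) forward screens
for meiotic chromosome-segregation mutants, where the raw data are counts of
scored progeny classes from crosses to compound-chromosome tester males.

## The model

**Nondisjunction frequencies.** Females are crossed to
`X^Y, In(1)EN; C(4)RM` tester males. An ovum is classified by its X dosage
(0, 1, 2 — nullo, normal, diplo) and 4th-chromosome dosage. Zygote viability
rules leave 12 scorable progeny classes; crucially, an X-exceptional ovum
survives with only one of the two sperm sex classes, so each scored
X-exceptional individual represents two ova. With `E` the summed counts of
X-exceptional classes and `N` the normal-class counts:

```
adjusted total = N + 2E
%X ND          = 100 · 2E / (N + 2E)
%4 ND          = 100 · (F₁ + 2F₂) / (N + 2E)
```

where `F₁`, `F₂` are 4-exceptional counts in X-normal and X-exceptional
classes respectively, with nullo/diplo breakdowns defined analogously.

**Complementation groups** are connected components of the
fail-to-complement graph: a pair of alleles fails to complement when the
transheterozygote's %X ND is at or above a threshold (default 5%, between
control baseline ≪1% and the weakest mutant class) on at least 50 adjusted
progeny.

**Saturation.** With `m` = alleles / loci recovered from unbiased screens,
percentage saturation is `100·(1 − e^(−m))`; a zero-truncated Poisson
class-ratio variant `m = 2·n₂/n₁` uses only loci seen once (`n₁`) and twice
(`n₂`). The lethal hit rate is a binomial proportion with a Wilson score
interval.

## Worked example

The package ships the count table of a published screen (a control and nine
mutants, 25 females each). From Python:

```python
>>> import meioscreen as ms
>>> table = {t.genotype: t for t in ms.load_table1_counts()}["mei-39^1"]
>>> s = ms.summarize(table)
>>> s.raw_total, s.adjusted_total
(314, 398)
>>> round(s.pct_x_ndj, 1), round(s.pct_4_ndj, 1)
(42.2, 33.4)
```

314 progeny were scored; doubling the 84 X-exceptional individuals gives the
adjusted total 398, of which 42.2% of ova nondisjoined the X and 33.4% the
4th — a strong meiotic mutant (the control runs 0.7% / 0.7%). The same via
the CLI:

```
$ meioscreen ndj --counts src/meioscreen/data/table1.tsv
statistic	y w	mei-39^1	...
Adjusted total	820	398	...
% X nondisjunction	0.7	42.2	...
```

Saturation of the X for fertile meiotic mutants, over all four unbiased
screens (11 loci, 33 alleles, m = 3):

```
$ meioscreen saturation --alleles src/meioscreen/data/table3_alleles.tsv
loci	11
alleles	33
m	3.000
saturation_pct	95.0
$ meioscreen hitrate --hits 10 --vials 195
rate_pct	5.1
ci95_pct	2.8	9.2
```

Simulation with known truth (`e` = true X-ND rate among ova):

```
$ meioscreen simulate cross --e 0.4 --f 0.3 --n 200000 --seed 7 --out sim.tsv
$ meioscreen ndj --counts sim.tsv --format json | python -c \
    "import json,sys; print(round(json.load(sys.stdin)[0]['pct_x_ndj'],1))"
39.8
```

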