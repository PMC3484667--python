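# Methods

## The tester cross and viability-adjusted counting

The nondisjunction assay crosses the female under test to
`X^Y, In(1)EN; C(4)RM` males. The male contributes two sperm sex classes
(`XY` and nullo-sex, written `0`) and two 4th-chromosome classes (the
compound `C(4)RM`, written `44`, and nullo-4). Ova are classified by X and
4th dosage, giving 9 ovum classes; the zygote survives only when the dosages
balance:

* X: a nullo-X egg needs the `XY` sperm, a diplo-X egg the nullo-sex sperm,
  a normal egg survives either;
* 4: nullo-4 and normal eggs need the compound-4 sperm, diplo-4 eggs the
  nullo-4 sperm.

Enumerating the rule over all 9 × 4 combinations leaves 12 admissible
progeny classes (a property test brute-forces this). An X-exceptional ovum is
thus recovered with probability 1/2 relative to a normal ovum (one admissible
sperm sex class instead of two), while the 4th-chromosome rule removes
exactly one of the two sperm 4-classes from *every* ovum class and cancels.
Hence X-exceptional classes carry counting weight 2 and 4-exceptional classes
carry no extra weight; the adjusted total is `N + 2E` and

    %X ND = 100·2E/(N+2E),    %4 ND = 100·(F₁+2F₂)/(N+2E),

with `F₁`/`F₂` the 4-exceptional counts within X-normal/X-exceptional
classes. Nullo/diplo breakdowns restrict the numerators to dosage 0 or 2 and
sum exactly to the corresponding ND percentage. The weight is a property of
the maternal class only, and the class table is a registry per cross design,
so other testers can be added as data.

Haplo-4 progeny (normal ovum × nullo-4 sperm) are treated as not scored:
the assay's count tables simply omit the class.

All statistics are exact rational functions of the counts; no rounding
happens internally. Display rounding is half-away-from-zero, with the
headline %X/%4 rows at a fixed one decimal and the nullo/diplo component rows
gaining a second decimal below 1% (so control-level frequencies such as
0.24% remain visible). A stated input total that disagrees with the sum of
the class counts triggers a warning and the computed sum is used; a zero
adjusted total is an error, not 0/0 = 0.

## Complementation grouping

Pairwise transheterozygote assays are classified *fail* / *complement* /
*inconclusive* by two parameters: `fail_threshold` (default 5% X ND) and
`min_n` (default 50 adjusted progeny). The threshold sits between the
control baseline (≪1%) and the weakest mutant class (a few percent up);
only calls near the boundary are sensitive to it, and the consistency report
surfaces those cases. Inconclusive pairs contribute no edge — they are
treated as absent rather than as complementing. Groups are connected
components of the fail graph (networkx), ordered and named by their
lexicographically smallest member; the test suite checks the partition
against a brute-force reachability oracle. The consistency report lists
intransitive triangles, contradictory duplicate calls, and alleles whose own
homozygote phenotype is below threshold despite membership in a multi-allele
group — the situation that makes weak groups unresolvable in practice.

## Saturation and the lethal hit rate

Under equal per-locus mutability the number of alleles per locus is Poisson
with mean m, and saturation is `100·(1 − e^(−m))` with `m = alleles/loci`
counted over loci observed in the table (no unseen-species correction —
richness estimation is out of scope). Because observed loci exclude the
Poisson zero class, the plain ratio is a slightly truncated-inflated
estimate of m; hypermutable loci inflate it further, which the simulator
demonstrates directionally. Two mitigations are provided: explicit gene or
source exclusions, and the zero-truncated class-ratio estimator
`m = 2·n₂/n₁` from the singleton and doubleton locus counts (from
`P(2)/P(1) = m/2`), flagged as unreliable when either class has fewer than
five loci.

The lethal hit rate is `100·hits/vials` with a Wilson score interval
(statsmodels), chosen for its behaviour at small counts; default level 0.95.

## The generative simulator

`simulate_cross` draws ova from a joint distribution over the 9 ovum classes
built from true rates (e, f): exceptionality indicators for X and 4 are
coupled by a mixture — with probability `rho` they share one uniform draw
(comonotone, maximal positive association), otherwise they are independent.
This preserves both marginals exactly for any (e, f, rho), which a naive
"force the indicators equal" coupling does not when e ≠ f. Exceptional ova
split between diplo and nullo with configurable probabilities (default
0.5/0.5; 1/3 diplo reproduces a 2:1 nullo-4 bias). Sperm classes default to
uniform 1/4. Sampling is by multinomial class counts (ova, then sperm within
each ovum class), which is distributionally identical to per-ovum simulation;
the viability filter is then deterministic and consumes no randomness. One
root seed is split into documented child streams (ova, sperm), so outputs
are reproducible bit-for-bit.

Because recovery probabilities are 1/2 (X-normal) vs 1/4 (X-exceptional),
the weight-2 adjusted counting makes the estimated rates unbiased for
(e, f); the test suite verifies this over a grid of rates, at 200,000 ova
and 20 replicates per grid point, within three Monte-Carlo standard errors.
These problem sizes keep each check well under a second while leaving
standard errors of order 0.1 percentage points.

`simulate_mutagenesis` draws per-chromosome hit counts from a Poisson with
the configured mean and assigns them to loci proportionally to relative
mutability weights (default equal), returning the allele table of hits and
the true fraction of loci hit — the quantity the saturation formula targets.
`simulate_vial_selection` models the screen's selection step: scorable
progeny arise only through 2nd-chromosome nondisjunction in the female, with
half of the exceptional zygote classes viable, so progeny per vial is
Poisson(mean progeny × ndj2 rate / 2), and vials under the pupae threshold
(default 2, the screen's discard rule) are dropped.

### What the simulator does and does not emulate

It emulates the statistical skeleton of the screen: multinomial ova with
independent or positively associated X/4 errors, fixed sperm-class
frequencies, deterministic zygote viability, Poissonian mutational hits with
mutability heterogeneity, and vial-level truncation. It does not model
recombination or interference, clone-induction efficiency, fecundity
variation, sperm-viability asymmetries of the X^Y male beyond the
configurable frequencies, or maternal-effect classes. Passing tests
therefore certify the estimators' arithmetic and their unbiasedness under
the stated sampling model, not robustness to biological effects outside it;
screen-level yields (candidate and confirmed mutant counts) depend on
unmodelled wet-lab variables and are deliberately not calibration targets.

## Numerical and interface choices

* Tables are tab-separated UTF-8 with `#` comments; validation errors carry
  1-based line numbers; CLI exit codes are 0 (success) and 2 (validation).
* Strict reading requires all 12 classes per genotype; lenient zero-fills.
* JSON reports carry unrounded values and round-trip exactly; TSV/markdown
  apply display rounding.
* The packaged complementation fixture is a synthetic reconstruction (the
  original pairwise values were unpublished): percentages are illustrative,
  the induced partition matches the reported nine groups.
* The labels `0;0` and `0;44` are valid for both ovum and sperm classes;
  role-free parsing rejects them as ambiguous and the file format always
  supplies the role by column.
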