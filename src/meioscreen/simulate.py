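"""Generative models of the tester cross and the germline-clone screen.

`simulate_cross` draws ova from a joint (X, 4th) meiotic-error distribution,
pairs them with sperm of the X^Y tester male, applies the zygote viability
rules of the cross design, and returns a scored progeny-count table — the
same object the estimators consume.  Because a normal-X ovum survives with
both sperm sex classes while an X-exceptional ovum survives with one (recovery
1/2 vs 1/4 of ova after the uniform 4th-chromosome halving), the adjusted
(weight-2) counting makes the estimated rates unbiased for the true (e, f).

`simulate_mutagenesis` and `simulate_vial_selection` emulate the screen
itself: Poisson mutational hits spread over loci with configurable relative
mutability, and vial-level selection where progeny only appear via
2nd-chromosome nondisjunction in the female and sparse vials are discarded.

Randomness: one root seed; child streams are split in the documented order
(ova, sperm) for the cross and (hits, loci, vials) for the screen, so outputs
are reproducible per config + seed.  Exact per-class counts are drawn with
multinomials — distributionally identical to per-ovum sampling; the viability
filter is deterministic given the class pair and consumes no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross_model import (
    ALL_MATERNAL_CLASSES,
    ALL_PATERNAL_CLASSES,
    CrossDesign,
    MaternalGameteClass,
    PaternalGameteClass,
    xy_c4rm_tester,
)
from .ndj import ProgenyCountTable

__all__ = [
    "CrossSimConfig",
    "ScreenSimConfig",
    "ovum_class_probabilities",
    "simulate_cross",
    "simulate_mutagenesis",
    "simulate_vial_selection",
]

SIM_SOURCE = "simulated_screen"


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class CrossSimConfig:
    """True parameters of one simulated nondisjunction assay.

    e, f
        True X and 4th chromosome nondisjunction rates among ova.
    rho
        Mixture weight coupling the two exceptionality events: with
        probability ``rho`` the two indicators are drawn from one shared
        uniform (maximal positive association), otherwise independently.
        Marginals stay exactly e and f for any rho.
    p_diplo_given_exc_x, p_diplo_given_exc_4
        Split of exceptional ova between diplo (probability given) and nullo.
    sperm_frequencies
        Probability per paternal class; default uniform 1/4 (sex and 4th
        classes independent at 1/2 each).
    """

    e: float
    f: float
    n_ova: int
    rho: float = 0.0
    p_diplo_given_exc_x: float = 0.5
    p_diplo_given_exc_4: float = 0.5
    sperm_frequencies: Mapping[PaternalGameteClass, float] | None = None
    seed: int | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        for name in ("e", "f", "rho", "p_diplo_given_exc_x", "p_diplo_given_exc_4"):
            _check_prob(name, getattr(self, name))
        if self.n_ova < 1:
            raise ValueError(f"n_ova must be at least 1, got {self.n_ova}")
        if self.sperm_frequencies is not None:
            freqs = dict(self.sperm_frequencies)
            if set(freqs) != set(ALL_PATERNAL_CLASSES):
                raise ValueError("sperm_frequencies must cover all 4 paternal classes")
            total = sum(freqs.values())
            if any(p < 0 for p in freqs.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError("sperm_frequencies must be nonnegative and sum to 1")

    def sperm_probs(self) -> dict[PaternalGameteClass, float]:
        if self.sperm_frequencies is None:
            return {c: 0.25 for c in ALL_PATERNAL_CLASSES}
        return dict(self.sperm_frequencies)


def ovum_class_probabilities(config: CrossSimConfig) -> dict[MaternalGameteClass, float]:
    """Joint distribution over the 9 ovum classes implied by the config."""
    e, f, rho = config.e, config.f, config.rho
    # joint of the two exceptionality indicators: rho-mixture of the
    # comonotone coupling (shared uniform -> P(both) = min(e, f)) and
    # independence; marginals are exact under both components.
    p11 = rho * min(e, f) + (1.0 - rho) * e * f
    p10 = e - p11
    p01 = f - p11
    p00 = 1.0 - e - f + p11
    ind = {(1, 1): p11, (1, 0): p10, (0, 1): p01, (0, 0): p00}

    def x_split(exc: int) -> dict[int, float]:
        if not exc:
            return {1: 1.0}
        return {2: config.p_diplo_given_exc_x, 0: 1.0 - config.p_diplo_given_exc_x}

    def four_split(exc: int) -> dict[int, float]:
        if not exc:
            return {1: 1.0}
        return {2: config.p_diplo_given_exc_4, 0: 1.0 - config.p_diplo_given_exc_4}

    probs = {cls: 0.0 for cls in ALL_MATERNAL_CLASSES}
    for (ix, i4), p_ind in ind.items():
        for xd, px in x_split(ix).items():
            for fd, pf in four_split(i4).items():
                probs[MaternalGameteClass(xd, fd)] += p_ind * px * pf
    return probs


def simulate_cross(
    config: CrossSimConfig,
    design: CrossDesign | None = None,
    rng: np.random.Generator | None = None,
) -> ProgenyCountTable:
    """Simulate one scored nondisjunction assay.

    Samples ``n_ova`` ovum classes from the joint (X, 4th) distribution, pairs
    each with a sperm class at the configured frequencies, discards inviable
    (inadmissible) zygotes and returns counts over the design's admissible
    progeny classes.
    """
    if design is None:
        design = xy_c4rm_tester()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rng_ova, rng_sperm = rng.spawn(2)

    ovum_probs = ovum_class_probabilities(config)
    maternal_classes = list(ovum_probs)
    ova_counts = rng_ova.multinomial(config.n_ova, list(ovum_probs.values()))

    sperm_probs = config.sperm_probs()
    paternal_classes = list(sperm_probs)
    sperm_p = list(sperm_probs.values())

    counts: dict = {cls: 0 for cls in design.admissible_classes}
    by_pair = {(c.maternal, c.paternal): c for c in design.admissible_classes}
    for m_cls, n_m in zip(maternal_classes, ova_counts):
        if n_m == 0:
            continue
        sperm_counts = rng_sperm.multinomial(int(n_m), sperm_p)
        for p_cls, n_mp in zip(paternal_classes, sperm_counts):
            cls = by_pair.get((m_cls, p_cls))
            if cls is not None:  # inadmissible zygotes die unscored
                counts[cls] += int(n_mp)

    genotype = config.genotype or f"sim(e={config.e}, f={config.f})"
    return ProgenyCountTable(genotype=genotype, counts=counts, design=design)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of a simulated germline-clone mutagenesis screen.

    n_chromosomes mutagenized chromosomes are screened, each receiving a
    Poisson(expected_hits_per_chromosome) number of meiotic-gene hits spread
    over ``n_loci`` loci in proportion to ``relative_mutability`` (default
    equal).  Vial-level selection: a vial yields scorable progeny only through
    2nd-chromosome nondisjunction in the female (rate ``baseline_ndj2`` or
    ``mutant_ndj2``), of which half the exceptional zygote classes are viable;
    vials with fewer than ``min_pupae_keep`` pupae are discarded.
    """

    n_chromosomes: int
    n_loci: int
    expected_hits_per_chromosome: float
    relative_mutability: Sequence[float] | None = None
    progeny_per_vial_mean: float = 200.0
    baseline_ndj2: float = 0.001
    mutant_ndj2: float = 0.3
    min_pupae_keep: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 0:
            raise ValueError("n_chromosomes must be nonnegative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be at least 1")
        if self.expected_hits_per_chromosome < 0:
            raise ValueError("expected_hits_per_chromosome must be nonnegative")
        if self.progeny_per_vial_mean < 0:
            raise ValueError("progeny_per_vial_mean must be nonnegative")
        for name in ("baseline_ndj2", "mutant_ndj2"):
            _check_prob(name, getattr(self, name))
        if self.min_pupae_keep < 0:
            raise ValueError("min_pupae_keep must be nonnegative")
        if self.relative_mutability is not None:
            w = np.asarray(self.relative_mutability, dtype=float)
            if w.shape != (self.n_loci,):
                raise ValueError(
                    f"relative_mutability must have length n_loci={self.n_loci}"
                )
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("relative_mutability must be nonnegative, not all zero")

    def locus_probs(self) -> np.ndarray:
        if self.relative_mutability is None:
            return np.full(self.n_loci, 1.0 / self.n_loci)
        w = np.asarray(self.relative_mutability, dtype=float)
        return w / w.sum()


def simulate_mutagenesis(
    config: ScreenSimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate mutational hits across the screen.

    Returns an allele table (gene/allele/source rows, one per hit) together
    with hit statistics, including the true fraction of loci hit at least
    once — the quantity the Poisson saturation formula estimates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rng_hits, rng_loci, _rng_vials = rng.spawn(3)

    hits_per_chrom = rng_hits.poisson(
        config.expected_hits_per_chromosome, size=config.n_chromosomes
    )
    total_hits = int(hits_per_chrom.sum())
    locus_ids = rng_loci.choice(config.n_loci, size=total_hits, p=config.locus_probs())

    records = []
    k = 0
    for chrom, n_hits in enumerate(hits_per_chrom):
        for j in range(int(n_hits)):
            records.append(
                {
                    "gene": f"locus{int(locus_ids[k]):05d}",
                    "allele": f"chr{chrom}.{j}",
                    "source": SIM_SOURCE,
                }
            )
            k += 1
    alleles = pd.DataFrame(records, columns=["gene", "allele", "source"])

    hits_by_locus = np.bincount(locus_ids, minlength=config.n_loci)
    stats = {
        "n_chromosomes": config.n_chromosomes,
        "n_loci": config.n_loci,
        "total_hits": total_hits,
        "n_loci_hit": int((hits_by_locus > 0).sum()),
        "fraction_loci_hit": float((hits_by_locus > 0).mean()),
        "mean_hits_per_locus": total_hits / config.n_loci,
    }
    return alleles, stats


def simulate_vial_selection(
    config: ScreenSimConfig,
    ndj2_rate: float | None = None,
    n_vials: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-vial progeny yields and the keep/discard decision.

    Progeny per vial ~ Poisson(progeny_per_vial_mean * ndj2_rate / 2): a
    scored offspring requires a diplo-2 ovum (rate ``ndj2_rate``) and only
    half of the exceptional zygote classes are viable, mirroring the X-class
    viability logic applied to chromosome 2.  A vial is kept iff its progeny
    count reaches ``min_pupae_keep``.  ``ndj2_rate`` defaults to the baseline
    (non-mutant) rate; ``n_vials`` defaults to ``n_chromosomes``.
    """
    if ndj2_rate is None:
        ndj2_rate = config.baseline_ndj2
    _check_prob("ndj2_rate", ndj2_rate)
    if n_vials is None:
        n_vials = config.n_chromosomes
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _rng_hits, _rng_loci, rng_vials = rng.spawn(3)

    lam = config.progeny_per_vial_mean * ndj2_rate * 0.5
    n_progeny = rng_vials.poisson(lam, size=n_vials)
    return pd.DataFrame(
        {
            "vial": np.arange(n_vials),
            "n_progeny": n_progeny,
            "kept": n_progeny >= config.min_pupae_keep,
        }
    )
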