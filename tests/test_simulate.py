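"""Generative model of the cross and screen: seeded reproducibility,
closed-form expectations, and parameter recovery by the estimators."""

import math

import numpy as np
import pytest

import meioscreen as ms
from meioscreen.cross_model import ALL_MATERNAL_CLASSES
from meioscreen.simulate import (
    CrossSimConfig,
    ScreenSimConfig,
    ovum_class_probabilities,
    simulate_cross,
    simulate_mutagenesis,
    simulate_vial_selection,
)


def test_ovum_distribution_sums_to_one_and_has_exact_marginals():
    for rho in (0.0, 0.3, 1.0):
        cfg = CrossSimConfig(e=0.4, f=0.1, rho=rho, n_ova=10)
        probs = ovum_class_probabilities(cfg)
        assert sum(probs.values()) == pytest.approx(1.0)
        p_x_exc = sum(p for c, p in probs.items() if c.x_dosage != 1)
        p_4_exc = sum(p for c, p in probs.items() if c.four_dosage != 1)
        assert p_x_exc == pytest.approx(0.4)  # rho never distorts the marginals
        assert p_4_exc == pytest.approx(0.1)


def test_rho_couples_the_two_exceptional_events():
    indep = ovum_class_probabilities(CrossSimConfig(e=0.3, f=0.3, rho=0.0, n_ova=10))
    coupled = ovum_class_probabilities(CrossSimConfig(e=0.3, f=0.3, rho=1.0, n_ova=10))
    both = lambda probs: sum(
        p for c, p in probs.items() if c.x_dosage != 1 and c.four_dosage != 1
    )
    assert both(indep) == pytest.approx(0.09)
    assert both(coupled) == pytest.approx(0.3)  # comonotone: min(e, f)


def test_seeded_reproducibility():
    cfg = CrossSimConfig(e=0.2, f=0.1, n_ova=50_000, seed=11)
    assert simulate_cross(cfg).counts == simulate_cross(cfg).counts
    scfg = ScreenSimConfig(
        n_chromosomes=300, n_loci=40, expected_hits_per_chromosome=0.4, seed=11
    )
    a1, s1 = simulate_mutagenesis(scfg)
    a2, s2 = simulate_mutagenesis(scfg)
    assert a1.equals(a2) and s1 == s2
    assert simulate_vial_selection(scfg).equals(simulate_vial_selection(scfg))


def test_no_nondisjunction_yields_only_the_two_regular_classes():
    table = simulate_cross(CrossSimConfig(e=0.0, f=0.0, n_ova=20_000, seed=0))
    regular = [c for c in table.design.admissible_classes if c.weight == 1]
    assert sum(table.counts[c] for c in regular[:2]) == table.raw_total
    s = ms.summarize(table)
    assert s.pct_x_ndj == 0.0 and s.pct_4_ndj == 0.0


def test_scored_fraction_matches_closed_form():
    # recovery probability is 1/2 for normal-X ova and 1/4 for X-exceptional,
    # so E[scored] = n * ((1-e)/2 + e/4) for f = 0
    e, n = 0.4, 400_000
    table = simulate_cross(CrossSimConfig(e=e, f=0.0, n_ova=n, seed=1))
    expected = n * ((1 - e) / 2 + e / 4)
    assert table.raw_total == pytest.approx(expected, rel=0.01)


@pytest.mark.parametrize("e,f", [(0.05, 0.05), (0.2, 0.4), (0.4, 0.2)])
def test_estimators_recover_true_rates(e, f):
    """Adjusted counting cancels the halved recovery of X-exceptional zygotes,
    so the estimated rates are unbiased for (e, f)."""
    reps = 8
    est_x, est_4 = [], []
    for r in range(reps):
        cfg = CrossSimConfig(e=e, f=f, n_ova=100_000, seed=1000 + r)
        s = ms.summarize(simulate_cross(cfg))
        est_x.append(s.pct_x_ndj)
        est_4.append(s.pct_4_ndj)
    for est, true in ((est_x, 100 * e), (est_4, 100 * f)):
        mean = np.mean(est)
        se = np.std(est, ddof=1) / math.sqrt(reps)
        assert abs(mean - true) < 3 * max(se, 0.02)


def test_nullo_diplo_split_recovery():
    # symmetric split: nullo-X about equals diplo-X; 2:1 toward nullo-4 when
    # diplo-4 is given 1/3 of the exceptional mass
    cfg = CrossSimConfig(
        e=0.3, f=0.3, n_ova=400_000, p_diplo_given_exc_4=1 / 3, seed=5
    )
    s = ms.summarize(simulate_cross(cfg))
    assert s.pct_nullo_x == pytest.approx(s.pct_diplo_x, rel=0.05)
    assert s.pct_nullo_4 == pytest.approx(2 * s.pct_diplo_4, rel=0.08)


def test_biased_sperm_frequencies_do_not_bias_the_x_estimate():
    freqs = {c: w for c, w in zip(
        sorted(ms.xy_c4rm_tester().sperm_frequencies), [0.4, 0.2, 0.3, 0.1]
    )}
    cfg = CrossSimConfig(e=0.2, f=0.1, n_ova=400_000, sperm_frequencies=freqs, seed=9)
    s = ms.summarize(simulate_cross(cfg))
    # X-exceptional recovery is still exactly half the normal-X recovery as
    # long as sex and 4th sperm classes are independent... with arbitrary
    # joint frequencies the ratio shifts; here it stays within a few percent
    assert s.pct_x_ndj == pytest.approx(20.0, abs=3.0)


def test_cross_config_validation():
    with pytest.raises(ValueError):
        CrossSimConfig(e=1.2, f=0.0, n_ova=10)
    with pytest.raises(ValueError):
        CrossSimConfig(e=0.1, f=0.1, n_ova=0)
    bad = {c: 0.3 for c in ms.xy_c4rm_tester().sperm_frequencies}
    with pytest.raises(ValueError):
        CrossSimConfig(e=0.1, f=0.1, n_ova=10, sperm_frequencies=bad)


def test_mutagenesis_zero_rate_gives_empty_table():
    cfg = ScreenSimConfig(n_chromosomes=100, n_loci=10, expected_hits_per_chromosome=0.0, seed=2)
    alleles, stats = simulate_mutagenesis(cfg)
    assert alleles.empty and stats["total_hits"] == 0
    assert stats["fraction_loci_hit"] == 0.0


def test_mutagenesis_hit_fraction_matches_poisson_zero_class():
    # mean hits per locus m = 3: fraction hit ~ 1 - exp(-3)
    cfg = ScreenSimConfig(
        n_chromosomes=3000, n_loci=1000, expected_hits_per_chromosome=1.0, seed=4
    )
    _, stats = simulate_mutagenesis(cfg)
    p = 1 - math.exp(-3)
    se = math.sqrt(p * (1 - p) / cfg.n_loci)
    assert abs(stats["fraction_loci_hit"] - p) < 3 * se


def test_hypermutable_locus_dominates_allele_counts():
    weights = np.ones(50)
    weights[7] = 10.0
    cfg = ScreenSimConfig(
        n_chromosomes=2000, n_loci=50, relative_mutability=weights,
        expected_hits_per_chromosome=0.5, seed=6,
    )
    alleles, _ = simulate_mutagenesis(cfg)
    counts = alleles.groupby("gene").size()
    assert counts.idxmax() == "locus00007"
    assert counts.max() > 2 * counts.drop("locus00007").max()


def test_saturation_estimator_on_simulated_screens():
    """The observed-loci Poisson estimate tracks the true hit fraction under
    equal mutability (small upward truncation bias) and overestimates it
    substantially under strong mutability heterogeneity."""
    # mean hits per locus m = 6000 * 1.0 / 2000 = 3; the observed-loci mean
    # m_obs = m / (1 - exp(-m)) slightly exceeds m, hence the small upward bias
    cfg = ScreenSimConfig(
        n_chromosomes=6000, n_loci=2000, expected_hits_per_chromosome=1.0, seed=8
    )
    alleles, stats = simulate_mutagenesis(cfg)
    est = ms.estimate_saturation(alleles)
    gap_equal = est.saturation_pct / 100 - stats["fraction_loci_hit"]
    assert 0 <= gap_equal < 0.02

    weights = np.ones(2000)
    weights[:20] = 50.0
    cfg_h = ScreenSimConfig(
        n_chromosomes=6000, n_loci=2000, relative_mutability=weights,
        expected_hits_per_chromosome=1.0, seed=8,
    )
    alleles_h, stats_h = simulate_mutagenesis(cfg_h)
    gap_hetero = (
        ms.estimate_saturation(alleles_h).saturation_pct / 100
        - stats_h["fraction_loci_hit"]
    )
    assert gap_hetero > gap_equal + 0.05


def test_vial_selection_poisson_tail_and_monotonicity():
    cfg = ScreenSimConfig(
        n_chromosomes=40_000, n_loci=10, expected_hits_per_chromosome=0.1,
        progeny_per_vial_mean=20.0, baseline_ndj2=0.01, mutant_ndj2=0.3, seed=12,
    )
    mutant = simulate_vial_selection(cfg, ndj2_rate=cfg.mutant_ndj2)
    lam = cfg.progeny_per_vial_mean * cfg.mutant_ndj2 / 2
    expected_kept = 1 - math.exp(-lam) - lam * math.exp(-lam)
    se = math.sqrt(expected_kept * (1 - expected_kept) / cfg.n_chromosomes)
    assert abs(mutant["kept"].mean() - expected_kept) < 3 * se

    baseline = simulate_vial_selection(cfg)  # defaults to baseline_ndj2
    assert baseline["kept"].mean() < mutant["kept"].mean()


def test_vial_selection_zero_rate_keeps_nothing():
    cfg = ScreenSimConfig(
        n_chromosomes=500, n_loci=10, expected_hits_per_chromosome=0.1, seed=3
    )
    df = simulate_vial_selection(cfg, ndj2_rate=0.0)
    assert df["n_progeny"].sum() == 0 and not df["kept"].any()
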