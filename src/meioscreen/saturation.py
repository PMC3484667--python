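"""Screen saturation under the classical Poisson model, and the lethal hit rate.

If every mutable locus receives hits independently at the same mean rate, the
number of alleles recovered per locus is Poisson with mean m, and the chance a
locus has been hit at least once — the saturation of the screen — is

    saturation% = 100 * (1 - exp(-m)),        m = alleles / loci.

m estimated as the plain mean is inflated by hypermutable loci, so two
refinements are provided: excluding suspect loci from the allele table, and a
zero-truncated Poisson class-ratio estimator using only the counts of loci
seen exactly once (n1) and exactly twice (n2).  Under truncated-Poisson
sampling P(2)/P(1) = m/2, giving m = 2 * n2 / n1 — usable without discarding
data, but unreliable when either class count is small.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SaturationEstimate",
    "HitRate",
    "saturation_pct_from_m",
    "estimate_saturation",
    "alleles_per_locus",
    "m_from_class_counts",
    "lethal_hit_rate",
]

ALLELE_COLUMNS = ("gene", "allele", "source")


@dataclass(frozen=True)
class SaturationEstimate:
    n_loci: int
    n_alleles: int
    m: float
    saturation_pct: float


@dataclass(frozen=True)
class HitRate:
    n_hit_vials: int
    n_vials: int
    rate_pct: float
    ci_low_pct: float
    ci_high_pct: float
    ci_level: float


def saturation_pct_from_m(m: float) -> float:
    if m < 0:
        raise ValueError(f"m must be nonnegative, got {m}")
    return 100.0 * (1.0 - math.exp(-m))


def _validate_allele_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALLELE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele table lacks required columns: {missing}")
    if table[["gene", "allele"]].duplicated().any():
        dupes = table[table[["gene", "allele"]].duplicated(keep=False)]
        raise ValueError(
            f"duplicate (gene, allele) records: {dupes[['gene', 'allele']].values.tolist()}"
        )
    if table["source"].isna().any() or (table["source"].astype(str).str.strip() == "").any():
        raise ValueError("every allele record needs a nonempty source")
    return table


def estimate_saturation(
    table: pd.DataFrame,
    exclude_genes: Iterable[str] = (),
    exclude_sources: Iterable[str] = (),
) -> SaturationEstimate:
    """Poisson saturation from an allele table (columns gene/allele/source).

    Loci counted are the distinct genes remaining after exclusions (observed
    loci only); m is total remaining alleles divided by that count.
    """
    table = _validate_allele_table(table)
    exclude_genes = set(exclude_genes)
    exclude_sources = set(exclude_sources)
    kept = table[
        ~table["gene"].isin(exclude_genes) & ~table["source"].isin(exclude_sources)
    ]
    n_loci = kept["gene"].nunique()
    n_alleles = len(kept)
    if n_loci == 0:
        raise ValueError("no loci remain after exclusions; saturation is undefined")
    m = n_alleles / n_loci
    return SaturationEstimate(
        n_loci=n_loci,
        n_alleles=n_alleles,
        m=m,
        saturation_pct=saturation_pct_from_m(m),
    )


def alleles_per_locus(table: pd.DataFrame) -> Counter:
    """Histogram of allele counts per locus: {k: number of loci with k alleles}."""
    table = _validate_allele_table(table)
    per_gene = table.groupby("gene", sort=False).size()
    return Counter(per_gene.values.tolist())


def m_from_class_counts(n_singleton_loci: int, n_doubleton_loci: int) -> float:
    """Zero-truncated Poisson class-ratio estimate of m from loci seen once/twice.

    Among observed loci P(k alleles) is truncated Poisson, so the doubleton to
    singleton ratio estimates m/2 and m = 2 * n2 / n1.  Emits a warning when
    either class has fewer than 5 loci, where the ratio is dominated by noise.
    """
    if n_singleton_loci < 0 or n_doubleton_loci < 0:
        raise ValueError("class counts must be nonnegative")
    if n_singleton_loci == 0:
        raise ZeroDivisionError(
            "no singleton loci: the class-ratio estimator of m is undefined"
        )
    if n_singleton_loci < 5 or n_doubleton_loci < 5:
        warnings.warn(
            f"class-ratio m estimate from small classes (n1={n_singleton_loci}, "
            f"n2={n_doubleton_loci}) is unreliable",
            stacklevel=2,
        )
    return 2.0 * n_doubleton_loci / n_singleton_loci


def lethal_hit_rate(
    n_hit_vials: int, n_vials: int, ci_level: float = 0.95
) -> HitRate:
    """Fraction of mutagenized chromosomes carrying a recessive lethal.

    Assayed as the fraction of single-chromosome test vials producing only
    balancer-marked males; the Wilson score interval is reported because it
    behaves at the small counts typical of these assays.
    """
    if n_vials < 1:
        raise ValueError(f"n_vials must be at least 1, got {n_vials}")
    if not 0 <= n_hit_vials <= n_vials:
        raise ValueError(
            f"n_hit_vials must be between 0 and n_vials={n_vials}, got {n_hit_vials}"
        )
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    low, high = proportion_confint(
        n_hit_vials, n_vials, alpha=1.0 - ci_level, method="wilson"
    )
    # the Wilson bounds are exactly 0/1 at the boundary counts; clear the
    # floating-point residue so callers can compare against them
    if n_hit_vials == 0:
        low = 0.0
    if n_hit_vials == n_vials:
        high = 1.0
    return HitRate(
        n_hit_vials=n_hit_vials,
        n_vials=n_vials,
        rate_pct=100.0 * n_hit_vials / n_vials,
        ci_low_pct=100.0 * float(low),
        ci_high_pct=100.0 * float(high),
        ci_level=ci_level,
    )
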