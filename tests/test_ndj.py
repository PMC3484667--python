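"""Viability-adjusted nondisjunction statistics against printed values, a
pseudo-observation oracle, and algebraic invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import meioscreen as ms
from meioscreen.ndj import ProgenyCountTable, UndefinedRateError, ValidationError

from conftest import PRINTED_DERIVED_BLOCK

count_lists = st.lists(st.integers(min_value=0, max_value=500), min_size=12, max_size=12)
nonzero_count_lists = count_lists.filter(lambda v: sum(v) > 0)


def table_from(values, genotype="t"):
    return ProgenyCountTable.from_row_order(genotype, values)


def pseudo_observation_summary(table):
    """Brute-force oracle: expand each progeny class into `weight` pseudo-ova
    and take simple proportions."""
    num = {"x": 0, "4": 0, "nullo_x": 0, "diplo_x": 0, "nullo_4": 0, "diplo_4": 0}
    total = 0
    for cls, n in table.counts.items():
        w = cls.weight * n
        total += w
        m = cls.maternal
        num["x"] += w * (m.x_dosage != 1)
        num["4"] += w * (m.four_dosage != 1)
        num["nullo_x"] += w * (m.x_dosage == 0)
        num["diplo_x"] += w * (m.x_dosage == 2)
        num["nullo_4"] += w * (m.four_dosage == 0)
        num["diplo_4"] += w * (m.four_dosage == 2)
    return total, {k: 100.0 * v / total for k, v in num.items()}


@pytest.mark.parametrize("genotype", sorted(PRINTED_DERIVED_BLOCK))
def test_derived_block_matches_published_values(count_tables, genotype):
    """Every adjusted total and percentage reproduces the published cell after
    display rounding (70 cells over the 10 genotypes)."""
    adjusted, px, p4, pnx, pdx, pn4, pd4 = PRINTED_DERIVED_BLOCK[genotype]
    s = ms.summarize(count_tables[genotype])
    assert s.adjusted_total == adjusted
    assert ms.format_pct(s.pct_x_ndj, decimals=1) == px
    assert ms.format_pct(s.pct_4_ndj, decimals=1) == p4
    assert ms.format_pct(s.pct_nullo_x) == pnx
    assert ms.format_pct(s.pct_diplo_x) == pdx
    assert ms.format_pct(s.pct_nullo_4) == pn4
    assert ms.format_pct(s.pct_diplo_4) == pd4


def test_control_column_exact_values(count_tables):
    s = ms.summarize(count_tables["y w"])
    assert s.raw_total == 817  # the printed 808 total is inconsistent with its own column
    assert s.adjusted_total == 820
    assert s.pct_x_ndj == pytest.approx(100 * 2 * 3 / 820)


def test_adjusted_total_without_exceptional_counts_equals_raw():
    t = table_from([100, 100] + [0] * 10)
    assert ms.adjusted_total(t) == t.raw_total == 200


def test_uniform_counts_hand_enumeration():
    # 12 classes of 1: adjusted = 6*1 + 2*6 = 18, X-exceptional pseudo-ova = 12
    t = table_from([1] * 12)
    assert ms.adjusted_total(t) == 18
    assert ms.pct_x_ndj(t) == pytest.approx(100 * 12 / 18)


def test_all_exceptional_table_gives_100_pct():
    values = [0, 0] + [1] * 2 + [0] * 4 + [1] * 4
    assert ms.pct_x_ndj(table_from(values)) == pytest.approx(100.0)


def test_zero_adjusted_total_is_an_error():
    t = table_from([0] * 12)
    for fn in (ms.pct_x_ndj, ms.pct_4_ndj, ms.gamete_class_pcts, ms.summarize):
        with pytest.raises(UndefinedRateError):
            fn(t)


@pytest.mark.parametrize(
    "values, error",
    [
        ([1] * 11, "expected 12 counts"),
        ([1] * 13, "expected 12 counts"),
        ([-1] + [1] * 11, "nonnegative"),
        ([1.5] + [1] * 11, "nonnegative"),
    ],
)
def test_invalid_tables_rejected(values, error):
    with pytest.raises(ValidationError, match=error):
        table_from(values)


def test_stated_total_mismatch_warns_and_uses_computed_sum():
    with pytest.warns(UserWarning, match="disagrees"):
        t = ProgenyCountTable.from_row_order("g", [10] * 12, stated_total=100)
    assert t.raw_total == 120


@given(nonzero_count_lists)
def test_partition_identities(values):
    """%nullo + %diplo equals the corresponding ND percentage for both
    chromosomes, on arbitrary tables."""
    t = table_from(values)
    nullo_x, diplo_x, nullo_4, diplo_4 = ms.gamete_class_pcts(t)
    assert nullo_x + diplo_x == pytest.approx(ms.pct_x_ndj(t), abs=1e-9)
    assert nullo_4 + diplo_4 == pytest.approx(ms.pct_4_ndj(t), abs=1e-9)


@given(nonzero_count_lists, st.integers(min_value=1, max_value=9))
def test_scale_invariance(values, k):
    t1, tk = table_from(values), table_from([k * v for v in values])
    assert ms.adjusted_total(tk) == k * ms.adjusted_total(t1)
    assert ms.pct_x_ndj(tk) == pytest.approx(ms.pct_x_ndj(t1))
    assert ms.gamete_class_pcts(tk) == pytest.approx(ms.gamete_class_pcts(t1))


@given(nonzero_count_lists)
def test_pseudo_observation_oracle_equivalence(values):
    """The closed-form statistics agree with expanding each class into
    `weight` pseudo-observations and taking simple proportions."""
    t = table_from(values)
    total, pcts = pseudo_observation_summary(t)
    s = ms.summarize(t)
    assert s.adjusted_total == total
    assert s.pct_x_ndj == pytest.approx(pcts["x"], rel=1e-12)
    assert s.pct_4_ndj == pytest.approx(pcts["4"], rel=1e-12)
    assert s.pct_nullo_x == pytest.approx(pcts["nullo_x"], rel=1e-12)
    assert s.pct_diplo_4 == pytest.approx(pcts["diplo_4"], rel=1e-12)


def test_pooling_sums_counts_class_by_class(count_tables):
    pooled = ms.pool_tables(count_tables.values())
    assert pooled.raw_total == sum(t.raw_total for t in count_tables.values())
    assert ms.adjusted_total(pooled) == sum(
        ms.adjusted_total(t) for t in count_tables.values()
    )


@pytest.mark.parametrize(
    "value, decimals, expected",
    [
        (0.7317, 1, "0.7"),
        (0.2439, None, "0.24"),
        (31.9569, None, "32.0"),
        (15.625, None, "15.6"),
        (0.245, None, "0.25"),  # ties round half away from zero
        (2.35, 1, "2.4"),
    ],
)
def test_display_rounding(value, decimals, expected):
    assert ms.format_pct(value, decimals) == expected
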