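"""Viability-adjusted X and 4th chromosome nondisjunction statistics.

Under the X^Y; C(4)RM tester, an X-exceptional (nullo-X or diplo-X) ovum
produces a viable zygote with only one of the two sperm sex classes, so each
scored X-exceptional individual represents two ova.  The *adjusted total*
therefore counts X-exceptional classes twice:

    adjusted = sum(normal-X counts) + 2 * sum(X-exceptional counts)

and the frequencies reported per female genotype are

    %X ND  = 100 * 2 * sum(X-exceptional counts) / adjusted
    %4 ND  = 100 * (sum(4-exc, X-normal) + 2 * sum(4-exc, X-exc)) / adjusted

with nullo/diplo breakdowns defined the same way restricted to dosage 0 or 2.
All internal values are exact; display rounding (one decimal, two below 1%)
is applied only when formatting.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence
import warnings

from .cross_model import CrossDesign, ProgenyClass, xy_c4rm_tester

__all__ = [
    "ValidationError",
    "UndefinedRateError",
    "ProgenyCountTable",
    "NdjSummary",
    "adjusted_total",
    "pct_x_ndj",
    "pct_4_ndj",
    "gamete_class_pcts",
    "summarize",
    "pool_tables",
    "round_display",
    "format_pct",
]


class ValidationError(ValueError):
    """Raised for a structurally invalid progeny-count table."""


class UndefinedRateError(ZeroDivisionError):
    """Raised when a rate is requested from a table with adjusted total zero."""


@dataclass(frozen=True)
class ProgenyCountTable:
    """Scored progeny counts for one female genotype over the 12 tester classes.

    ``counts`` maps every admissible :class:`ProgenyClass` of ``design`` to a
    nonnegative integer; all 12 keys must be present (zeros allowed).
    """

    genotype: str
    counts: Mapping[ProgenyClass, int]
    design: CrossDesign = None  # type: ignore[assignment]
    n_females: int | None = None

    def __post_init__(self) -> None:
        if self.design is None:
            object.__setattr__(self, "design", xy_c4rm_tester())
        expected = set(self.design.admissible_classes)
        got = set(self.counts)
        if got != expected:
            missing = sorted(c.label for c in expected - got)
            extra = sorted(getattr(c, "label", str(c)) for c in got - expected)
            parts = []
            if missing:
                parts.append(f"missing classes: {missing}")
            if extra:
                parts.append(f"unexpected classes: {extra}")
            raise ValidationError(
                f"counts for genotype {self.genotype!r} must cover exactly the "
                f"{len(expected)} admissible classes; " + "; ".join(parts)
            )
        for cls, n in self.counts.items():
            if not isinstance(n, numbers.Integral) or isinstance(n, bool) or n < 0:
                raise ValidationError(
                    f"count for class {cls.label!r} must be a nonnegative integer, got {n!r}"
                )
        if self.n_females is not None and self.n_females <= 0:
            raise ValidationError(f"n_females must be positive, got {self.n_females}")

    @classmethod
    def from_row_order(
        cls,
        genotype: str,
        values: Sequence[int],
        design: CrossDesign | None = None,
        n_females: int | None = None,
        stated_total: int | None = None,
    ) -> "ProgenyCountTable":
        """Build a table from counts listed in the design's canonical row order.

        If a ``stated_total`` (e.g. a printed "Total progeny" figure) disagrees
        with the sum of the counts, a warning is emitted and the computed sum
        is used.
        """
        if design is None:
            design = xy_c4rm_tester()
        classes = design.admissible_classes
        if len(values) != len(classes):
            raise ValidationError(
                f"expected {len(classes)} counts for genotype {genotype!r}, got {len(values)}"
            )
        table = cls(
            genotype=genotype,
            counts=dict(zip(classes, values)),
            design=design,
            n_females=n_females,
        )
        if stated_total is not None and stated_total != table.raw_total:
            warnings.warn(
                f"genotype {genotype!r}: stated total {stated_total} disagrees with "
                f"the sum of class counts {table.raw_total}; using the computed sum",
                stacklevel=2,
            )
        return table

    @property
    def raw_total(self) -> int:
        return sum(self.counts.values())

    def row_order_counts(self) -> list[int]:
        return [self.counts[c] for c in self.design.admissible_classes]


@dataclass(frozen=True)
class NdjSummary:
    """Adjusted total and the six derived nondisjunction percentages (unrounded)."""

    genotype: str
    raw_total: int
    adjusted_total: int
    pct_x_ndj: float
    pct_4_ndj: float
    pct_nullo_x: float
    pct_diplo_x: float
    pct_nullo_4: float
    pct_diplo_4: float

    def as_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "raw_total": self.raw_total,
            "adjusted_total": self.adjusted_total,
            "pct_x_ndj": self.pct_x_ndj,
            "pct_4_ndj": self.pct_4_ndj,
            "pct_nullo_x": self.pct_nullo_x,
            "pct_diplo_x": self.pct_diplo_x,
            "pct_nullo_4": self.pct_nullo_4,
            "pct_diplo_4": self.pct_diplo_4,
        }


def adjusted_total(table: ProgenyCountTable) -> int:
    """Viability-adjusted progeny total: X-exceptional classes count double."""
    return sum(cls.weight * n for cls, n in table.counts.items())


def _weighted_sum(table: ProgenyCountTable, predicate) -> int:
    return sum(
        cls.weight * n for cls, n in table.counts.items() if predicate(cls.maternal)
    )


def _require_adjusted(table: ProgenyCountTable) -> int:
    adj = adjusted_total(table)
    if adj == 0:
        raise UndefinedRateError(
            f"genotype {table.genotype!r}: adjusted total is zero; rates are undefined"
        )
    return adj


def pct_x_ndj(table: ProgenyCountTable) -> float:
    """Percent X nondisjunction among ova, viability-adjusted."""
    adj = _require_adjusted(table)
    return 100.0 * _weighted_sum(table, lambda m: m.is_x_exceptional) / adj


def pct_4_ndj(table: ProgenyCountTable) -> float:
    """Percent 4th chromosome nondisjunction among ova, viability-adjusted."""
    adj = _require_adjusted(table)
    return 100.0 * _weighted_sum(table, lambda m: m.is_four_exceptional) / adj


def gamete_class_pcts(table: ProgenyCountTable) -> tuple[float, float, float, float]:
    """(%nullo-X, %diplo-X, %nullo-4, %diplo-4), viability-adjusted."""
    adj = _require_adjusted(table)
    return (
        100.0 * _weighted_sum(table, lambda m: m.x_dosage == 0) / adj,
        100.0 * _weighted_sum(table, lambda m: m.x_dosage == 2) / adj,
        100.0 * _weighted_sum(table, lambda m: m.four_dosage == 0) / adj,
        100.0 * _weighted_sum(table, lambda m: m.four_dosage == 2) / adj,
    )


def summarize(table: ProgenyCountTable) -> NdjSummary:
    """All derived nondisjunction statistics for one genotype."""
    nullo_x, diplo_x, nullo_4, diplo_4 = gamete_class_pcts(table)
    return NdjSummary(
        genotype=table.genotype,
        raw_total=table.raw_total,
        adjusted_total=adjusted_total(table),
        pct_x_ndj=pct_x_ndj(table),
        pct_4_ndj=pct_4_ndj(table),
        pct_nullo_x=nullo_x,
        pct_diplo_x=diplo_x,
        pct_nullo_4=nullo_4,
        pct_diplo_4=diplo_4,
    )


def pool_tables(
    tables: Iterable[ProgenyCountTable], genotype: str = "pooled"
) -> ProgenyCountTable:
    """Sum several count tables class-by-class into a single pooled table."""
    tables = list(tables)
    if not tables:
        raise ValidationError("cannot pool an empty collection of tables")
    design = tables[0].design
    pooled = {cls: 0 for cls in design.admissible_classes}
    for t in tables:
        if t.design is not design and t.design.name != design.name:
            raise ValidationError("cannot pool tables from different cross designs")
        for cls, n in t.counts.items():
            pooled[cls] += n
    return ProgenyCountTable(genotype=genotype, counts=pooled, design=design)


def _display_decimals(value: float, decimals: int | None) -> int:
    if decimals is not None:
        return decimals
    return 2 if abs(value) < 1 else 1


def round_display(value: float, decimals: int | None = None) -> float:
    """Display rounding, half away from zero.

    By default 1 decimal place, or 2 when |value| < 1 — the convention of the
    nullo/diplo breakdown rows of a nondisjunction table, where control-level
    frequencies would otherwise vanish.  The headline %X ND and %4 ND rows are
    conventionally printed at a fixed 1 decimal (pass ``decimals=1``).
    """
    d = _display_decimals(value, decimals)
    q = Decimal(1).scaleb(-d)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(value: float, decimals: int | None = None) -> str:
    """Format a percentage the way nondisjunction tables print it."""
    d = _display_decimals(value, decimals)
    return f"{round_display(value, d):.{d}f}"
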