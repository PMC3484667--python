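"""Readers, writers, run configuration and packaged reference fixtures.

File conventions: tab-separated UTF-8 with a header line; ``#`` lines are
comments.  Validation errors carry 1-based line numbers.  Three fixtures ship
with the package: ``table1.tsv`` (the control + 9 mutant count columns of the
nondisjunction assay), ``table3_alleles.tsv`` (the 33 X-chromosome meiotic
alleles from the four unbiased screens) and
``complementation_edges_synthetic.tsv`` (a synthetic reconstruction of the
pairwise complementation tests; see its header comment).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import IO, Sequence

import pandas as pd
import yaml

from .complementation import DEFAULT_FAIL_THRESHOLD, DEFAULT_MIN_N, ComplementationTest
from .cross_model import (
    CrossDesign,
    GameteLabelError,
    parse_maternal_label,
    parse_paternal_label,
    xy_c4rm_tester,
)
from .ndj import NdjSummary, ProgenyCountTable, ValidationError, format_pct
from .saturation import ALLELE_COLUMNS, _validate_allele_table

__all__ = [
    "RunConfig",
    "read_counts",
    "write_report",
    "read_summaries_json",
    "read_alleles",
    "read_complementation_tests",
    "load_table1_counts",
    "load_allele_table",
    "load_complementation_tests",
]

logger = logging.getLogger("meioscreen")

_COUNT_HEADER = ["genotype", "maternal", "paternal", "count"]
_TEST_HEADER = ["allele_a", "allele_b", "x_ndj_pct", "n_progeny"]

REPORT_ROWS = (
    ("raw_total", "Total progeny"),
    ("adjusted_total", "Adjusted total"),
    ("pct_x_ndj", "% X nondisjunction"),
    ("pct_4_ndj", "% 4 nondisjunction"),
    ("pct_nullo_x", "% nullo-X"),
    ("pct_diplo_x", "% diplo-X"),
    ("pct_nullo_4", "% nullo-4"),
    ("pct_diplo_4", "% diplo-4"),
)


@dataclass
class RunConfig:
    """Validated run options shared by the command-line tools."""

    fail_threshold: float = DEFAULT_FAIL_THRESHOLD
    min_n: int = DEFAULT_MIN_N
    ci_level: float = 0.95
    seed: int | None = None
    strict: bool = True
    output_format: str = "tsv"

    def __post_init__(self) -> None:
        if self.fail_threshold < 0:
            raise ValueError("fail_threshold must be nonnegative")
        if self.min_n < 0:
            raise ValueError("min_n must be nonnegative")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.output_format not in ("tsv", "json", "md"):
            raise ValueError(f"unknown output format {self.output_format!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        loaded.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**loaded)


def _iter_tsv(path: str | Path, expected_header: Sequence[str]):
    """Yield (line_number, row_dict) from a commented TSV, checking the header."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            cells = [c.strip() for c in row]
            if header is None:
                header = cells
                if header != list(expected_header):
                    raise ValidationError(
                        f"{path}:{lineno}: expected header {list(expected_header)}, got {header}"
                    )
                continue
            if len(cells) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            yield lineno, dict(zip(header, cells))
        if header is None:
            raise ValidationError(f"{path}: empty file (no header found)")


def read_counts(
    path: str | Path,
    strict: bool = True,
    design: CrossDesign | None = None,
) -> list[ProgenyCountTable]:
    """Read long-format progeny counts into one table per genotype.

    Each record is (genotype, maternal label, paternal label, count).  Strict
    mode requires all admissible classes per genotype; lenient mode zero-fills
    the missing ones.  Genotypes keep file order.
    """
    if design is None:
        design = xy_c4rm_tester()
    by_pair = {(c.maternal, c.paternal): c for c in design.admissible_classes}
    tables: dict[str, dict] = {}
    n_records = 0
    for lineno, row in _iter_tsv(path, _COUNT_HEADER):
        try:
            maternal = parse_maternal_label(row["maternal"])
            paternal = parse_paternal_label(row["paternal"])
        except GameteLabelError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        cls = by_pair.get((maternal, paternal))
        if cls is None:
            raise ValidationError(
                f"{path}:{lineno}: class {maternal.label} x {paternal.label} is not "
                f"admissible under design {design.name!r}"
            )
        try:
            count = int(row["count"])
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: count must be an integer, got {row['count']!r}"
            ) from None
        if count < 0:
            raise ValidationError(f"{path}:{lineno}: negative count {count}")
        genotype = row["genotype"]
        counts = tables.setdefault(genotype, {})
        if cls in counts:
            raise ValidationError(
                f"{path}:{lineno}: duplicate class {cls.label!r} for genotype {genotype!r}"
            )
        counts[cls] = count
        n_records += 1

    out = []
    for genotype, counts in tables.items():
        if strict:
            missing = [c.label for c in design.admissible_classes if c not in counts]
            if missing:
                raise ValidationError(
                    f"{path}: genotype {genotype!r} is missing classes {missing} "
                    f"(use lenient mode to zero-fill)"
                )
        else:
            for c in design.admissible_classes:
                counts.setdefault(c, 0)
        out.append(ProgenyCountTable(genotype=genotype, counts=counts, design=design))
    logger.info(
        "read_counts: %s -> %d records, %d genotypes", path, n_records, len(out)
    )
    return out


def _summaries_frame(summaries: Sequence[NdjSummary], rounded: bool) -> pd.DataFrame:
    data = {}
    for s in summaries:
        col = {}
        for key, label in REPORT_ROWS:
            value = getattr(s, key)
            if rounded and key.startswith("pct_"):
                # the headline ND rows print at a fixed 1 decimal; the
                # nullo/diplo rows gain a second decimal below 1%
                decimals = 1 if key in ("pct_x_ndj", "pct_4_ndj") else None
                value = format_pct(value, decimals)
            col[label] = value
        data[s.genotype] = col
    return pd.DataFrame(data, columns=[s.genotype for s in summaries])


def _markdown_table(frame: pd.DataFrame) -> str:
    header = [""] + [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for idx, row in frame.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
    return "\n".join(lines) + "\n"


def write_report(
    summaries: Sequence[NdjSummary],
    out: IO[str] | str | Path,
    output_format: str = "tsv",
) -> None:
    """Write the derived nondisjunction block for one or more genotypes.

    ``tsv`` and ``md`` apply display rounding; ``json`` carries the exact
    unrounded values (round-trippable via :func:`read_summaries_json`).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no summaries to report")
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w", encoding="utf-8")
        close = True
    else:
        fh = out
    try:
        if output_format == "json":
            json.dump([s.as_dict() for s in summaries], fh, indent=2)
            fh.write("\n")
        elif output_format == "tsv":
            frame = _summaries_frame(summaries, rounded=True)
            frame.to_csv(fh, sep="\t", index_label="statistic")
        elif output_format == "md":
            fh.write(_markdown_table(_summaries_frame(summaries, rounded=True)))
        else:
            raise ValidationError(f"unknown output format {output_format!r}")
    finally:
        if close:
            fh.close()
    logger.info("write_report: %d genotype(s), format=%s", len(summaries), output_format)


def read_summaries_json(path: str | Path) -> list[NdjSummary]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [NdjSummary(**entry) for entry in payload]


def read_alleles(path: str | Path) -> pd.DataFrame:
    """Read a gene/allele/source table for saturation analysis."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(frame.columns) != list(ALLELE_COLUMNS):
        raise ValidationError(
            f"{path}: expected header {list(ALLELE_COLUMNS)}, got {list(frame.columns)}"
        )
    try:
        _validate_allele_table(frame)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    logger.info("read_alleles: %s -> %d records", path, len(frame))
    return frame


def read_complementation_tests(path: str | Path) -> list[ComplementationTest]:
    """Read pairwise transheterozygote tests (allele_a/allele_b/x_ndj_pct/n_progeny)."""
    tests = []
    for lineno, row in _iter_tsv(path, _TEST_HEADER):
        try:
            tests.append(
                ComplementationTest(
                    allele_a=row["allele_a"],
                    allele_b=row["allele_b"],
                    x_ndj_pct=float(row["x_ndj_pct"]),
                    n_progeny=int(row["n_progeny"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read_complementation_tests: %s -> %d tests", path, len(tests))
    return tests


def _fixture_path(name: str):
    return resources.files("meioscreen.data").joinpath(name)


def load_table1_counts() -> list[ProgenyCountTable]:
    """The packaged control + 9 mutant nondisjunction count tables."""
    with resources.as_file(_fixture_path("table1.tsv")) as p:
        return read_counts(p)


def load_allele_table() -> pd.DataFrame:
    """The packaged 33-record X-chromosome meiotic allele table."""
    with resources.as_file(_fixture_path("table3_alleles.tsv")) as p:
        return read_alleles(p)


def load_complementation_tests() -> list[ComplementationTest]:
    """The packaged synthetic reconstruction of the pairwise tests."""
    with resources.as_file(_fixture_path("complementation_edges_synthetic.tsv")) as p:
        return read_complementation_tests(p)
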