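"""Gamete classes, progeny classes and viability rules of the X^Y; C(4)RM tester cross.

Females to be assayed for *X* and 4th chromosome nondisjunction are crossed to
``X^Y, In(1)EN, v f B; C(4)RM, ci ey^R`` males.  The male produces essentially
two sperm sex classes (``XY`` carrying the attached X^Y, and nullo-sex ``0``)
and two sperm 4th-chromosome classes (the compound ``C(4)RM``, written ``44``,
and nullo-4 ``0``).  An ovum is characterised by its X dosage (0, 1 or 2 —
nullo, normal, diplo) and its 4th-chromosome dosage (likewise).  Only some
ovum x sperm combinations yield viable, scorable adults:

* a normal-X ovum survives with either sperm sex class, whereas a nullo-X ovum
  requires the ``XY`` sperm and a diplo-X ovum requires the nullo-sex sperm —
  the reciprocal zygotes (e.g. nullo-X egg x nullo-sex sperm) die.  Hence an
  X-exceptional ovum class is recovered in only one of the two sperm sex
  classes, i.e. at half the rate of a normal ovum, which is why X-exceptional
  progeny classes carry a counting weight of 2.
* a nullo-4 or normal-4 ovum requires the compound-4 sperm, and a diplo-4 ovum
  the nullo-4 sperm.  Every ovum class loses exactly one of the two sperm
  4-classes, so this halving is uniform and cancels out of all frequencies; 4th
  chromosome exceptional classes therefore carry no extra weight.

Applying the two rules to all 9 x 4 ovum x sperm combinations leaves exactly
12 admissible progeny classes, which are the rows of a standard nondisjunction
count table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Union

__all__ = [
    "GameteLabelError",
    "MaternalGameteClass",
    "PaternalGameteClass",
    "ProgenyClass",
    "CrossDesign",
    "parse_maternal_label",
    "parse_paternal_label",
    "parse_gamete_label",
    "admissible_progeny_classes",
    "xy_c4rm_tester",
    "get_design",
    "DESIGNS",
]


class GameteLabelError(ValueError):
    """Raised for an unknown token or malformed gamete-class label."""


_X_TOKEN = {0: "0", 1: "X", 2: "XX"}
_X_DOSAGE = {v: k for k, v in _X_TOKEN.items()}
_FOUR_TOKEN = {0: "0", 1: "4", 2: "44"}
_FOUR_DOSAGE = {v: k for k, v in _FOUR_TOKEN.items()}

_SPERM_SEX = ("XY", "nullo")
_SPERM_FOUR = ("C4", "nullo")
_SPERM_SEX_TOKEN = {"XY": "XY", "nullo": "0"}
_SPERM_FOUR_TOKEN = {"C4": "44", "nullo": "0"}


@dataclass(frozen=True, order=True)
class MaternalGameteClass:
    """An ovum class: X and 4th chromosome dosage, each 0 (nullo), 1, or 2 (diplo)."""

    x_dosage: int
    four_dosage: int

    def __post_init__(self) -> None:
        if self.x_dosage not in (0, 1, 2):
            raise ValueError(f"x_dosage must be 0, 1 or 2, got {self.x_dosage!r}")
        if self.four_dosage not in (0, 1, 2):
            raise ValueError(f"four_dosage must be 0, 1 or 2, got {self.four_dosage!r}")

    @property
    def label(self) -> str:
        return f"{_X_TOKEN[self.x_dosage]};{_FOUR_TOKEN[self.four_dosage]}"

    @property
    def is_x_exceptional(self) -> bool:
        return self.x_dosage != 1

    @property
    def is_four_exceptional(self) -> bool:
        return self.four_dosage != 1

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True, order=True)
class PaternalGameteClass:
    """A sperm class of the X^Y male: sex class XY/nullo, 4th class C(4)RM/nullo."""

    sex_class: str
    four_class: str

    def __post_init__(self) -> None:
        if self.sex_class not in _SPERM_SEX:
            raise ValueError(f"sex_class must be 'XY' or 'nullo', got {self.sex_class!r}")
        if self.four_class not in _SPERM_FOUR:
            raise ValueError(f"four_class must be 'C4' or 'nullo', got {self.four_class!r}")

    @property
    def label(self) -> str:
        return f"{_SPERM_SEX_TOKEN[self.sex_class]};{_SPERM_FOUR_TOKEN[self.four_class]}"

    def __str__(self) -> str:
        return self.label


GameteClass = Union[MaternalGameteClass, PaternalGameteClass]

ALL_MATERNAL_CLASSES: tuple[MaternalGameteClass, ...] = tuple(
    MaternalGameteClass(x, f) for x, f in itertools.product((0, 1, 2), repeat=2)
)
ALL_PATERNAL_CLASSES: tuple[PaternalGameteClass, ...] = tuple(
    PaternalGameteClass(s, f) for s, f in itertools.product(_SPERM_SEX, _SPERM_FOUR)
)

_MATERNAL_BY_LABEL = {c.label: c for c in ALL_MATERNAL_CLASSES}
_PATERNAL_BY_LABEL = {c.label: c for c in ALL_PATERNAL_CLASSES}


def _normalize_label(label: str) -> str:
    if not isinstance(label, str):
        raise GameteLabelError(f"gamete label must be a string, got {type(label).__name__}")
    parts = label.upper().split(";")
    if len(parts) != 2:
        raise GameteLabelError(
            f"malformed gamete label {label!r}: expected two ';'-separated tokens"
        )
    return ";".join(p.strip().replace(" ", "") for p in parts)


def parse_maternal_label(label: str) -> MaternalGameteClass:
    """Parse an ovum-class label such as ``"XX;44"`` (case/whitespace tolerant)."""
    norm = _normalize_label(label)
    x_tok, four_tok = norm.split(";")
    if x_tok not in _X_DOSAGE:
        raise GameteLabelError(f"unknown maternal sex-chromosome token {x_tok!r} in {label!r}")
    if four_tok not in _FOUR_DOSAGE:
        raise GameteLabelError(f"unknown maternal 4th-chromosome token {four_tok!r} in {label!r}")
    return _MATERNAL_BY_LABEL[norm]


def parse_paternal_label(label: str) -> PaternalGameteClass:
    """Parse a sperm-class label such as ``"XY;0"`` (case/whitespace tolerant)."""
    norm = _normalize_label(label)
    sex_tok, four_tok = norm.split(";")
    if sex_tok not in ("XY", "0"):
        raise GameteLabelError(f"unknown paternal sex-class token {sex_tok!r} in {label!r}")
    if four_tok not in ("44", "0"):
        raise GameteLabelError(f"unknown paternal 4th-class token {four_tok!r} in {label!r}")
    return _PATERNAL_BY_LABEL[norm]


def parse_gamete_label(label: str, role: str | None = None) -> GameteClass:
    """Parse a gamete-class label as maternal or paternal.

    ``role`` may be ``"maternal"`` or ``"paternal"``; if omitted the role is
    inferred, but the labels ``"0;0"`` and ``"0;44"`` are valid for both ovum
    and sperm classes and then raise a :class:`GameteLabelError` asking for an
    explicit role.
    """
    if role == "maternal":
        return parse_maternal_label(label)
    if role == "paternal":
        return parse_paternal_label(label)
    if role is not None:
        raise ValueError(f"role must be 'maternal' or 'paternal', got {role!r}")
    results: list[GameteClass] = []
    for parser in (parse_maternal_label, parse_paternal_label):
        try:
            results.append(parser(label))
        except GameteLabelError:
            pass
    if not results:
        raise GameteLabelError(f"unknown gamete label {label!r}")
    if len(results) > 1:
        raise GameteLabelError(
            f"gamete label {label!r} is valid as both a maternal and a paternal class; "
            "pass role='maternal' or role='paternal'"
        )
    return results[0]


@dataclass(frozen=True, order=True)
class ProgenyClass:
    """One admissible (ovum class, sperm class) pairing, with its counting weight.

    The weight is 2 for maternal X-exceptional classes — only one of the two
    sperm sex classes yields a viable zygote, so each scored individual stands
    for two ova relative to the normal classes — and 1 otherwise.
    """

    maternal: MaternalGameteClass
    paternal: PaternalGameteClass

    @property
    def weight(self) -> int:
        return 2 if self.maternal.is_x_exceptional else 1

    @property
    def label(self) -> str:
        return f"{self.maternal.label} x {self.paternal.label}"

    def __str__(self) -> str:
        return self.label


def _tester_admissible(maternal: MaternalGameteClass, paternal: PaternalGameteClass) -> bool:
    # Sex-chromosome balance: nullo-X egg needs the XY sperm, diplo-X the nullo
    # sperm; a normal egg survives either.
    if maternal.x_dosage == 0 and paternal.sex_class != "XY":
        return False
    if maternal.x_dosage == 2 and paternal.sex_class != "nullo":
        return False
    # 4th chromosome: nullo-4 and normal eggs need the compound-4 sperm,
    # diplo-4 eggs the nullo-4 sperm.
    if maternal.four_dosage in (0, 1) and paternal.four_class != "C4":
        return False
    if maternal.four_dosage == 2 and paternal.four_class != "nullo":
        return False
    return True


# The 12 admissible classes in canonical count-table row order: the two normal
# rows, X nondisjunction, 4 nondisjunction, then simultaneous X;4 events.
_TESTER_ROW_LABELS: tuple[tuple[str, str], ...] = (
    ("X;4", "XY;44"),
    ("X;4", "0;44"),
    ("0;4", "XY;44"),
    ("XX;4", "0;44"),
    ("X;0", "XY;44"),
    ("X;0", "0;44"),
    ("X;44", "XY;0"),
    ("X;44", "0;0"),
    ("0;0", "XY;44"),
    ("XX;44", "0;0"),
    ("0;44", "XY;0"),
    ("XX;0", "0;44"),
)


@dataclass(frozen=True)
class CrossDesign:
    """A tester cross: ordered admissible progeny classes plus sperm frequencies.

    ``sperm_frequencies`` are used only by the simulator; estimation never
    needs them because the viability weights already absorb sperm recovery.
    """

    name: str
    admissible_classes: tuple[ProgenyClass, ...]
    sperm_frequencies: Mapping[PaternalGameteClass, float] = field(
        default_factory=lambda: {c: 0.25 for c in ALL_PATERNAL_CLASSES}
    )

    def __post_init__(self) -> None:
        total = sum(self.sperm_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sperm_frequencies must sum to 1, got {total}")
        if any(p < 0 for p in self.sperm_frequencies.values()):
            raise ValueError("sperm_frequencies must be nonnegative")
        from_rule = {
            (m, p)
            for m in ALL_MATERNAL_CLASSES
            for p in ALL_PATERNAL_CLASSES
            if self.is_admissible(m, p)
        }
        listed = {(c.maternal, c.paternal) for c in self.admissible_classes}
        if from_rule != listed:
            raise ValueError(
                f"design {self.name!r}: admissible_classes disagree with the "
                f"admissibility rule"
            )

    def is_admissible(
        self, maternal: MaternalGameteClass, paternal: PaternalGameteClass
    ) -> bool:
        return _tester_admissible(maternal, paternal)

    @property
    def class_index(self) -> Mapping[tuple[str, str], int]:
        return {
            (c.maternal.label, c.paternal.label): i
            for i, c in enumerate(self.admissible_classes)
        }


def xy_c4rm_tester() -> CrossDesign:
    """The X^Y, In(1)EN; C(4)RM tester design (12 admissible classes)."""
    return _TESTER


_TESTER = CrossDesign(
    name="xy_c4rm_tester",
    admissible_classes=tuple(
        ProgenyClass(_MATERNAL_BY_LABEL[m], _PATERNAL_BY_LABEL[p])
        for m, p in _TESTER_ROW_LABELS
    ),
)

DESIGNS: dict[str, CrossDesign] = {_TESTER.name: _TESTER}


def get_design(name: str) -> CrossDesign:
    try:
        return DESIGNS[name]
    except KeyError:
        raise KeyError(
            f"unknown cross design {name!r}; available: {sorted(DESIGNS)}"
        ) from None


def admissible_progeny_classes(design: CrossDesign | None = None) -> tuple[ProgenyClass, ...]:
    """The ordered admissible progeny classes of ``design`` (default: tester)."""
    if design is None:
        design = _TESTER
    return design.admissible_classes
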