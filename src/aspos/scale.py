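"""The ASPOS instrument: item definitions, scoring and severity grouping.

ASPOS (Adam's Scale of Posterior Stroke) is a seven-item ordinal
instrument for grading the severity of posterior-circulation ischaemic
stroke.  Five items (Reactivity, Eyes, Pharynx, Strength, Balance) are
scored 0-3 and two (Ataxia, Sensory) are scored 0-2, so the maximum
attainable total is 19.  Items that deliberately mirror NIHSS content
carry an ``nihss_like`` flag.

Scoring conventions implemented here:

* when several level descriptions apply, the highest applicable level is
  recorded (:func:`score_item`);
* an item that cannot be examined for reasons other than the stroke is
  marked not-assessable and simply omitted from the total -- the total is
  never pro-rated to compensate (:func:`total_score`);
* totals map onto three severity strata used in the threshold analysis:
  LOW (0-2), INTERMEDIATE (3) and HIGH (>= 4) (:func:`severity_group`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import DegenerateAssessmentError, InvalidInputError

__all__ = [
    "ItemLevel",
    "ItemDefinition",
    "ScaleDefinition",
    "ItemResponse",
    "Assessment",
    "SeverityGroup",
    "NOT_ASSESSABLE",
    "TIMEPOINTS",
    "DAY1_SLOTS",
    "RETEST_SLOT",
    "build_default_scale",
    "score_item",
    "total_score",
    "severity_group",
    "scale_to_csv",
    "scale_from_csv",
]

#: Marker used in text files for an item that could not be examined.
NOT_ASSESSABLE = "NA"

DAY1_SLOTS = ("day1_r1", "day1_r2", "day1_r3")
RETEST_SLOT = "day1_retest"
TIMEPOINTS = DAY1_SLOTS + (RETEST_SLOT,)


@dataclass(frozen=True)
class ItemLevel:
    """One scored level of an item: an integer code and its clinical label."""

    code: int
    label: str


@dataclass(frozen=True)
class ItemDefinition:
    """A single scale item: ordered levels plus the NIHSS-similarity flag."""

    name: str
    levels: tuple[ItemLevel, ...]
    nihss_like: bool = False

    def __post_init__(self) -> None:
        codes = [lv.code for lv in self.levels]
        if codes != list(range(len(codes))):
            raise InvalidInputError(
                f"item {self.name!r}: level codes must be consecutive "
                f"integers starting at 0, got {codes}"
            )

    @property
    def max_code(self) -> int:
        return self.levels[-1].code

    @property
    def valid_codes(self) -> range:
        return range(self.max_code + 1)


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered collection of items forming one instrument."""

    items: tuple[ItemDefinition, ...]

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"duplicate item names: {names}")

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)

    @property
    def max_total(self) -> int:
        return sum(it.max_code for it in self.items)

    def item(self, name: str) -> ItemDefinition:
        for it in self.items:
            if it.name == name:
                return it
        raise InvalidInputError(f"unknown item {name!r}; expected one of {self.item_names}")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ItemResponse:
    """One rater's score on one item; ``score=None`` means not assessable."""

    item: str
    score: Optional[int]

    @property
    def assessable(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class Assessment:
    """One rater's complete item-level scoring of one patient at one timepoint."""

    patient_id: str
    rater_id: str
    timepoint: str
    responses: tuple[ItemResponse, ...]

    def validate(self, scale: ScaleDefinition) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise InvalidInputError(
                f"timepoint {self.timepoint!r} not in {TIMEPOINTS}"
            )
        seen = [r.item for r in self.responses]
        if sorted(seen) != sorted(scale.item_names):
            raise InvalidInputError(
                f"assessment for {self.patient_id!r} must contain each of "
                f"{scale.item_names} exactly once, got {seen}"
            )
        for r in self.responses:
            if r.score is not None and r.score not in scale.item(r.item).valid_codes:
                raise InvalidInputError(
                    f"score {r.score} out of range 0-"
                    f"{scale.item(r.item).max_code} for item {r.item!r}"
                )


class SeverityGroup(str, Enum):
    """Severity strata of the total score used in the threshold analysis."""

    LOW = "LOW"  # total 0-2
    INTERMEDIATE = "INTERMEDIATE"  # total 3
    HIGH = "HIGH"  # total >= 4


# Level labels transcribed from the published instrument.
_DEFAULT_ITEMS: tuple[tuple[str, bool, tuple[str, ...]], ...] = (
    (
        "Reactivity",
        True,
        ("conscious", "somnolence, confusion", "sopor", "coma"),
    ),
    (
        "Eyes",
        True,
        (
            "normal eye movement and visual fields",
            "nystagmus, double vision, hemianopia",
            "eye movement disturbances",
            "oftalmoplegia, cortical blindness",
        ),
    ),
    (
        "Pharynx",
        False,
        (
            "normal swallowing, no dysarthria",
            "mild dysarthria",
            "moderate dysarthria, choking on liquids",
            "anarthria, choking on solid foods, nosogastric tube",
        ),
    ),
    (
        "Strength",
        True,
        (
            "without motor deficit of limbs or face",
            "mild motor deficit of limbs or face",
            "moderate/severe motor deficit of limbs or face",
            "limb paralysis",
        ),
    ),
    (
        "Balance",
        False,
        (
            "Romberg's attempt negative, normal gait",
            "guided walk, Romberg's attempt unstable",
            "walking with aids or help of another person",
            "bedridden",
        ),
    ),
    (
        "Ataxia",
        True,
        ("without ataxia", "ataxia present in one limb", "ataxia present in two limbs"),
    ),
    (
        "Sensory",
        True,
        (
            "without reactive and defective sensory deficit",
            "paraesthesia, facial or single limb hypoaesthesia",
            "hemianesthesia",
        ),
    ),
)


def build_default_scale() -> ScaleDefinition:
    """Return the published seven-item ASPOS instrument.

    Five items score 0-3, Ataxia and Sensory score 0-2; the maximum
    total is 19.  The ``nihss_like`` flag marks the items whose content
    parallels the NIHSS.
    """
    items = tuple(
        ItemDefinition(
            name=name,
            levels=tuple(ItemLevel(code, label) for code, label in enumerate(labels)),
            nihss_like=nihss_like,
        )
        for name, nihss_like, labels in _DEFAULT_ITEMS
    )
    return ScaleDefinition(items=items)


def score_item(applicable_levels: Iterable[int]) -> int:
    """Resolve several applicable level codes within one item to one score.

    When an examiner hesitates between levels, or several descriptions
    apply simultaneously, the level with the higher score is recorded.

    Parameters
    ----------
    applicable_levels:
        Non-empty collection of valid level codes of a single item.
    """
    codes = list(applicable_levels)
    if not codes:
        raise InvalidInputError("score_item requires at least one applicable level")
    if any((not isinstance(c, (int,)) or isinstance(c, bool)) for c in codes):
        raise InvalidInputError(f"level codes must be integers, got {codes}")
    return max(codes)


def total_score(
    assessment: Assessment, scale: Optional[ScaleDefinition] = None
) -> tuple[int, int]:
    """Sum assessable item scores.

    Returns ``(total, n_assessable)``.  Non-assessable items are simply
    omitted; the total is not rescaled for the missing items (the same
    convention the NIHSS uses).

    Raises
    ------
    DegenerateAssessmentError
        If every item is non-assessable.
    """
    if scale is None:
        scale = build_default_scale()
    assessment.validate(scale)
    scored = [r.score for r in assessment.responses if r.assessable]
    if not scored:
        raise DegenerateAssessmentError(
            f"assessment of {assessment.patient_id!r} at {assessment.timepoint!r} "
            "has no assessable items; no total score exists"
        )
    return sum(scored), len(scored)


def severity_group(total: Union[int, float]) -> SeverityGroup:
    """Map a total score (0-19) onto the LOW / INTERMEDIATE / HIGH strata.

    LOW covers totals 0-2, INTERMEDIATE exactly 3, HIGH 4 and above.
    A total of 0 (never observed in the development cohort, whose minimum
    was 1) falls in LOW, the sub-threshold stratum.
    """
    if total != int(total):
        raise InvalidInputError(f"total score must be an integer, got {total}")
    total = int(total)
    if not 0 <= total <= 19:
        raise InvalidInputError(f"total score {total} outside the valid range 0-19")
    if total <= 2:
        return SeverityGroup.LOW
    if total == 3:
        return SeverityGroup.INTERMEDIATE
    return SeverityGroup.HIGH


# ---------------------------------------------------------------------------
# serialization: one record per level so alternative instruments can be
# declared in a text file without touching code.

_SCALE_FIELDS = ("item", "code", "label", "nihss_like")


def scale_to_csv(scale: ScaleDefinition, path) -> None:
    """Write the instrument definition as CSV, one row per item level."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCALE_FIELDS)
        for it in scale.items:
            for lv in it.levels:
                writer.writerow([it.name, lv.code, lv.label, int(it.nihss_like)])


def scale_from_csv(path) -> ScaleDefinition:
    """Read an instrument definition written by :func:`scale_to_csv`."""
    per_item: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(
            _SCALE_FIELDS
        ):
            raise InvalidInputError(
                f"scale file must have header {_SCALE_FIELDS}, got {reader.fieldnames}"
            )
        for row in reader:
            name = row["item"]
            if name not in per_item:
                per_item[name] = {"levels": [], "nihss_like": bool(int(row["nihss_like"]))}
                order.append(name)
            per_item[name]["levels"].append(ItemLevel(int(row["code"]), row["label"]))
    items = tuple(
        ItemDefinition(
            name=name,
            levels=tuple(sorted(per_item[name]["levels"], key=lambda lv: lv.code)),
            nihss_like=per_item[name]["nihss_like"],
        )
        for name in order
    )
    return ScaleDefinition(items=items)
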