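"""Automated CTCAE toxicity grading of numeric laboratory results.

A lab value is graded relative to its reference range.  Values below the
lower limit of normal (LLN) or above the upper limit of normal (ULN) are
*out of range*; for gradeable lab types a directional rule maps the value to
a CTCAE grade 1-4 through an ordered list of severity bands.  Lab types may
carry two rules — one adverse-event term for the low direction and a
distinct one for the high direction (e.g. potassium: hypokalemia below LLN
3.5 mEq/L, hyperkalemia above ULN 5.1 mEq/L).

Band convention
---------------
CTCAE prints lab criteria like ``<LLN - 3.0`` (grade 1 hypokalemia) and
``>ULN - 5.5`` (grade 1 hyperkalemia).  Bands are therefore half-open toward
severity:

* low direction: ``lower <= value < upper`` — the printed numeric bound is
  inclusive, the LLN side exclusive (3.0 is still grade 1);
* high direction: ``lower < value <= upper`` — the printed numeric bound is
  inclusive, the ULN side exclusive.

Equality with LLN or ULN itself is *normal* (strict inequalities define the
out-of-range directions).  Grade 0 means no band matched; grade 5 (death) is
never assigned numerically.  Grades attainable only with clinical
information (e.g. "symptomatic", "hospitalization indicated") are declared
as context-dependent and surface as a ``needs_clinical_info`` flag rather
than a numeric grade.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from .catalog import Catalog

__all__ = [
    "GradingError",
    "UngradeableError",
    "ReferenceRange",
    "Band",
    "GradingRule",
    "RuleSet",
    "Override",
    "GradedResult",
    "ExceptionRecord",
    "select_direction",
    "assign_grade",
    "grade_result",
    "apply_override",
    "batch_grade",
    "normalize_unit",
    "units_compatible",
    "load_rules",
    "load_ranges",
    "default_rules_path",
    "default_ranges_path",
    "default_rules",
    "default_ranges",
]

Direction = Literal["low", "high"]
LLN = "LLN"
ULN = "ULN"

# lab codes whose mEq/L and mmol/L readings are numerically identical
# (monovalent ions); only for these is the unit pair interchangeable
MONOVALENT_LABS = frozenset({"K", "NA", "CL", "LI"})

RULES_COLUMNS = [
    "lab_type", "direction", "ctcae_version", "ae_term_id", "meddra_code",
    "unit", "grade", "lower_bound", "upper_bound", "context_dependent",
    "clinical_only",
]


class GradingError(ValueError):
    """Raised for invalid rules, ranges, or contract violations."""


class UngradeableError(GradingError):
    """Raised when a single result cannot enter the grading flow at all
    (non-numeric value, missing unit, unknown lab type)."""


@dataclass(frozen=True)
class ReferenceRange:
    """Normal limits for one lab type: ``lln < uln`` in a fixed unit."""

    lab_type: str
    lln: float
    uln: float
    unit: str

    def __post_init__(self) -> None:
        if not (self.lln < self.uln):
            raise GradingError(
                f"{self.lab_type}: lln ({self.lln}) must be < uln ({self.uln})"
            )
        if not self.unit:
            raise GradingError(f"{self.lab_type}: unit must be non-empty")


Bound = Union[float, str, None]  # numeric, "LLN"/"ULN" sentinel, or unbounded


@dataclass(frozen=True)
class Band:
    """One severity band: grade plus (lower, upper) bounds.

    Bounds may be numeric constants, the sentinels ``"LLN"``/``"ULN"``
    (substituted with the reference range at grading time), or ``None`` for
    unbounded toward severity.
    """

    grade: int
    lower: Bound = None
    upper: Bound = None

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise GradingError(f"band grade must be 1-4, got {self.grade}")


def _resolve(bound: Bound, range_: ReferenceRange, default: float) -> float:
    if bound is None:
        return default
    if bound == LLN:
        return range_.lln
    if bound == ULN:
        return range_.uln
    return float(bound)


@dataclass(frozen=True)
class GradingRule:
    """Directional grading rule for one lab type and one AE term."""

    lab_type: str
    direction: Direction
    ae_term_id: str
    meddra_code: int
    unit: str
    bands: tuple[Band, ...]
    context_dependent_grades: frozenset = frozenset()
    clinical_only: bool = False
    ctcae_version: int = 4

    def __post_init__(self) -> None:
        if self.direction not in ("low", "high"):
            raise GradingError(f"direction must be low/high, got {self.direction!r}")
        if self.ctcae_version not in (3, 4):
            raise GradingError(f"ctcae_version must be 3 or 4")
        grades = [b.grade for b in self.bands]
        if grades != sorted(grades) or len(set(grades)) != len(grades):
            raise GradingError(
                f"{self.lab_type}/{self.direction}: bands must be ordered by "
                f"strictly increasing grade, got {grades}"
            )
        for g in self.context_dependent_grades:
            if g not in (1, 2, 3, 4) or g in grades:
                raise GradingError(
                    f"{self.lab_type}/{self.direction}: context-dependent grade "
                    f"{g} invalid or duplicates a numeric band"
                )
        # contiguity away from the normal range: each band's severe-side
        # bound must equal the next band's normal-side bound
        for a, b in zip(self.bands, self.bands[1:]):
            far = a.lower if self.direction == "low" else a.upper
            near = b.upper if self.direction == "low" else b.lower
            if far is None:
                raise GradingError(
                    f"{self.lab_type}/{self.direction}: band grade {a.grade} "
                    f"is unbounded but a more severe band follows"
                )
            if near is None or float(far) != float(near):
                raise GradingError(
                    f"{self.lab_type}/{self.direction}: bands for grades "
                    f"{a.grade} and {b.grade} are not contiguous"
                )


def select_direction(value: float, range_: ReferenceRange) -> str:
    """``low`` iff value < LLN, ``high`` iff value > ULN, else ``normal``.

    Equality with either limit is normal (strict inequalities).
    """
    if not math.isfinite(value):
        raise GradingError(f"value must be finite, got {value!r}")
    if value < range_.lln:
        return "low"
    if value > range_.uln:
        return "high"
    return "normal"


def assign_grade(
    value: float, rule: GradingRule, range_: ReferenceRange
) -> tuple[int, bool]:
    """Locate the severity band containing ``value``; return (grade, flag).

    The caller must have resolved the direction: ``value`` lies on the
    rule's side of the reference range.  The flag is True when the rule
    declares a context-dependent grade strictly above the numeric grade
    (clinical information could raise the final grade), or when the rule is
    marked ``clinical_only``.
    """
    direction = select_direction(value, range_)
    if direction == "normal":
        raise GradingError(
            f"value {value} is inside the normal range "
            f"[{range_.lln}, {range_.uln}]; nothing to grade"
        )
    if direction != rule.direction:
        raise GradingError(
            f"value {value} is {direction} of normal but rule is for "
            f"{rule.direction} direction"
        )
    grade = 0
    for band in rule.bands:
        if rule.direction == "low":
            lo = _resolve(band.lower, range_, -math.inf)
            hi = _resolve(band.upper, range_, range_.lln)
            if lo <= value < hi:
                grade = band.grade
                break
        else:
            lo = _resolve(band.lower, range_, range_.uln)
            hi = _resolve(band.upper, range_, math.inf)
            if lo < value <= hi:
                grade = band.grade
                break
    needs_info = rule.clinical_only or any(
        g > grade for g in rule.context_dependent_grades
    )
    return grade, needs_info


class RuleSet:
    """Indexed collection of grading rules, one per (lab_type, direction)."""

    def __init__(self, rules: Iterable[GradingRule]):
        self._rules: dict[tuple[str, str], GradingRule] = {}
        for rule in rules:
            key = (rule.lab_type, rule.direction)
            if key in self._rules:
                raise GradingError(
                    f"duplicate rule for lab_type={rule.lab_type!r} "
                    f"direction={rule.direction!r}"
                )
            self._rules[key] = rule

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules.values())

    def get(self, lab_type: str, direction: str) -> Optional[GradingRule]:
        return self._rules.get((lab_type, direction))

    def for_lab(self, lab_type: str) -> list[GradingRule]:
        return [r for (lt, _), r in self._rules.items() if lt == lab_type]

    @property
    def lab_types(self) -> frozenset:
        return frozenset(lt for lt, _ in self._rules)

    def validate_against(self, catalog: Catalog) -> None:
        """Check every rule's AE term resolves in the given catalog."""
        for rule in self:
            term = catalog.get(rule.ae_term_id)
            if term.meddra_code != rule.meddra_code:
                raise GradingError(
                    f"rule {rule.lab_type}/{rule.direction}: meddra_code "
                    f"{rule.meddra_code} disagrees with catalog term "
                    f"{rule.ae_term_id!r} ({term.meddra_code})"
                )


@dataclass(frozen=True)
class Override:
    """A clinician's manual grade, recorded alongside the automatic one."""

    user: str
    new_grade: int
    reason: str
    timestamp: Optional[datetime] = None


@dataclass(frozen=True)
class GradedResult:
    """Outcome of grading one lab result.

    ``numeric_grade`` is ``None`` for results that are out of range but not
    gradeable (no rule for the lab type, or a unit mismatch); such results
    are still forwarded so clinicians can act on them.  An override never
    replaces the automatic grade; ``effective_grade`` prefers it.
    """

    source: object
    direction: str
    numeric_grade: Optional[int]
    ae_term_id: Optional[str] = None
    meddra_code: Optional[int] = None
    out_of_range: bool = False
    needs_clinical_info: bool = False
    gradeable: bool = True
    unit_mismatch: bool = False
    override: Optional[Override] = None
    locked: bool = False  # set once signed into an AE document

    def __post_init__(self) -> None:
        if self.numeric_grade is not None and self.numeric_grade not in range(6):
            raise GradingError(f"grade must be 0-5, got {self.numeric_grade}")
        has_term = self.ae_term_id is not None
        graded_ae = self.numeric_grade is not None and self.numeric_grade >= 1
        if has_term != graded_ae:
            raise GradingError(
                "ae_term_id must be present exactly when numeric_grade >= 1"
            )

    @property
    def effective_grade(self) -> Optional[int]:
        if self.override is not None:
            return self.override.new_grade
        return self.numeric_grade


def grade_result(
    result,
    rules: RuleSet,
    ranges: dict[str, ReferenceRange],
    catalog: Optional[Catalog] = None,
) -> GradedResult:
    """Grade one lab result against the rule table.

    The reference range carried on the result itself (from its OBX segment)
    wins over the configured defaults, since labs report
    instrument-specific ranges.  Raises :class:`UngradeableError` for
    results that cannot enter the flow (non-numeric value, missing unit,
    unknown lab type); use :func:`batch_grade` to isolate such failures.
    """
    value = getattr(result, "value", None)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        try:
            value = float(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise UngradeableError(f"non-numeric value {value!r}") from None
    unit = getattr(result, "unit", None)
    if not unit:
        raise UngradeableError("missing unit")
    lab_type = getattr(result, "lab_type", None)
    if not lab_type:
        raise UngradeableError("missing lab type")

    own_range = getattr(result, "reference_range", None)
    if own_range is not None:
        range_ = ReferenceRange(lab_type, float(own_range[0]), float(own_range[1]), unit)
    elif lab_type in ranges:
        range_ = ranges[lab_type]
    else:
        raise UngradeableError(f"unknown lab type {lab_type!r}: no reference range")

    clinical_only_flagged = any(r.clinical_only for r in rules.for_lab(lab_type))
    direction = select_direction(value, range_)
    if direction == "normal":
        return GradedResult(
            source=result,
            direction="normal",
            numeric_grade=0,
            out_of_range=False,
            needs_clinical_info=clinical_only_flagged,
        )
    rule = rules.get(lab_type, direction)
    if rule is None:
        # out of range but ungradeable: no rule covers this lab/direction
        return GradedResult(
            source=result,
            direction=direction,
            numeric_grade=None,
            out_of_range=True,
            gradeable=False,
            needs_clinical_info=clinical_only_flagged,
        )
    if not units_compatible(unit, rule.unit, lab_type):
        return GradedResult(
            source=result,
            direction=direction,
            numeric_grade=None,
            out_of_range=True,
            gradeable=False,
            unit_mismatch=True,
        )
    grade, needs_info = assign_grade(value, rule, range_)
    if catalog is not None and grade >= 1:
        catalog.get(rule.ae_term_id)  # referential check
    return GradedResult(
        source=result,
        direction=direction,
        numeric_grade=grade,
        ae_term_id=rule.ae_term_id if grade >= 1 else None,
        meddra_code=rule.meddra_code if grade >= 1 else None,
        out_of_range=True,
        needs_clinical_info=needs_info or clinical_only_flagged,
    )


def apply_override(
    graded: GradedResult,
    user: str,
    new_grade: int,
    reason: str,
    timestamp: Optional[datetime] = None,
) -> GradedResult:
    """Record a manual grade on top of the automatic one (audit preserved)."""
    if graded.locked:
        raise GradingError("result already signed into an AE document")
    if new_grade not in range(6):
        raise GradingError(f"override grade must be 0-5, got {new_grade}")
    if not reason or not reason.strip():
        raise GradingError("override reason must be non-empty")
    return replace(
        graded, override=Override(user=user, new_grade=new_grade,
                                  reason=reason.strip(), timestamp=timestamp)
    )


@dataclass(frozen=True)
class ExceptionRecord:
    """One per-result failure from a batch run."""

    index: int
    source: object
    reason: str


def batch_grade(
    results: Iterable,
    rules: RuleSet,
    ranges: dict[str, ReferenceRange],
    catalog: Optional[Catalog] = None,
) -> tuple[list[GradedResult], list[ExceptionRecord]]:
    """Grade a stream of results, isolating per-result failures.

    Order-preserving; nothing raises mid-batch.  The graded list contains
    both gradeable results and out-of-range-but-ungradeable ones (both are
    forwarded to the AE workflow); the exception report holds results that
    could not be processed at all.
    """
    graded: list[GradedResult] = []
    exceptions: list[ExceptionRecord] = []
    for i, result in enumerate(results):
        try:
            graded.append(grade_result(result, rules, ranges, catalog))
        except GradingError as exc:
            exceptions.append(ExceptionRecord(index=i, source=result, reason=str(exc)))
    return graded, exceptions


def normalize_unit(unit: str) -> str:
    """Case/spacing normalization; ``10^9/L`` variants collapse to ``10*9/l``."""
    u = unit.strip().lower().replace(" ", "")
    u = u.replace("10^9/l", "10*9/l").replace("x10*9/l", "10*9/l")
    u = u.replace("10e9/l", "10*9/l")
    return u


def units_compatible(unit_a: str, unit_b: str, lab_type: str) -> bool:
    """Exact match after normalization; mEq/L == mmol/L for monovalent ions.

    Anything else is a mismatch — never a silent conversion.
    """
    a, b = normalize_unit(unit_a), normalize_unit(unit_b)
    if a == b:
        return True
    if lab_type in MONOVALENT_LABS and {a, b} == {"meq/l", "mmol/l"}:
        return True
    return False


def _parse_bound(raw: str) -> Bound:
    raw = raw.strip()
    if not raw:
        return None
    if raw.upper() in (LLN, ULN):
        return raw.upper()
    return float(raw)


def load_rules(path: Union[str, Path], catalog: Optional[Catalog] = None) -> RuleSet:
    """Load a grading-rules CSV (one row per band) into a :class:`RuleSet`."""
    path = Path(path)
    if not path.exists():
        raise GradingError(f"rules file not found: {path}")
    groups: dict[tuple[str, str], dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(RULES_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise GradingError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            key = (row["lab_type"].strip(), row["direction"].strip())
            grp = groups.setdefault(
                key,
                {
                    "ae_term_id": row["ae_term_id"].strip(),
                    "meddra_code": int(row["meddra_code"]),
                    "unit": row["unit"].strip(),
                    "ctcae_version": int(row["ctcae_version"]),
                    "bands": [],
                    "context": set(),
                    "clinical_only": False,
                },
            )
            try:
                grade = int(row["grade"])
                if row.get("clinical_only", "0").strip() in ("1", "true", "yes"):
                    grp["clinical_only"] = True
                if row.get("context_dependent", "0").strip() in ("1", "true", "yes"):
                    grp["context"].add(grade)
                else:
                    grp["bands"].append(
                        Band(
                            grade=grade,
                            lower=_parse_bound(row.get("lower_bound", "")),
                            upper=_parse_bound(row.get("upper_bound", "")),
                        )
                    )
            except (ValueError, GradingError) as exc:
                raise GradingError(f"{path} row {line_no}: {exc}") from None
    rules = []
    for (lab_type, direction), grp in groups.items():
        rules.append(
            GradingRule(
                lab_type=lab_type,
                direction=direction,  # type: ignore[arg-type]
                ae_term_id=grp["ae_term_id"],
                meddra_code=grp["meddra_code"],
                unit=grp["unit"],
                bands=tuple(sorted(grp["bands"], key=lambda b: b.grade)),
                context_dependent_grades=frozenset(grp["context"]),
                clinical_only=grp["clinical_only"],
                ctcae_version=grp["ctcae_version"],
            )
        )
    ruleset = RuleSet(rules)
    if catalog is not None:
        ruleset.validate_against(catalog)
    return ruleset


def load_ranges(path: Union[str, Path]) -> dict[str, ReferenceRange]:
    """Load default reference ranges, keyed by lab type."""
    path = Path(path)
    if not path.exists():
        raise GradingError(f"ranges file not found: {path}")
    ranges: dict[str, ReferenceRange] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for line_no, row in enumerate(csv.DictReader(fh), start=2):
            lab_type = row["lab_type"].strip()
            if lab_type in ranges:
                raise GradingError(f"{path} row {line_no}: duplicate lab_type {lab_type!r}")
            ranges[lab_type] = ReferenceRange(
                lab_type=lab_type,
                lln=float(row["lln"]),
                uln=float(row["uln"]),
                unit=row["unit"].strip(),
            )
    return ranges


def default_rules_path() -> Path:
    return Path(str(resources.files("aecap").joinpath("data/grading_rules.csv")))


def default_ranges_path() -> Path:
    return Path(str(resources.files("aecap").joinpath("data/reference_ranges.csv")))


def default_rules(catalog: Optional[Catalog] = None) -> RuleSet:
    """The shipped demonstration rule table (28 lab types, CTCAE v4)."""
    return load_rules(default_rules_path(), catalog)


def default_ranges() -> dict[str, ReferenceRange]:
    return load_ranges(default_ranges_path())
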