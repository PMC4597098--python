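"""CTCAE term catalog: load, validate, and query the adverse-event vocabulary.

The Common Terminology Criteria for Adverse Events (CTCAE) is the NCI's
standard vocabulary for adverse events in cancer trials.  Each term carries a
system organ class (e.g. "Cardiac disorders"), a MedDRA code, and — when the
condition has an ICD-9 code — a diagnosis categorization; everything else is
a symptom.  Diagnosis lists are additionally grouped under clinical
subheadings (e.g. "arrhythmias", "valvular heart disease") so that clinicians
can locate a term without knowing its exact alphabetical name.

The package ships a small demonstration catalog (CTCAE v4-consistent, with a
few v3 entries) covering the lab-gradeable terms used by :mod:`aecap.grading`
plus cardiac and gastrointestinal examples.  Full CTCAE vocabularies use the
same CSV schema and can be supplied by the user.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

__all__ = [
    "CatalogError",
    "CtcaeTerm",
    "Catalog",
    "categorize_term",
    "load_catalog",
    "save_catalog",
    "default_catalog_path",
    "default_catalog",
]

Category = Literal["symptom", "diagnosis"]

CATALOG_COLUMNS = [
    "term_id",
    "name",
    "ctcae_version",
    "system_organ_class",
    "meddra_code",
    "icd9_code",
    "subheading",
    "description",
]


class CatalogError(ValueError):
    """Raised when a catalog file violates the schema or its invariants."""


def categorize_term(icd9_code: Optional[str]) -> Category:
    """Classify a term as diagnosis or symptom from its ICD-9 code.

    A term is a *diagnosis* if and only if it carries a non-empty ICD-9
    code; otherwise it is a *symptom*.  Blank or whitespace-only codes are
    treated as absent, since blank cells are common in tabular sources.
    """
    if icd9_code is None or not icd9_code.strip():
        return "symptom"
    return "diagnosis"


@dataclass(frozen=True)
class CtcaeTerm:
    """One CTCAE vocabulary entry.

    ``category`` is derived, never stored: diagnosis iff ``icd9_code`` is
    present.  ``subheading`` applies only to diagnosis lists; symptoms are
    listed flat per organ system.
    """

    term_id: str
    name: str
    ctcae_version: int
    system_organ_class: str
    meddra_code: Optional[int] = None
    icd9_code: Optional[str] = None
    subheading: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.term_id:
            raise CatalogError("term_id must be non-empty")
        if not self.name:
            raise CatalogError(f"term {self.term_id!r}: name must be non-empty")
        if self.ctcae_version not in (3, 4):
            raise CatalogError(
                f"term {self.term_id!r}: ctcae_version must be 3 or 4, "
                f"got {self.ctcae_version!r}"
            )
        if self.meddra_code is not None and self.meddra_code <= 0:
            raise CatalogError(
                f"term {self.term_id!r}: meddra_code must be a positive "
                f"integer, got {self.meddra_code!r}"
            )

    @property
    def category(self) -> Category:
        return categorize_term(self.icd9_code)


@dataclass
class Catalog:
    """A versioned collection of CTCAE terms, indexed by id and organ system."""

    version: int
    terms: tuple[CtcaeTerm, ...] = ()
    _by_id: dict[str, CtcaeTerm] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, CtcaeTerm] = {}
        for term in self.terms:
            if term.ctcae_version != self.version:
                raise CatalogError(
                    f"term {term.term_id!r} has version {term.ctcae_version}, "
                    f"catalog is version {self.version}"
                )
            if term.term_id in by_id:
                raise CatalogError(f"duplicate term_id {term.term_id!r}")
            by_id[term.term_id] = term
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def __iter__(self):
        return iter(self.terms)

    def get(self, term_id: str) -> CtcaeTerm:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise CatalogError(f"unknown term_id {term_id!r}") from None

    @property
    def system_organ_classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.system_organ_class, None)
        return tuple(sorted(seen))

    def find_by_name(self, name: str) -> Optional[CtcaeTerm]:
        """Exact-name lookup (no synonym or fuzzy matching)."""
        for t in self.terms:
            if t.name == name:
                return t
        return None

    def list_terms(
        self,
        system_organ_class: str,
        category: Literal["symptom", "diagnosis", "both"] = "both",
    ) -> list[CtcaeTerm]:
        """Terms of one organ system in clinical display order.

        Diagnoses are grouped by subheading (alphabetical; terms without a
        subheading last), symptoms follow as a flat list; names are
        alphabetical within each group.  The order is deterministic, and
        diagnoses and symptoms are never interleaved within a group.
        """
        if system_organ_class not in {t.system_organ_class for t in self.terms}:
            raise CatalogError(
                f"unknown system_organ_class {system_organ_class!r}"
            )
        subset = [
            t
            for t in self.terms
            if t.system_organ_class == system_organ_class
            and (category == "both" or t.category == category)
        ]

        def key(t: CtcaeTerm):
            return (
                t.subheading is None,
                (t.subheading or "").lower(),
                t.category == "symptom",
                t.name.lower(),
                t.term_id,
            )

        return sorted(subset, key=key)


def _parse_row(row: dict, line_no: int, errors: list[str]) -> Optional[CtcaeTerm]:
    meddra_raw = (row.get("meddra_code") or "").strip()
    meddra: Optional[int] = None
    if meddra_raw:
        try:
            meddra = int(meddra_raw)
        except ValueError:
            errors.append(f"row {line_no}: malformed MedDRA code {meddra_raw!r}")
            return None
        if meddra <= 0:
            errors.append(f"row {line_no}: MedDRA code must be positive, got {meddra}")
            return None
    try:
        version = int((row.get("ctcae_version") or "").strip())
    except ValueError:
        errors.append(
            f"row {line_no}: malformed ctcae_version {row.get('ctcae_version')!r}"
        )
        return None
    try:
        return CtcaeTerm(
            term_id=(row.get("term_id") or "").strip(),
            name=(row.get("name") or "").strip(),
            ctcae_version=version,
            system_organ_class=(row.get("system_organ_class") or "").strip(),
            meddra_code=meddra,
            icd9_code=(row.get("icd9_code") or "").strip() or None,
            subheading=(row.get("subheading") or "").strip() or None,
            description=(row.get("description") or "").strip(),
        )
    except CatalogError as exc:
        errors.append(f"row {line_no}: {exc}")
        return None


def load_catalog(path: Union[str, Path], version: int) -> Catalog:
    """Load a catalog CSV, keeping only rows of the requested CTCAE version.

    Rows violating the schema or the catalog invariants are collected into a
    single :class:`CatalogError` with row-numbered diagnostics.  Duplicate
    (name, version) pairs are rejected naming both offending rows.
    """
    if version not in (3, 4):
        raise CatalogError(f"version must be 3 or 4, got {version!r}")
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    errors: list[str] = []
    terms: list[CtcaeTerm] = []
    seen_names: dict[tuple[str, int], int] = {}
    seen_ids: dict[str, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty file (no header)")
        missing = set(CATALOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CatalogError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            term = _parse_row(row, line_no, errors)
            if term is None or term.ctcae_version != version:
                continue
            name_key = (term.name, term.ctcae_version)
            if name_key in seen_names:
                errors.append(
                    f"row {line_no}: duplicate (name, version) "
                    f"{name_key!r}, first seen at row {seen_names[name_key]}"
                )
                continue
            if term.term_id in seen_ids:
                errors.append(
                    f"row {line_no}: duplicate term_id {term.term_id!r}, "
                    f"first seen at row {seen_ids[term.term_id]}"
                )
                continue
            seen_names[name_key] = line_no
            seen_ids[term.term_id] = line_no
            terms.append(term)
    if errors:
        raise CatalogError(f"{path}: " + "; ".join(errors))
    return Catalog(version=version, terms=tuple(terms))


def save_catalog(catalog: Catalog, path: Union[str, Path]) -> None:
    """Serialize a catalog back to the CSV schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_COLUMNS)
        for t in catalog.terms:
            writer.writerow(
                [
                    t.term_id,
                    t.name,
                    t.ctcae_version,
                    t.system_organ_class,
                    "" if t.meddra_code is None else t.meddra_code,
                    t.icd9_code or "",
                    t.subheading or "",
                    t.description,
                ]
            )


def default_catalog_path() -> Path:
    """Path of the demonstration catalog shipped with the package."""
    return Path(str(resources.files("aecap").joinpath("data/ctcae_catalog.csv")))


def default_catalog(version: int = 4) -> Catalog:
    """Load the shipped demonstration catalog (CTCAE v4 by default)."""
    return load_catalog(default_catalog_path(), version)
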