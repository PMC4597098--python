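"""AE document generation, case-report exports, and workflow metrics.

Documents group adverse events into sections by assessment date and AE
category; lab-based AEs are filed as separate documents ("Lab Based
Adverse Event" note type) from office-visit AE documentation.  Narrative
rendering is template-driven and a pure function of its inputs, so
regenerating a document from unchanged data is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "ReportingError",
    "AeEntry",
    "AeDocument",
    "LabBatch",
    "generate_ae_document",
    "sign_document",
    "export_case_report_rows",
    "write_case_report_csv",
    "read_case_report_csv",
    "query_metrics",
]

DocumentType = Literal["office_visit_ae", "lab_based_ae"]

DOCUMENT_TITLES = {
    "office_visit_ae": "Office Visit Adverse Event",
    "lab_based_ae": "Lab Based Adverse Event",
}

CASE_REPORT_COLUMNS = [
    "ae_id", "participant_id", "study_id", "term_id", "term_name",
    "meddra_code", "grade", "status", "onset_date", "resolution_date",
    "attribution_agent", "attribution_relatedness", "source",
]


class ReportingError(ValueError):
    """Raised for unfinalized sources or immutability violations."""


@dataclass(frozen=True)
class AeEntry:
    """One adverse event as it appears in a document section."""

    ae_id: str
    term_name: str
    category: str  # symptom | diagnosis
    meddra_code: Optional[int]
    grade: int
    status: str  # ongoing | resolved
    assessment_date: date
    attribution: Optional[tuple[str, str]] = None  # (agent, relatedness)
    source: str = "office_visit"


@dataclass(frozen=True)
class AeDocument:
    """A generated AE assessment document.

    Sections are keyed by (assessment date, AE category) in deterministic
    order.  Once signed, a document is immutable.
    """

    document_id: str
    participant_id: str
    csn: str
    provider: str
    document_type: DocumentType
    groups: tuple[tuple[tuple[str, str], tuple[AeEntry, ...]], ...]
    narrative: str
    created_at: datetime
    signed: bool = False


@dataclass(frozen=True)
class LabBatch:
    """A batch of lab-sourced AEs awaiting document generation."""

    participant_id: str
    study_id: str
    entries: tuple[AeEntry, ...]
    created_at: datetime
    finalized: bool = True


def _group_entries(
    entries: Sequence[AeEntry],
) -> tuple[tuple[tuple[str, str], tuple[AeEntry, ...]], ...]:
    keys = sorted({(e.assessment_date.isoformat(), e.category) for e in entries})
    groups = []
    for key in keys:
        members = sorted(
            (
                e
                for e in entries
                if (e.assessment_date.isoformat(), e.category) == key
            ),
            key=lambda e: (e.term_name.lower(), e.ae_id),
        )
        groups.append((key, tuple(members)))
    return tuple(groups)


def _render_narrative(
    document_type: DocumentType,
    participant_id: str,
    csn: str,
    provider: str,
    groups,
) -> str:
    lines = [
        "ADVERSE EVENT ASSESSMENT NOTE",
        f"Document type: {DOCUMENT_TITLES[document_type]}",
        f"Participant: {participant_id} | Encounter (CSN): {csn} | Provider: {provider}",
        "",
    ]
    if not groups:
        lines.append("No adverse events to report.")
    for (day, category), entries in groups:
        lines.append(f"Assessment date {day} - {category}:")
        for e in entries:
            meddra = f" (MedDRA {e.meddra_code})" if e.meddra_code else ""
            attr = (
                f"; attribution: {e.attribution[0]} ({e.attribution[1]})"
                if e.attribution
                else ""
            )
            lines.append(
                f"  - {e.term_name}{meddra}: grade {e.grade}, {e.status}{attr}"
            )
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def generate_ae_document(
    source,
    provider: str,
    csn: str,
    *,
    entries: Optional[Sequence[AeEntry]] = None,
    document_id: Optional[str] = None,
    created_at: Optional[datetime] = None,
) -> AeDocument:
    """Build a document from a finalized visit assessment or a lab batch.

    ``source`` is either a finalized visit assessment (``state ==
    "finalized"``) whose entries the caller resolved, or a
    :class:`LabBatch`.  Lab batches always produce ``lab_based_ae``
    documents, filed separately from office-visit documentation.
    """
    if isinstance(source, LabBatch):
        if not source.finalized:
            raise ReportingError("lab batch is not finalized")
        doc_type: DocumentType = "lab_based_ae"
        entries = source.entries if entries is None else tuple(entries)
        participant_id = source.participant_id
        created_at = created_at or source.created_at
    else:
        state = getattr(source, "state", None)
        if state != "finalized":
            raise ReportingError(
                f"assessment must be finalized before document generation "
                f"(state={state!r})"
            )
        doc_type = "office_visit_ae"
        if entries is None:
            raise ReportingError("entries must be supplied for visit assessments")
        participant_id = source.participant_id
        if created_at is None:
            raise ReportingError("created_at must be supplied for visit assessments")
    groups = _group_entries(tuple(entries))
    narrative = _render_narrative(doc_type, participant_id, csn, provider, groups)
    return AeDocument(
        document_id=document_id or f"DOC-{participant_id}-{csn}",
        participant_id=participant_id,
        csn=csn,
        provider=provider,
        document_type=doc_type,
        groups=groups,
        narrative=narrative,
        created_at=created_at,
        signed=False,
    )


def sign_document(document: AeDocument, provider: str) -> AeDocument:
    """Provider signature; returns the immutable signed document."""
    if document.signed:
        raise ReportingError(f"document {document.document_id} is already signed")
    return replace(document, signed=True, provider=provider)


def _ae_row(ae, catalog) -> dict:
    term = catalog.get(ae.term_id)
    agent, relatedness = ae.attribution if ae.attribution else ("", "")
    return {
        "ae_id": ae.ae_id,
        "participant_id": ae.participant_id,
        "study_id": ae.study_id,
        "term_id": ae.term_id,
        "term_name": term.name,
        "meddra_code": term.meddra_code if term.meddra_code else "",
        "grade": ae.current_grade,
        "status": ae.status,
        "onset_date": ae.onset_date.isoformat(),
        "resolution_date": ae.resolution_date.isoformat() if ae.resolution_date else "",
        "attribution_agent": agent,
        "attribution_relatedness": relatedness,
        "source": ae.source,
    }


def export_case_report_rows(aes: Iterable, catalog) -> pd.DataFrame:
    """One case-report row per adverse event (no loss, no duplication)."""
    rows = [_ae_row(ae, catalog) for ae in aes]
    return pd.DataFrame(rows, columns=CASE_REPORT_COLUMNS)


def write_case_report_csv(aes: Iterable, catalog, path: Union[str, Path]) -> None:
    export_case_report_rows(aes, catalog).to_csv(path, index=False)


def read_case_report_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Reload a case-report export with the same column dtypes as written."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["grade"] = df["grade"].astype(int)
    return df


def query_metrics(total_queries: int, ae_related: int) -> int:
    """Percentage of data queries that were AE-related, as an integer.

    Rounds half-up (73 of 106 queries gives 69%).
    """
    if total_queries <= 0:
        raise ReportingError("total_queries must be positive")
    if not 0 <= ae_related <= total_queries:
        raise ReportingError("ae_related must lie in [0, total_queries]")
    pct = Decimal(100 * ae_related) / Decimal(total_queries)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
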