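"""Single-file embedded store for registry + lifecycle state.

A JSON snapshot of the whole workflow state (registry, AEs, assessments,
lab documents, reminder log, clock position), so the command-line
workflow survives between invocations without any database server.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path
from typing import Union

from . import reporting
from .catalog import Catalog, default_catalog
from .lifecycle import (
    AdverseEvent,
    AeTracker,
    Evaluation,
    HistoryEntry,
    ManualClock,
    VisitAssessment,
)
from .registry import Registry

__all__ = ["save_state", "load_state"]


def _ae_to_dict(ae: AdverseEvent) -> dict:
    return {
        "ae_id": ae.ae_id,
        "participant_id": ae.participant_id,
        "study_id": ae.study_id,
        "term_id": ae.term_id,
        "status": ae.status,
        "current_grade": ae.current_grade,
        "onset_date": ae.onset_date.isoformat(),
        "source": ae.source,
        "created_at": ae.created_at.isoformat(),
        "resolution_date": ae.resolution_date.isoformat() if ae.resolution_date else None,
        "attribution": list(ae.attribution) if ae.attribution else None,
        "signed": ae.signed,
        "history": [
            [h.date.isoformat(), h.grade, h.status, h.actor] for h in ae.history
        ],
    }


def _ae_from_dict(d: dict) -> AdverseEvent:
    return AdverseEvent(
        ae_id=d["ae_id"],
        participant_id=d["participant_id"],
        study_id=d["study_id"],
        term_id=d["term_id"],
        status=d["status"],
        current_grade=d["current_grade"],
        onset_date=date.fromisoformat(d["onset_date"]),
        source=d["source"],
        created_at=datetime.fromisoformat(d["created_at"]),
        resolution_date=(
            date.fromisoformat(d["resolution_date"]) if d["resolution_date"] else None
        ),
        attribution=tuple(d["attribution"]) if d["attribution"] else None,
        signed=d["signed"],
        history=[
            HistoryEntry(date.fromisoformat(h[0]), h[1], h[2], h[3])
            for h in d["history"]
        ],
    )


def _eval_to_list(ev: Evaluation) -> list:
    return [ev.decision, ev.grade, ev.date.isoformat(), ev.actor]


def _eval_from_list(v: list) -> Evaluation:
    return Evaluation(v[0], v[1], date.fromisoformat(v[2]), v[3])


def _assessment_to_dict(a: VisitAssessment) -> dict:
    return {
        "assessment_id": a.assessment_id,
        "participant_id": a.participant_id,
        "study_id": a.study_id,
        "created_at": a.created_at.isoformat(),
        "evaluations": {
            ae_id: (_eval_to_list(ev) if ev else None)
            for ae_id, ev in a.evaluations.items()
        },
        "evaluation_history": [
            [ae_id, _eval_to_list(ev)] for ae_id, ev in a.evaluation_history
        ],
        "new_aes": a.new_aes,
        "state": a.state,
        "csn": a.csn,
        "finalized_by": a.finalized_by,
    }


def _assessment_from_dict(d: dict) -> VisitAssessment:
    return VisitAssessment(
        assessment_id=d["assessment_id"],
        participant_id=d["participant_id"],
        study_id=d["study_id"],
        created_at=datetime.fromisoformat(d["created_at"]),
        evaluations={
            k: (_eval_from_list(v) if v else None)
            for k, v in d["evaluations"].items()
        },
        evaluation_history=[
            (ae_id, _eval_from_list(v)) for ae_id, v in d["evaluation_history"]
        ],
        new_aes=list(d["new_aes"]),
        state=d["state"],
        csn=d["csn"],
        finalized_by=d["finalized_by"],
    )


def _entry_to_dict(e: reporting.AeEntry) -> dict:
    return {
        "ae_id": e.ae_id,
        "term_name": e.term_name,
        "category": e.category,
        "meddra_code": e.meddra_code,
        "grade": e.grade,
        "status": e.status,
        "assessment_date": e.assessment_date.isoformat(),
        "attribution": list(e.attribution) if e.attribution else None,
        "source": e.source,
    }


def _entry_from_dict(d: dict) -> reporting.AeEntry:
    return reporting.AeEntry(
        ae_id=d["ae_id"],
        term_name=d["term_name"],
        category=d["category"],
        meddra_code=d["meddra_code"],
        grade=d["grade"],
        status=d["status"],
        assessment_date=date.fromisoformat(d["assessment_date"]),
        attribution=tuple(d["attribution"]) if d["attribution"] else None,
        source=d["source"],
    )


def _doc_to_dict(doc: reporting.AeDocument) -> dict:
    return {
        "document_id": doc.document_id,
        "participant_id": doc.participant_id,
        "csn": doc.csn,
        "provider": doc.provider,
        "document_type": doc.document_type,
        "groups": [
            [list(key), [_entry_to_dict(e) for e in entries]]
            for key, entries in doc.groups
        ],
        "narrative": doc.narrative,
        "created_at": doc.created_at.isoformat(),
        "signed": doc.signed,
    }


def _doc_from_dict(d: dict) -> reporting.AeDocument:
    return reporting.AeDocument(
        document_id=d["document_id"],
        participant_id=d["participant_id"],
        csn=d["csn"],
        provider=d["provider"],
        document_type=d["document_type"],
        groups=tuple(
            (tuple(key), tuple(_entry_from_dict(e) for e in entries))
            for key, entries in d["groups"]
        ),
        narrative=d["narrative"],
        created_at=datetime.fromisoformat(d["created_at"]),
        signed=d["signed"],
    )


def save_state(path: Union[str, Path], tracker: AeTracker) -> None:
    payload = {
        "registry": tracker.registry.to_dict(),
        "clock": tracker.now().isoformat(),
        "aes": [_ae_to_dict(ae) for ae in tracker.aes.values()],
        "assessments": [
            _assessment_to_dict(a) for a in tracker.assessments.values()
        ],
        "lab_documents": [_doc_to_dict(d) for d in tracker.lab_documents.values()],
        "lab_document_study": tracker._lab_document_study,
        "reminder_log": {k: v.isoformat() for k, v in tracker._reminder_log.items()},
        "counters": tracker._counters,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_state(path: Union[str, Path], catalog: Catalog = None) -> AeTracker:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    registry = Registry.from_dict(payload["registry"])
    clock = ManualClock(datetime.fromisoformat(payload["clock"]))
    tracker = AeTracker(registry, catalog or default_catalog(), clock)
    for d in payload["aes"]:
        ae = _ae_from_dict(d)
        tracker.aes[ae.ae_id] = ae
    for d in payload["assessments"]:
        a = _assessment_from_dict(d)
        tracker.assessments[a.assessment_id] = a
    for d in payload["lab_documents"]:
        doc = _doc_from_dict(d)
        tracker.lab_documents[doc.document_id] = doc
    tracker._lab_document_study = dict(payload["lab_document_study"])
    tracker._reminder_log = {
        k: datetime.fromisoformat(v) for k, v in payload["reminder_log"].items()
    }
    tracker._counters = dict(payload["counters"])
    tracker.clock = clock
    return tracker
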