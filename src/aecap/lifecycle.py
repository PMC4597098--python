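"""Adverse-event lifecycle: creation, visit assessment, resolution, reminders.

The tracker enforces the workflow rules of an AE capture system:

* **Deduplication** — at most one *ongoing* AE per (participant, study,
  CTCAE term); selecting a term with an ongoing episode is rejected naming
  the blocking AE.  A resolved term may recur later as a new episode.
* **Completeness** — a visit assessment opens pre-populated with every
  ongoing AE; it cannot be finalized while any of them is unevaluated
  (the unevaluated set is the UI's "red frame" list).
* **Authorization** — a nurse may assess, but finalizing/signing requires
  an authorized provider, and finalization binds the assessment to an
  encounter CSN so the documentation lands in the correct progress note.
* **Lab AEs** — graded lab results auto-create (or grade-update) lab-source
  AEs that await provider signature in separate lab-based documents.
* **Reminders** — unfinalized assessments and unsigned lab documents older
  than 24 hours emit reminder records, idempotently within a configurable
  re-reminder interval.

All timestamps come from an injected clock; the module never reads the
wall clock, which makes the 24-hour rule directly testable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Callable, Iterable, Literal, Optional, Union

from . import reporting
from .catalog import Catalog
from .grading import GradedResult
from .registry import Registry, RegistryError

__all__ = [
    "LifecycleError",
    "DuplicateOngoingAeError",
    "IncompleteAssessmentError",
    "UnauthorizedError",
    "ManualClock",
    "HistoryEntry",
    "AdverseEvent",
    "Evaluation",
    "VisitAssessment",
    "Reminder",
    "BoundGraded",
    "LabIngestReport",
    "AeTracker",
    "REMINDER_THRESHOLD",
]

Status = Literal["ongoing", "resolved"]
Source = Literal["lab", "office_visit"]

REMINDER_THRESHOLD = timedelta(hours=24)


class LifecycleError(ValueError):
    """Base error for workflow violations."""


class DuplicateOngoingAeError(LifecycleError):
    """Selecting a term that already has an ongoing AE for this
    participant+study; carries the blocking AE id."""

    def __init__(self, message: str, blocking_ae_id: str):
        super().__init__(message)
        self.blocking_ae_id = blocking_ae_id


class IncompleteAssessmentError(LifecycleError):
    """Finalization attempted while ongoing AEs remain unevaluated."""

    def __init__(self, message: str, pending: list):
        super().__init__(message)
        self.pending = list(pending)


class UnauthorizedError(LifecycleError):
    """Action denied by the registry's access rules."""


class ManualClock:
    """Injectable clock for deterministic workflow timing."""

    def __init__(self, start: datetime):
        self._now = start

    def now(self) -> datetime:
        return self._now

    def advance(self, delta: timedelta) -> datetime:
        self._now += delta
        return self._now

    def set(self, when: datetime) -> None:
        self._now = when

    def __call__(self) -> datetime:
        return self._now


@dataclass(frozen=True)
class HistoryEntry:
    date: date
    grade: int
    status: Status
    actor: str


@dataclass
class AdverseEvent:
    """One tracked adverse-event episode with an append-only history."""

    ae_id: str
    participant_id: str
    study_id: str
    term_id: str
    status: Status
    current_grade: int
    onset_date: date
    source: Source
    created_at: datetime
    resolution_date: Optional[date] = None
    attribution: Optional[tuple[str, str]] = None  # (agent, relatedness label)
    signed: bool = False
    history: list[HistoryEntry] = field(default_factory=list)


@dataclass(frozen=True)
class Evaluation:
    decision: Status
    grade: int
    date: date
    actor: str


@dataclass
class VisitAssessment:
    """One encounter's evaluation sheet over all ongoing AEs."""

    assessment_id: str
    participant_id: str
    study_id: str
    created_at: datetime
    evaluations: dict[str, Optional[Evaluation]] = field(default_factory=dict)
    evaluation_history: list[tuple[str, Evaluation]] = field(default_factory=list)
    new_aes: list[str] = field(default_factory=list)
    state: Literal["open", "finalized"] = "open"
    csn: Optional[str] = None
    finalized_by: Optional[str] = None


@dataclass(frozen=True)
class Reminder:
    """A reminder record (transport such as e-mail is out of scope)."""

    target_id: str
    target_kind: Literal["assessment", "lab_document"]
    provider: str
    due_since: datetime
    emitted_at: datetime


@dataclass(frozen=True)
class BoundGraded:
    """A graded lab result bound to one participant on one study."""

    graded: GradedResult
    participant_id: str
    study_id: str


@dataclass
class LabIngestReport:
    """Outcome of one graded-lab ingest batch."""

    created: list[str] = field(default_factory=list)       # new lab AE ids
    updated: list[str] = field(default_factory=list)       # grade-changed AE ids
    retained: list[BoundGraded] = field(default_factory=list)  # no AE created
    documents: list[str] = field(default_factory=list)     # unsigned doc ids


class AeTracker:
    """State machine over AEs, visit assessments, and lab documents."""

    def __init__(
        self,
        registry: Registry,
        catalog: Union[Catalog, dict[int, Catalog]],
        clock: Union[ManualClock, Callable[[], datetime]],
        reminder_threshold: timedelta = REMINDER_THRESHOLD,
        re_reminder_interval: timedelta = timedelta(hours=24),
    ):
        self.registry = registry
        self.catalogs: dict[int, Catalog] = (
            {catalog.version: catalog} if isinstance(catalog, Catalog) else dict(catalog)
        )
        self.clock = clock if isinstance(clock, ManualClock) else None
        self._clock = clock.now if isinstance(clock, ManualClock) else clock
        self.reminder_threshold = reminder_threshold
        self.re_reminder_interval = re_reminder_interval
        self.aes: dict[str, AdverseEvent] = {}
        self.assessments: dict[str, VisitAssessment] = {}
        self.lab_documents: dict[str, reporting.AeDocument] = {}
        self._lab_document_study: dict[str, str] = {}
        self._reminder_log: dict[str, datetime] = {}
        self._counters = {"ae": 0, "assessment": 0, "doc": 0}

    # -- helpers --------------------------------------------------------
    def now(self) -> datetime:
        return self._clock()

    def _next_id(self, kind: str, prefix: str) -> str:
        self._counters[kind] += 1
        return f"{prefix}{self._counters[kind]:05d}"

    def _catalog_for(self, study_id: str) -> Catalog:
        study = self.registry.studies.get(study_id)
        if study is None:
            raise LifecycleError(f"unknown study {study_id!r}")
        cat = self.catalogs.get(study.ctcae_version)
        if cat is None:
            raise LifecycleError(
                f"no catalog loaded for CTCAE version {study.ctcae_version}"
            )
        return cat

    def _require_enrolled(self, participant_id: str, study_id: str) -> None:
        participant = self.registry.participants.get(participant_id)
        if participant is None:
            raise LifecycleError(f"unknown participant {participant_id!r}")
        if study_id not in participant.enrolled_studies:
            raise LifecycleError(
                f"participant {participant_id!r} is not enrolled in {study_id!r}"
            )

    def ongoing_aes(self, participant_id: str, study_id: str) -> list[AdverseEvent]:
        return sorted(
            (
                ae
                for ae in self.aes.values()
                if ae.participant_id == participant_id
                and ae.study_id == study_id
                and ae.status == "ongoing"
            ),
            key=lambda ae: ae.ae_id,
        )

    def _ongoing_with_term(
        self, participant_id: str, study_id: str, term_id: str
    ) -> Optional[AdverseEvent]:
        for ae in self.ongoing_aes(participant_id, study_id):
            if ae.term_id == term_id:
                return ae
        return None

    # -- AE creation ----------------------------------------------------
    def create_ae(
        self,
        participant_id: str,
        study_id: str,
        term_id: str,
        grade: int,
        onset_date: date,
        source: Source = "office_visit",
        attribution: Optional[tuple[str, str]] = None,
        actor: str = "system",
    ) -> AdverseEvent:
        """Create a new ongoing AE episode; duplicates of an ongoing term
        are rejected naming the blocking AE (deduplication rule)."""
        self._require_enrolled(participant_id, study_id)
        catalog = self._catalog_for(study_id)
        catalog.get(term_id)  # raises for unknown terms
        if grade not in (1, 2, 3, 4, 5):
            raise LifecycleError(f"AE grade must be 1-5, got {grade}")
        blocking = self._ongoing_with_term(participant_id, study_id, term_id)
        if blocking is not None:
            raise DuplicateOngoingAeError(
                f"term {term_id!r} already ongoing for {participant_id}/{study_id} "
                f"as {blocking.ae_id}",
                blocking_ae_id=blocking.ae_id,
            )
        ae = AdverseEvent(
            ae_id=self._next_id("ae", "AE"),
            participant_id=participant_id,
            study_id=study_id,
            term_id=term_id,
            status="ongoing",
            current_grade=grade,
            onset_date=onset_date,
            source=source,
            created_at=self.now(),
            attribution=attribution,
            history=[HistoryEntry(onset_date, grade, "ongoing", actor)],
        )
        self.aes[ae.ae_id] = ae
        return ae

    # -- visit assessment -----------------------------------------------
    def open_visit_assessment(
        self, participant_id: str, study_id: str
    ) -> VisitAssessment:
        """Open an assessment pre-populated with every ongoing AE, all
        initially unevaluated.  One open assessment per participant+study."""
        self._require_enrolled(participant_id, study_id)
        for a in self.assessments.values():
            if (
                a.participant_id == participant_id
                and a.study_id == study_id
                and a.state == "open"
            ):
                raise LifecycleError(
                    f"assessment {a.assessment_id} is already open for "
                    f"{participant_id}/{study_id}"
                )
        assessment = VisitAssessment(
            assessment_id=self._next_id("assessment", "VA"),
            participant_id=participant_id,
            study_id=study_id,
            created_at=self.now(),
            evaluations={ae.ae_id: None for ae in self.ongoing_aes(participant_id, study_id)},
        )
        self.assessments[assessment.assessment_id] = assessment
        return assessment

    def pending_items(self, assessment_id: str) -> list[str]:
        """Ongoing AEs not yet evaluated in this open assessment (the
        "red frame" list)."""
        assessment = self._get_assessment(assessment_id, require_open=True)
        return [ae_id for ae_id, ev in assessment.evaluations.items() if ev is None]

    def _get_assessment(
        self, assessment_id: str, require_open: bool = False
    ) -> VisitAssessment:
        assessment = self.assessments.get(assessment_id)
        if assessment is None:
            raise LifecycleError(f"unknown assessment {assessment_id!r}")
        if require_open and assessment.state != "open":
            raise LifecycleError(f"assessment {assessment_id} is finalized")
        return assessment

    def evaluate_ae(
        self,
        assessment_id: str,
        ae_id: str,
        decision: Status,
        grade: int,
        when: date,
        actor: str = "nurse",
    ) -> VisitAssessment:
        """Record one AE's evaluation; re-evaluation overwrites (last write
        wins) while the full history of evaluations is kept."""
        assessment = self._get_assessment(assessment_id, require_open=True)
        if ae_id not in assessment.evaluations:
            raise LifecycleError(
                f"AE {ae_id!r} does not belong to assessment {assessment_id}"
            )
        if decision not in ("ongoing", "resolved"):
            raise LifecycleError(f"decision must be ongoing/resolved, got {decision!r}")
        if grade not in (0, 1, 2, 3, 4, 5):
            raise LifecycleError(f"grade must be 0-5, got {grade}")
        evaluation = Evaluation(decision=decision, grade=grade, date=when, actor=actor)
        assessment.evaluations[ae_id] = evaluation
        assessment.evaluation_history.append((ae_id, evaluation))
        return assessment

    def add_new_ae(
        self,
        assessment_id: str,
        term_id: str,
        grade: int,
        onset_date: date,
        attribution: Optional[tuple[str, str]] = None,
        actor: str = "nurse",
    ) -> AdverseEvent:
        """Create a new office-visit AE within an open assessment."""
        assessment = self._get_assessment(assessment_id, require_open=True)
        ae = self.create_ae(
            assessment.participant_id,
            assessment.study_id,
            term_id,
            grade,
            onset_date,
            source="office_visit",
            attribution=attribution,
            actor=actor,
        )
        assessment.new_aes.append(ae.ae_id)
        return ae

    def finalize_assessment(
        self, assessment_id: str, provider: str, csn: str
    ) -> tuple[VisitAssessment, reporting.AeDocument]:
        """Apply all evaluations atomically, bind the encounter CSN, and
        generate the signed office-visit AE document.

        Rejected while any ongoing AE is unevaluated, when the CSN does not
        belong to this participant, or when the user lacks provider
        authorization on the study.
        """
        assessment = self._get_assessment(assessment_id, require_open=True)
        try:
            allowed = self.registry.check_access(provider, assessment.study_id, "finalize")
        except RegistryError as exc:
            raise UnauthorizedError(str(exc)) from None
        if not allowed:
            raise UnauthorizedError(
                f"user {provider!r} may not finalize assessments on "
                f"{assessment.study_id!r}"
            )
        encounter = self.registry.encounters.get(csn)
        if encounter is None or encounter.participant_id != assessment.participant_id:
            raise LifecycleError(
                f"CSN {csn!r} does not identify an encounter of participant "
                f"{assessment.participant_id!r}"
            )
        pending = self.pending_items(assessment_id)
        if pending:
            raise IncompleteAssessmentError(
                f"assessment {assessment_id} has unevaluated ongoing AEs: "
                f"{', '.join(pending)}",
                pending=pending,
            )
        # validate every evaluation up front so the commit cannot half-apply
        for ae_id, evaluation in assessment.evaluations.items():
            ae = self.aes[ae_id]
            assert evaluation is not None
            if evaluation.decision == "resolved" and evaluation.date < ae.onset_date:
                raise LifecycleError(
                    f"AE {ae_id}: resolution date {evaluation.date} precedes "
                    f"onset {ae.onset_date}"
                )
        snapshot = {ae_id: copy.deepcopy(self.aes[ae_id]) for ae_id in assessment.evaluations}
        try:
            for ae_id, evaluation in assessment.evaluations.items():
                ae = self.aes[ae_id]
                assert evaluation is not None
                ae.history.append(
                    HistoryEntry(evaluation.date, evaluation.grade,
                                 evaluation.decision, evaluation.actor)
                )
                ae.current_grade = evaluation.grade
                ae.status = evaluation.decision
                ae.resolution_date = (
                    evaluation.date if evaluation.decision == "resolved" else None
                )
                ae.signed = True
        except Exception:
            self.aes.update(snapshot)
            raise
        assessment.state = "finalized"
        assessment.csn = csn
        assessment.finalized_by = provider
        catalog = self._catalog_for(assessment.study_id)
        entries = []
        for ae_id in list(assessment.evaluations) + assessment.new_aes:
            ae = self.aes[ae_id]
            term = catalog.get(ae.term_id)
            evaluation = assessment.evaluations.get(ae_id)
            entries.append(
                reporting.AeEntry(
                    ae_id=ae.ae_id,
                    term_name=term.name,
                    category=term.category,
                    meddra_code=term.meddra_code,
                    grade=ae.current_grade,
                    status=ae.status,
                    assessment_date=evaluation.date if evaluation else ae.onset_date,
                    attribution=ae.attribution,
                    source=ae.source,
                )
            )
        document = reporting.generate_ae_document(
            assessment,
            provider,
            csn,
            entries=entries,
            document_id=self._next_id("doc", "DOC"),
            created_at=self.now(),
        )
        document = reporting.sign_document(document, provider)
        return assessment, document

    # -- lab AEs --------------------------------------------------------
    def ingest_graded_labs(
        self, items: Iterable[Union[BoundGraded, tuple]]
    ) -> LabIngestReport:
        """Turn graded, study-bound lab results into lab-source AEs.

        Grade >=1 results create a new unsigned lab AE, or update the grade
        of an ongoing same-term AE (one AE per episode, never a duplicate).
        Grade-0 and out-of-range-ungradeable results are retained in the
        report but create no AE.  Per-item failures never abort the batch.
        """
        report = LabIngestReport()
        touched: dict[tuple[str, str], list[str]] = {}
        for item in items:
            bound = item if isinstance(item, BoundGraded) else BoundGraded(*item)
            graded = bound.graded
            grade = graded.effective_grade
            if (
                grade is None
                or grade == 0
                or graded.ae_term_id is None
            ):
                report.retained.append(bound)
                continue
            observed = getattr(graded.source, "observed_at", None)
            onset = observed.date() if observed is not None else self.now().date()
            existing = self._ongoing_with_term(
                bound.participant_id, bound.study_id, graded.ae_term_id
            )
            if existing is not None:
                # lab messages may arrive out of order; the grade change is
                # recorded no earlier than the last history entry
                entry_date = max(onset, existing.history[-1].date)
                existing.history.append(
                    HistoryEntry(entry_date, grade, "ongoing", "lab")
                )
                existing.current_grade = grade
                report.updated.append(existing.ae_id)
                key = (bound.participant_id, bound.study_id)
                touched.setdefault(key, []).append(existing.ae_id)
            else:
                ae = self.create_ae(
                    bound.participant_id,
                    bound.study_id,
                    graded.ae_term_id,
                    grade,
                    onset,
                    source="lab",
                    actor="lab",
                )
                ae.signed = False
                report.created.append(ae.ae_id)
                key = (bound.participant_id, bound.study_id)
                touched.setdefault(key, []).append(ae.ae_id)
        for (participant_id, study_id), ae_ids in sorted(touched.items()):
            catalog = self._catalog_for(study_id)
            entries = []
            for ae_id in dict.fromkeys(ae_ids):  # dedupe, order-preserving
                ae = self.aes[ae_id]
                term = catalog.get(ae.term_id)
                entries.append(
                    reporting.AeEntry(
                        ae_id=ae.ae_id,
                        term_name=term.name,
                        category=term.category,
                        meddra_code=term.meddra_code,
                        grade=ae.current_grade,
                        status=ae.status,
                        assessment_date=ae.history[-1].date,
                        attribution=ae.attribution,
                        source="lab",
                    )
                )
            batch = reporting.LabBatch(
                participant_id=participant_id,
                study_id=study_id,
                entries=tuple(entries),
                created_at=self.now(),
            )
            document = reporting.generate_ae_document(
                batch, provider="", csn="",
                document_id=self._next_id("doc", "LD"),
                created_at=self.now(),
            )
            self.lab_documents[document.document_id] = document
            self._lab_document_study[document.document_id] = study_id
            report.documents.append(document.document_id)
        return report

    def sign_lab_document(self, document_id: str, provider: str) -> reporting.AeDocument:
        """Provider signature on a pending lab-based AE document."""
        document = self.lab_documents.get(document_id)
        if document is None:
            raise LifecycleError(f"unknown lab document {document_id!r}")
        study_id = self._lab_document_study[document_id]
        try:
            allowed = self.registry.check_access(provider, study_id, "sign")
        except RegistryError as exc:
            raise UnauthorizedError(str(exc)) from None
        if not allowed:
            raise UnauthorizedError(
                f"user {provider!r} may not sign documents on {study_id!r}"
            )
        signed = reporting.sign_document(document, provider)
        self.lab_documents[document_id] = signed
        for _, entries in signed.groups:
            for entry in entries:
                if entry.ae_id in self.aes:
                    self.aes[entry.ae_id].signed = True
        return signed

    # -- reminders ------------------------------------------------------
    def _default_provider(self, study_id: str) -> str:
        providers = sorted(
            u.user_id
            for u in self.registry.personnel.values()
            if u.role == "provider" and study_id in u.authorized_studies
        )
        return providers[0] if providers else ""

    def due_reminders(self, now: datetime) -> list[Reminder]:
        """Reminders for items unfinalized/unsigned for more than the
        24-hour threshold at ``now``; idempotent within the re-reminder
        interval (calling twice at the same instant emits nothing new)."""
        reminders: list[Reminder] = []
        targets: list[tuple[str, str, str, datetime]] = []
        for a in self.assessments.values():
            if a.state == "open":
                targets.append(
                    ("assessment", a.assessment_id,
                     self._default_provider(a.study_id), a.created_at)
                )
        for doc_id, doc in self.lab_documents.items():
            if not doc.signed:
                targets.append(
                    ("lab_document", doc_id,
                     self._default_provider(self._lab_document_study[doc_id]),
                     doc.created_at)
                )
        for kind, target_id, provider, created_at in sorted(
            targets, key=lambda t: (t[0], t[1])
        ):
            if now - created_at <= self.reminder_threshold:
                continue
            last = self._reminder_log.get(target_id)
            if last is not None and now - last < self.re_reminder_interval:
                continue
            reminders.append(
                Reminder(
                    target_id=target_id,
                    target_kind=kind,  # type: ignore[arg-type]
                    provider=provider,
                    due_since=created_at + self.reminder_threshold,
                    emitted_at=now,
                )
            )
            self._reminder_log[target_id] = now
        return reminders

    # -- invariants ------------------------------------------------------
    def check_invariants(self) -> None:
        """Raise if any lifecycle invariant is violated (used heavily by
        property tests over random operation streams)."""
        seen_ongoing: set[tuple[str, str, str]] = set()
        for ae in self.aes.values():
            if not ae.history:
                raise AssertionError(f"{ae.ae_id}: empty history")
            dates = [h.date for h in ae.history]
            if dates != sorted(dates):
                raise AssertionError(f"{ae.ae_id}: history not chronological")
            first = ae.history[0]
            if first.date != ae.onset_date:
                raise AssertionError(f"{ae.ae_id}: first history entry != onset")
            if ae.status == "resolved":
                if ae.resolution_date is None or ae.resolution_date < ae.onset_date:
                    raise AssertionError(
                        f"{ae.ae_id}: resolved without valid resolution_date"
                    )
            else:
                key = (ae.participant_id, ae.study_id, ae.term_id)
                if key in seen_ongoing:
                    raise AssertionError(f"duplicate ongoing AE for {key}")
                seen_ongoing.add(key)
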