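"""AE lifecycle: deduplication, assessment workflow, reminders, lab ingest."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from aecap.grading import batch_grade
from aecap.lifecycle import (
    BoundGraded,
    DuplicateOngoingAeError,
    IncompleteAssessmentError,
    LifecycleError,
    UnauthorizedError,
)
from conftest import T0, make_lab

D0 = date(2014, 3, 1)


class TestDedup:
    def test_new_term_creates_an_ongoing_ae(self, tracker):
        ae = tracker.create_ae("P1", "S1", "nausea", 1, D0)
        assert ae.status == "ongoing" and ae.history[0].grade == 1

    def test_ongoing_term_blocks_duplicate_and_names_blocker(self, tracker):
        first = tracker.create_ae("P1", "S1", "nausea", 1, D0)
        with pytest.raises(DuplicateOngoingAeError) as err:
            tracker.create_ae("P1", "S1", "nausea", 2, D0)
        assert err.value.blocking_ae_id == first.ae_id

    def test_dedup_applies_across_symptom_and_diagnosis_sources(self, tracker):
        # the rule holds whether the episode was documented from a visit or a lab
        first = tracker.create_ae("P1", "S1", "hypokalemia", 1, D0, source="lab")
        with pytest.raises(DuplicateOngoingAeError):
            tracker.create_ae("P1", "S1", "hypokalemia", 2, D0, source="office_visit")

    def test_resolved_term_may_recur_as_a_new_episode(self, tracker, registry):
        first = tracker.create_ae("P1", "S1", "nausea", 1, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        tracker.evaluate_ae(a.assessment_id, first.ae_id, "resolved", 0, date(2014, 3, 2))
        tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        second = tracker.create_ae("P1", "S1", "nausea", 2, date(2014, 3, 10))
        assert second.ae_id != first.ae_id
        assert tracker.aes[first.ae_id].status == "resolved"

    def test_same_term_on_another_study_is_independent(self, tracker):
        tracker.create_ae("P2", "S1", "nausea", 1, D0)
        tracker.create_ae("P2", "S2", "nausea", 1, D0)  # no error
        tracker.check_invariants()

    def test_unknown_term_and_bad_grade_rejected(self, tracker):
        with pytest.raises(Exception, match="unknown term"):
            tracker.create_ae("P1", "S1", "no_such_term", 1, D0)
        with pytest.raises(LifecycleError, match="grade"):
            tracker.create_ae("P1", "S1", "nausea", 7, D0)


class TestAssessment:
    def seed_three(self, tracker):
        for term in ("nausea", "vomiting", "diarrhea"):
            tracker.create_ae("P1", "S1", term, 1, D0)

    def test_opens_prepopulated_with_every_ongoing_ae(self, tracker):
        self.seed_three(tracker)
        a = tracker.open_visit_assessment("P1", "S1")
        assert len(a.evaluations) == 3
        assert all(ev is None for ev in a.evaluations.values())

    def test_no_ongoing_aes_gives_an_empty_but_valid_assessment(self, tracker):
        a = tracker.open_visit_assessment("P1", "S1")
        assert a.evaluations == {} and tracker.pending_items(a.assessment_id) == []

    def test_second_concurrent_open_assessment_rejected(self, tracker):
        tracker.open_visit_assessment("P1", "S1")
        with pytest.raises(LifecycleError, match="already open"):
            tracker.open_visit_assessment("P1", "S1")

    def test_pending_items_partition_the_ongoing_set(self, tracker):
        self.seed_three(tracker)
        a = tracker.open_visit_assessment("P1", "S1")
        ongoing = {ae.ae_id for ae in tracker.ongoing_aes("P1", "S1")}
        evaluated = sorted(ongoing)[:2]
        for ae_id in evaluated:
            tracker.evaluate_ae(a.assessment_id, ae_id, "ongoing", 1, date(2014, 3, 3))
        pending = tracker.pending_items(a.assessment_id)
        assert len(pending) == 1
        assert set(evaluated) | set(pending) == ongoing
        assert set(evaluated) & set(pending) == set()

    def test_reevaluation_overwrites_but_keeps_history(self, tracker):
        self.seed_three(tracker)
        a = tracker.open_visit_assessment("P1", "S1")
        ae_id = next(iter(a.evaluations))
        tracker.evaluate_ae(a.assessment_id, ae_id, "ongoing", 2, date(2014, 3, 3))
        tracker.evaluate_ae(a.assessment_id, ae_id, "resolved", 0, date(2014, 3, 3))
        assert a.evaluations[ae_id].decision == "resolved"
        assert len(a.evaluation_history) == 2

    def test_foreign_ae_rejected(self, tracker):
        tracker.create_ae("P2", "S2", "nausea", 1, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        foreign = next(iter(tracker.aes))
        with pytest.raises(LifecycleError, match="belong"):
            tracker.evaluate_ae(a.assessment_id, foreign, "ongoing", 1, D0)


class TestFinalize:
    def test_incomplete_assessment_rejected_listing_red_frame_items(self, tracker):
        for term in ("nausea", "vomiting"):
            tracker.create_ae("P1", "S1", term, 1, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        only = sorted(a.evaluations)[0]
        tracker.evaluate_ae(a.assessment_id, only, "ongoing", 1, date(2014, 3, 3))
        with pytest.raises(IncompleteAssessmentError) as err:
            tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        assert err.value.pending == tracker.pending_items(a.assessment_id)

    def test_nurse_cannot_finalize(self, tracker):
        a = tracker.open_visit_assessment("P1", "S1")
        with pytest.raises(UnauthorizedError):
            tracker.finalize_assessment(a.assessment_id, "rn_b", "CSN1")

    def test_csn_must_belong_to_the_participant(self, tracker):
        a = tracker.open_visit_assessment("P1", "S1")
        with pytest.raises(LifecycleError, match="CSN"):
            tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN2")

    def test_complete_finalization_applies_evaluations_and_signs(self, tracker):
        ae = tracker.create_ae("P1", "S1", "nausea", 1, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        tracker.evaluate_ae(a.assessment_id, ae.ae_id, "ongoing", 3, date(2014, 3, 3))
        finalized, document = tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        assert finalized.state == "finalized" and finalized.csn == "CSN1"
        assert tracker.aes[ae.ae_id].current_grade == 3
        assert len(tracker.aes[ae.ae_id].history) == 2
        assert document.signed and document.document_type == "office_visit_ae"
        with pytest.raises(LifecycleError, match="finalized"):
            tracker.evaluate_ae(a.assessment_id, ae.ae_id, "ongoing", 1, date(2014, 3, 4))

    def test_resolution_sets_status_and_date(self, tracker):
        ae = tracker.create_ae("P1", "S1", "nausea", 2, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        tracker.evaluate_ae(a.assessment_id, ae.ae_id, "resolved", 0, date(2014, 3, 3))
        tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        assert tracker.aes[ae.ae_id].status == "resolved"
        assert tracker.aes[ae.ae_id].resolution_date == date(2014, 3, 3)

    def test_atomicity_under_injected_failure(self, tracker, monkeypatch):
        """If the commit fails midway, no evaluation is applied at all."""
        ids = [
            tracker.create_ae("P1", "S1", term, 1, D0).ae_id
            for term in ("nausea", "vomiting", "diarrhea")
        ]
        a = tracker.open_visit_assessment("P1", "S1")
        for ae_id in ids:
            tracker.evaluate_ae(a.assessment_id, ae_id, "ongoing", 4, date(2014, 3, 3))
        before = {ae_id: tracker.aes[ae_id].current_grade for ae_id in ids}
        import aecap.lifecycle as lc

        real_entry = lc.HistoryEntry
        calls = {"n": 0}

        def failing_factory(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("injected failure")
            return real_entry(*args, **kwargs)

        monkeypatch.setattr(lc, "HistoryEntry", failing_factory)
        with pytest.raises(RuntimeError):
            tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        monkeypatch.undo()
        after = {ae_id: tracker.aes[ae_id].current_grade for ae_id in ids}
        assert after == before
        assert all(len(tracker.aes[i].history) == 1 for i in ids)
        assert tracker.assessments[a.assessment_id].state == "open"


class TestLabIngest:
    def graded_for(self, value, rules, ranges, catalog, **kw):
        graded, _ = batch_grade([make_lab(value, **kw)], rules, ranges, catalog)
        return graded[0]

    def test_grade1_result_creates_unsigned_lab_ae(self, tracker, rules, ranges, catalog):
        g = self.graded_for(3.3, rules, ranges, catalog)
        report = tracker.ingest_graded_labs([BoundGraded(g, "P1", "S1")])
        assert len(report.created) == 1
        ae = tracker.aes[report.created[0]]
        assert ae.source == "lab" and not ae.signed and ae.term_id == "hypokalemia"
        assert len(report.documents) == 1
        assert not tracker.lab_documents[report.documents[0]].signed

    def test_repeat_abnormal_updates_grade_instead_of_duplicating(
        self, tracker, rules, ranges, catalog
    ):
        g1 = self.graded_for(3.3, rules, ranges, catalog)
        g2 = self.graded_for(2.4, rules, ranges, catalog)
        r1 = tracker.ingest_graded_labs([BoundGraded(g1, "P1", "S1")])
        r2 = tracker.ingest_graded_labs([BoundGraded(g2, "P1", "S1")])
        assert r2.created == [] and r2.updated == r1.created
        ae = tracker.aes[r1.created[0]]
        assert ae.current_grade == 4 and len(ae.history) == 2
        tracker.check_invariants()

    def test_grade0_and_ungradeable_results_are_retained_without_ae(
        self, tracker, rules, ranges, catalog
    ):
        normal = self.graded_for(4.2, rules, ranges, catalog)
        mismatched = self.graded_for(3.3, rules, ranges, catalog, unit="mg/dL")
        report = tracker.ingest_graded_labs(
            [BoundGraded(normal, "P1", "S1"), BoundGraded(mismatched, "P1", "S1")]
        )
        assert report.created == [] and len(report.retained) == 2
        assert tracker.aes == {}

    def test_provider_signature_marks_document_and_aes(self, tracker, rules, ranges, catalog):
        g = self.graded_for(3.3, rules, ranges, catalog)
        report = tracker.ingest_graded_labs([BoundGraded(g, "P1", "S1")])
        doc = tracker.sign_lab_document(report.documents[0], "dr_a")
        assert doc.signed
        assert tracker.aes[report.created[0]].signed
        with pytest.raises(UnauthorizedError):
            tracker.sign_lab_document(report.documents[0], "rn_b")


class TestReminders:
    def test_25h_old_assessment_triggers_and_23h_does_not(self, tracker):
        tracker.open_visit_assessment("P1", "S1")
        assert tracker.due_reminders(T0 + timedelta(hours=23)) == []
        due = tracker.due_reminders(T0 + timedelta(hours=25))
        assert len(due) == 1
        assert due[0].target_kind == "assessment"
        assert due[0].due_since == T0 + timedelta(hours=24)

    def test_repeated_call_at_same_instant_is_idempotent(self, tracker):
        tracker.open_visit_assessment("P1", "S1")
        now = T0 + timedelta(hours=25)
        assert len(tracker.due_reminders(now)) == 1
        assert tracker.due_reminders(now) == []

    def test_re_reminder_after_interval_elapses(self, tracker):
        tracker.open_visit_assessment("P1", "S1")
        assert len(tracker.due_reminders(T0 + timedelta(hours=25))) == 1
        assert tracker.due_reminders(T0 + timedelta(hours=30)) == []
        assert len(tracker.due_reminders(T0 + timedelta(hours=50))) == 1

    def test_unsigned_lab_documents_also_remind(self, tracker, rules, ranges, catalog):
        graded, _ = batch_grade([make_lab(3.3)], rules, ranges, catalog)
        tracker.ingest_graded_labs([BoundGraded(graded[0], "P1", "S1")])
        due = tracker.due_reminders(T0 + timedelta(hours=25))
        assert [r.target_kind for r in due] == ["lab_document"]
        assert due[0].provider == "dr_a"

    def test_finalized_assessments_never_remind(self, tracker):
        ae = tracker.create_ae("P1", "S1", "nausea", 1, D0)
        a = tracker.open_visit_assessment("P1", "S1")
        tracker.evaluate_ae(a.assessment_id, ae.ae_id, "ongoing", 1, date(2014, 3, 3))
        tracker.finalize_assessment(a.assessment_id, "dr_a", "CSN1")
        assert tracker.due_reminders(T0 + timedelta(days=10)) == []


class TestRandomOperationStreams:
    def test_invariants_hold_over_randomized_operations(self, registry, catalog, clock):
        """Dedup and history invariants under a random mix of lifecycle
        operations (seeded; the larger end-to-end stream runs in the
        acceptance suite)."""
        from aecap.lifecycle import AeTracker

        rng = np.random.default_rng(1234)
        tracker = AeTracker(registry, catalog, clock)
        run_random_ops(tracker, registry, catalog, rng, n_ops=1500, check_every=100)
        tracker.check_invariants()


def run_random_ops(tracker, registry, catalog, rng, n_ops, check_every):
    """Shared random-operation driver (also used by the acceptance suite)."""
    pairs = [
        (p.participant_id, s)
        for p in registry.participants.values()
        for s in p.enrolled_studies
    ]
    terms = sorted(t.term_id for t in catalog)
    day = [date(2014, 3, 1)]
    for i in range(n_ops):
        op = rng.integers(0, 5)
        participant_id, study_id = pairs[int(rng.integers(len(pairs)))]
        if int(rng.integers(0, 3)) == 0:
            day[0] = day[0] + timedelta(days=1)
        try:
            if op == 0:
                tracker.create_ae(
                    participant_id, study_id,
                    terms[int(rng.integers(len(terms)))],
                    int(rng.integers(1, 5)), day[0],
                )
            elif op == 1:
                tracker.open_visit_assessment(participant_id, study_id)
            elif op == 2:
                open_assessments = [
                    a for a in tracker.assessments.values() if a.state == "open"
                ]
                if open_assessments:
                    a = open_assessments[int(rng.integers(len(open_assessments)))]
                    if a.evaluations:
                        ae_id = sorted(a.evaluations)[
                            int(rng.integers(len(a.evaluations)))
                        ]
                        decision = "resolved" if rng.random() < 0.4 else "ongoing"
                        tracker.evaluate_ae(
                            a.assessment_id, ae_id, decision,
                            int(rng.integers(0, 5)), day[0],
                        )
            elif op == 3:
                open_assessments = [
                    a for a in tracker.assessments.values() if a.state == "open"
                ]
                if open_assessments:
                    a = open_assessments[int(rng.integers(len(open_assessments)))]
                    providers = sorted(
                        u.user_id for u in registry.personnel.values()
                        if u.role == "provider" and a.study_id in u.authorized_studies
                    )
                    encounters = registry.encounters_for(a.participant_id)
                    if providers and encounters:
                        tracker.finalize_assessment(
                            a.assessment_id, providers[0], encounters[0].csn
                        )
            else:
                from aecap.grading import GradedResult

                term_id = terms[int(rng.integers(len(terms)))]
                term = catalog.get(term_id)
                grade = int(rng.integers(1, 5))
                graded = GradedResult(
                    source=None, direction="low", numeric_grade=grade,
                    ae_term_id=term_id, meddra_code=term.meddra_code or 1,
                    out_of_range=True,
                )
                tracker.ingest_graded_labs(
                    [BoundGraded(graded, participant_id, study_id)]
                )
        except (LifecycleError, DuplicateOngoingAeError):
            pass  # rejected operations must leave the state untouched
        if (i + 1) % check_every == 0:
            tracker.check_invariants()
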