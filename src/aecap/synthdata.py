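"""Seed-deterministic synthetic registries, lab streams, and visit scenarios.

The generator emulates the input side of a trial-safety capture system:
a participant registry with studies, personnel, and encounters; a stream
of HL7 ORU-R01 lab-result messages mixing normal and abnormal values; and
visit scenarios with pre-existing ongoing AEs.

Generation is *truth-table first*: for each synthetic lab result the
intended direction and CTCAE grade are sampled first, then a value is
drawn strictly inside the corresponding severity band (or inside the
normal range for grade 0).  The emitted truth table therefore gives the
exact expected grade for every observation, so end-to-end validation of
the grading pipeline is exact rather than statistical.

A single seed drives everything; independent sub-streams are split off
per purpose (registry / labs / visits) so adding results does not perturb
the registry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog
from .grading import Band, GradingRule, ReferenceRange, RuleSet, LLN, ULN
from .hl7io import LabResult, render_oru
from .registry import Participant, Personnel, Registry, Study

__all__ = ["SimConfig", "gen_registry", "gen_lab_stream", "gen_visit_scenarios",
           "VisitScenario"]

_AGENT_NAMES = (
    "pembrolizumab", "carboplatin", "paclitaxel", "lenalidomide",
    "bortezomib", "nivolumab", "doxorubicin", "cyclophosphamide",
)

_EPOCH = datetime(2014, 3, 3, 8, 0, 0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    ``abnormal_rate`` is the per-result probability of an out-of-range
    value; ``severity_mix`` weights the target grade of abnormal results
    (renormalized over the grades a chosen rule actually defines);
    ``ongoing_ae_rate`` is the per-participant probability of entering a
    visit with pre-existing ongoing AEs.
    """

    seed: int = 0
    n_participants: int = 20
    n_studies: int = 3
    lab_panel: Optional[tuple[str, ...]] = None  # None = all rule-covered labs
    abnormal_rate: float = 0.3
    severity_mix: tuple[tuple[int, float], ...] = (
        (1, 0.4), (2, 0.25), (3, 0.2), (4, 0.15),
    )
    visits_per_participant: int = 2
    ongoing_ae_rate: float = 0.5
    results_per_participant: int = 10

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_studies <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.abnormal_rate <= 1.0:
            raise ValueError("abnormal_rate must be in [0, 1]")
        if not 0.0 <= self.ongoing_ae_rate <= 1.0:
            raise ValueError("ongoing_ae_rate must be in [0, 1]")
        if any(w < 0 for _, w in self.severity_mix) or not any(
            w > 0 for _, w in self.severity_mix
        ):
            raise ValueError("severity_mix weights must be non-negative, not all zero")


def _rng_streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_registry(config: SimConfig) -> Registry:
    """Synthesize studies, participants, personnel, and encounters.

    MRNs and CSNs are unique; each study gets a provider, a nurse, and a
    coordinator; each participant is enrolled in one or (occasionally)
    two studies and has ``visits_per_participant`` encounters.
    """
    rng = _rng_streams(config.seed)[0]
    registry = Registry()
    for i in range(config.n_studies):
        agent = _AGENT_NAMES[i % len(_AGENT_NAMES)]
        registry.add_study(
            Study(
                study_id=f"S{i + 1:03d}",
                title=f"Synthetic phase II trial of {agent}",
                agents=(agent,),
                interventional=True,
                ctcae_version=4,
            )
        )
    study_ids = list(registry.studies)
    for uid in study_ids:
        registry.add_personnel(Personnel(f"dr_{uid.lower()}", "provider", (uid,)))
        registry.add_personnel(Personnel(f"rn_{uid.lower()}", "nurse", (uid,)))
        registry.add_personnel(Personnel(f"cc_{uid.lower()}", "coordinator", (uid,)))
    mrns: list[str] = []
    seen: set[int] = set()
    while len(mrns) < config.n_participants:
        m = int(rng.integers(10_000_000, 100_000_000))
        if m not in seen:
            seen.add(m)
            mrns.append(str(m))
    for i in range(config.n_participants):
        primary = study_ids[int(rng.integers(len(study_ids)))]
        enrolled = [primary]
        if len(study_ids) > 1 and rng.random() < 0.15:
            others = [s for s in study_ids if s != primary]
            enrolled.append(others[int(rng.integers(len(others)))])
        registry.add_participant(
            Participant(
                participant_id=f"P{i + 1:04d}",
                mrn=mrns[i],
                enrolled_studies=tuple(enrolled),
            )
        )
    csn = 0
    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        for v in range(config.visits_per_participant):
            csn += 1
            registry.record_encounter(
                pid, f"CSN{csn:06d}", (_EPOCH + timedelta(days=14 * v)).date()
            )
    return registry


def _resolve_band_interval(
    band: Band, rule: GradingRule, range_: ReferenceRange
) -> tuple[float, float, bool, bool]:
    """Numeric (lo, hi, lo_open, hi_open) for a band, truncating the
    unbounded severe side to a finite sampling window."""
    def num(bound, default):
        if bound is None:
            return default
        if bound == LLN:
            return range_.lln
        if bound == ULN:
            return range_.uln
        return float(bound)

    if rule.direction == "low":
        hi = num(band.upper, range_.lln)
        lo = num(band.lower, None)
        if lo is None:
            lo = max(0.0, hi - max(abs(hi) * 0.5, 1.0))
        return lo, hi, False, True  # [lo, hi)
    lo = num(band.lower, range_.uln)
    hi = num(band.upper, None)
    if hi is None:
        hi = lo + max(abs(lo) * 0.5, 1.0)
    return lo, hi, True, False  # (lo, hi]


def _sample_in(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Draw strictly inside (lo, hi) with a margin wide enough that
    rounding to 3 decimals cannot land on a boundary."""
    span = hi - lo
    eps = max(span * 0.05, 0.002)
    value = rng.uniform(lo + eps, hi - eps)
    return round(float(value), 3)


def gen_lab_stream(
    config: SimConfig,
    registry: Registry,
    rules: RuleSet,
    ranges: dict[str, ReferenceRange],
    n_results: Optional[int] = None,
) -> tuple[str, pd.DataFrame]:
    """Generate an HL7 ORU file plus its truth table.

    Returns ``(hl7_text, truth)`` where ``truth`` has one row per OBX with
    the intended ``direction`` and ``grade``.  Results are batched into one
    ORU-R01 message per participant draw (up to 5 OBX per message).
    """
    rng = _rng_streams(config.seed)[1]
    panel = tuple(config.lab_panel) if config.lab_panel else tuple(sorted(rules.lab_types))
    unknown = [lt for lt in panel if lt not in ranges]
    if unknown:
        raise ValueError(f"lab panel entries without reference ranges: {unknown}")
    if n_results is None:
        n_results = config.results_per_participant * config.n_participants
    participants = sorted(registry.participants.values(), key=lambda p: p.participant_id)
    if not participants:
        raise ValueError("registry has no participants")

    truth_rows: list[dict] = []
    messages: list[str] = []
    msg_no = 0
    produced = 0
    while produced < n_results:
        participant = participants[int(rng.integers(len(participants)))]
        batch = int(min(rng.integers(1, 6), n_results - produced))
        msg_no += 1
        message_id = f"MSG{msg_no:06d}"
        observed = _EPOCH + timedelta(hours=int(rng.integers(0, 24 * 365)))
        results = []
        for _ in range(batch):
            lab_type = panel[int(rng.integers(len(panel)))]
            range_ = ranges[lab_type]
            lab_rules = rules.for_lab(lab_type)
            abnormal = bool(rng.random() < config.abnormal_rate) and bool(lab_rules)
            if not abnormal:
                value = _sample_in(rng, range_.lln, range_.uln)
                direction, grade = "normal", 0
            else:
                rule = lab_rules[int(rng.integers(len(lab_rules)))]
                grades = [b.grade for b in rule.bands]
                weights = np.array(
                    [dict(config.severity_mix).get(g, 0.0) for g in grades]
                )
                if weights.sum() == 0:
                    weights = np.ones(len(grades))
                band = rule.bands[int(rng.choice(len(grades), p=weights / weights.sum()))]
                lo, hi, _, _ = _resolve_band_interval(band, rule, range_)
                value = _sample_in(rng, lo, hi)
                direction, grade = rule.direction, band.grade
            results.append(
                LabResult(
                    message_id=message_id,
                    patient_id=participant.mrn,
                    lab_type=lab_type,
                    value=value,
                    unit=range_.unit,
                    observed_at=observed,
                    reference_range=(range_.lln, range_.uln),
                )
            )
            truth_rows.append(
                {
                    "message_id": message_id,
                    "obx_index": len(results),
                    "mrn": participant.mrn,
                    "participant_id": participant.participant_id,
                    "lab_type": lab_type,
                    "value": value,
                    "unit": range_.unit,
                    "direction": direction,
                    "grade": grade,
                }
            )
            produced += 1
        messages.append(render_oru(results))
    truth = pd.DataFrame(truth_rows)
    return "".join(m + "\n" for m in messages), truth


@dataclass(frozen=True)
class AeSeed:
    """Specification of one pre-existing ongoing AE."""

    participant_id: str
    study_id: str
    term_id: str
    grade: int
    onset_date: date


@dataclass(frozen=True)
class VisitScenario:
    """Pre-existing AEs plus the assessment schedule they feed."""

    preexisting: tuple[AeSeed, ...]
    schedule: tuple[tuple[str, str, str], ...]  # (participant, study, csn)


def gen_visit_scenarios(
    config: SimConfig, registry: Registry, catalog: Catalog
) -> VisitScenario:
    """Pre-existing ongoing AEs (distinct terms per participant+study, so
    the one-ongoing-per-term rule holds) and a visit schedule over real
    encounters."""
    rng = _rng_streams(config.seed)[2]
    term_ids = sorted(t.term_id for t in catalog)
    seeds: list[AeSeed] = []
    schedule: list[tuple[str, str, str]] = []
    for participant in sorted(registry.participants.values(),
                              key=lambda p: p.participant_id):
        encounters = registry.encounters_for(participant.participant_id)
        for study_id in participant.enrolled_studies:
            if rng.random() < config.ongoing_ae_rate:
                n_aes = int(rng.integers(1, 4))
                chosen = rng.choice(len(term_ids), size=min(n_aes, len(term_ids)),
                                    replace=False)
                for idx in sorted(int(i) for i in chosen):
                    seeds.append(
                        AeSeed(
                            participant_id=participant.participant_id,
                            study_id=study_id,
                            term_id=term_ids[idx],
                            grade=int(rng.integers(1, 4)),
                            onset_date=(_EPOCH - timedelta(days=int(rng.integers(5, 60)))).date(),
                        )
                    )
            for encounter in encounters:
                schedule.append((participant.participant_id, study_id, encounter.csn))
    return VisitScenario(preexisting=tuple(seeds), schedule=tuple(schedule))


def apply_scenario(tracker, scenario: VisitScenario) -> list:
    """Create the scenario's pre-existing AEs through a tracker."""
    return [
        tracker.create_ae(
            s.participant_id, s.study_id, s.term_id, s.grade, s.onset_date,
            source="office_visit", actor="seed",
        )
        for s in scenario.preexisting
    ]
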