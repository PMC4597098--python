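"""Trial registry: studies, participants, personnel, and encounters.

A minimal stand-in for the participant-registry and protocol-management
services an academic cancer center runs around its adverse-event capture
system: studies with their investigational agents and CTCAE version,
participants keyed by medical record number (MRN), personnel with
study-level authorization, and encounters identified by a unique Customer
Serial Number (CSN) used to route AE documentation into the correct
progress note.

Access control is deny-by-default: an action on a study is allowed only
for personnel explicitly authorized on that study, and finalizing or
signing additionally requires the provider role.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

__all__ = [
    "RegistryError",
    "Study",
    "Participant",
    "Personnel",
    "Encounter",
    "Registry",
    "load_registry",
    "save_registry",
]

Role = Literal["provider", "nurse", "coordinator"]
PROVIDER_ONLY_ACTIONS = frozenset({"finalize", "sign"})


class RegistryError(ValueError):
    """Raised for registry integrity violations and unknown entities."""


@dataclass(frozen=True)
class Study:
    study_id: str
    title: str
    agents: tuple[str, ...] = ()
    interventional: bool = True
    ctcae_version: int = 4

    def __post_init__(self) -> None:
        if self.interventional and not self.agents:
            raise RegistryError(
                f"interventional study {self.study_id!r} must list >=1 agent"
            )
        if self.ctcae_version not in (3, 4):
            raise RegistryError(f"study {self.study_id!r}: ctcae_version must be 3 or 4")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    mrn: str
    enrolled_studies: tuple[str, ...] = ()


@dataclass(frozen=True)
class Personnel:
    user_id: str
    role: Role
    authorized_studies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("provider", "nurse", "coordinator"):
            raise RegistryError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class Encounter:
    csn: str
    participant_id: str
    date: date


class Registry:
    """In-memory registry with referential-integrity checks on insert."""

    def __init__(self) -> None:
        self.studies: dict[str, Study] = {}
        self.participants: dict[str, Participant] = {}
        self.personnel: dict[str, Personnel] = {}
        self.encounters: dict[str, Encounter] = {}
        self._mrn_index: dict[str, str] = {}

    # -- population ----------------------------------------------------
    def add_study(self, study: Study) -> None:
        if study.study_id in self.studies:
            raise RegistryError(f"duplicate study_id {study.study_id!r}")
        self.studies[study.study_id] = study

    def add_participant(self, participant: Participant) -> None:
        mrn = participant.mrn.strip()
        if not mrn:
            raise RegistryError("participant MRN must be non-empty")
        if mrn in self._mrn_index:
            raise RegistryError(f"duplicate MRN {mrn!r}")
        if participant.participant_id in self.participants:
            raise RegistryError(f"duplicate participant_id {participant.participant_id!r}")
        for sid in participant.enrolled_studies:
            if sid not in self.studies:
                raise RegistryError(
                    f"participant {participant.participant_id!r} enrolled in "
                    f"unknown study {sid!r}"
                )
        self.participants[participant.participant_id] = participant
        self._mrn_index[mrn] = participant.participant_id

    def add_personnel(self, person: Personnel) -> None:
        if person.user_id in self.personnel:
            raise RegistryError(f"duplicate user_id {person.user_id!r}")
        for sid in person.authorized_studies:
            if sid not in self.studies:
                raise RegistryError(
                    f"user {person.user_id!r} authorized on unknown study {sid!r}"
                )
        self.personnel[person.user_id] = person

    # -- operations -----------------------------------------------------
    def check_access(self, user_id: str, study_id: str, action: str) -> bool:
        """Allow iff the user is authorized on the study; finalize/sign
        actions additionally require the provider role.  Deny-by-default."""
        if user_id not in self.personnel:
            raise RegistryError(f"unknown user {user_id!r}")
        user = self.personnel[user_id]
        if study_id not in user.authorized_studies:
            return False
        if action in PROVIDER_ONLY_ACTIONS and user.role != "provider":
            return False
        return True

    def lookup_by_mrn(self, mrn: str) -> Optional[Participant]:
        """Exact-match MRN lookup after whitespace trim; None when absent."""
        pid = self._mrn_index.get(mrn.strip())
        return self.participants.get(pid) if pid else None

    def record_encounter(
        self, participant_id: str, csn: str, when: Union[date, datetime, str]
    ) -> Encounter:
        if participant_id not in self.participants:
            raise RegistryError(f"unknown participant {participant_id!r}")
        if csn in self.encounters:
            raise RegistryError(f"duplicate CSN {csn!r}")
        if isinstance(when, str):
            when = date.fromisoformat(when)
        elif isinstance(when, datetime):
            when = when.date()
        encounter = Encounter(csn=csn, participant_id=participant_id, date=when)
        self.encounters[csn] = encounter
        return encounter

    def encounters_for(self, participant_id: str) -> list[Encounter]:
        return sorted(
            (e for e in self.encounters.values() if e.participant_id == participant_id),
            key=lambda e: (e.date, e.csn),
        )

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "studies": [asdict(s) for s in self.studies.values()],
            "participants": [asdict(p) for p in self.participants.values()],
            "personnel": [asdict(p) for p in self.personnel.values()],
            "encounters": [
                {"csn": e.csn, "participant_id": e.participant_id,
                 "date": e.date.isoformat()}
                for e in self.encounters.values()
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Registry":
        reg = cls()
        for s in payload.get("studies", []):
            reg.add_study(Study(
                study_id=s["study_id"], title=s["title"],
                agents=tuple(s.get("agents", ())),
                interventional=bool(s.get("interventional", True)),
                ctcae_version=int(s.get("ctcae_version", 4)),
            ))
        for p in payload.get("participants", []):
            reg.add_participant(Participant(
                participant_id=p["participant_id"], mrn=p["mrn"],
                enrolled_studies=tuple(p.get("enrolled_studies", ())),
            ))
        for p in payload.get("personnel", []):
            reg.add_personnel(Personnel(
                user_id=p["user_id"], role=p["role"],
                authorized_studies=tuple(p.get("authorized_studies", ())),
            ))
        for e in payload.get("encounters", []):
            reg.record_encounter(e["participant_id"], e["csn"], e["date"])
        return reg


_BUNDLE_FILES = ("studies.csv", "participants.csv", "personnel.csv", "encounters.csv")


def save_registry(registry: Registry, directory: Union[str, Path]) -> None:
    """Write the CSV bundle (studies/participants/personnel/encounters)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with (d / "studies.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["study_id", "title", "agents", "interventional", "ctcae_version"])
        for s in registry.studies.values():
            w.writerow([s.study_id, s.title, ";".join(s.agents),
                        int(s.interventional), s.ctcae_version])
    with (d / "participants.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "mrn", "enrolled_studies"])
        for p in registry.participants.values():
            w.writerow([p.participant_id, p.mrn, ";".join(p.enrolled_studies)])
    with (d / "personnel.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["user_id", "role", "authorized_studies"])
        for p in registry.personnel.values():
            w.writerow([p.user_id, p.role, ";".join(p.authorized_studies)])
    with (d / "encounters.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["csn", "participant_id", "date"])
        for e in registry.encounters.values():
            w.writerow([e.csn, e.participant_id, e.date.isoformat()])


def load_registry(directory: Union[str, Path]) -> Registry:
    """Load the CSV bundle written by :func:`save_registry`."""
    d = Path(directory)
    for name in _BUNDLE_FILES:
        if not (d / name).exists():
            raise RegistryError(f"registry bundle missing {name} in {d}")
    reg = Registry()
    with (d / "studies.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reg.add_study(Study(
                study_id=row["study_id"], title=row["title"],
                agents=tuple(a for a in row["agents"].split(";") if a),
                interventional=bool(int(row["interventional"])),
                ctcae_version=int(row["ctcae_version"]),
            ))
    with (d / "participants.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reg.add_participant(Participant(
                participant_id=row["participant_id"], mrn=row["mrn"],
                enrolled_studies=tuple(s for s in row["enrolled_studies"].split(";") if s),
            ))
    with (d / "personnel.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reg.add_personnel(Personnel(
                user_id=row["user_id"], role=row["role"],  # type: ignore[arg-type]
                authorized_studies=tuple(s for s in row["authorized_studies"].split(";") if s),
            ))
    with (d / "encounters.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reg.record_encounter(row["participant_id"], row["csn"], row["date"])
    return reg
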