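"""HL7 v2 ORU-R01 ingestion and outbound AE-document message rendering.

Implements a minimal, tolerant pipe-delimited HL7 v2 (2.3-2.5) reader for
the segment subset MSH/PID/PV1/OBR/OBX with the default encoding characters
``^~\\&``; unknown segments are ignored, not rejected.  MLLP framing bytes
(0x0B ... 0x1C 0x0D) are stripped when present, and plain-text files (one
or more messages, newline-separated) are accepted.

Each numeric OBX observation becomes one :class:`LabResult`; non-numeric
observations are returned in a skipped list with reasons, so that
``len(results) + len(skipped)`` always equals the number of OBX segments.

Outbound AE documents are rendered as an MDM^T02-like transcription
message with the narrative carried in OBX text segments.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Hl7Error",
    "LabResult",
    "SkippedObservation",
    "ParsedOru",
    "StudyBoundResult",
    "parse_oru",
    "parse_oru_file",
    "render_oru",
    "filter_to_participants",
    "render_ae_document_message",
    "results_to_csv",
    "format_hl7_timestamp",
    "parse_hl7_timestamp",
]

FIELD_SEP = "|"
COMPONENT_SEP = "^"
MLLP_START = "\x0b"
MLLP_END = "\x1c"


class Hl7Error(ValueError):
    """Raised for structurally unusable HL7 input."""


def parse_hl7_timestamp(ts: str) -> datetime:
    """Parse an HL7 TS value (YYYYMMDD[HHMM[SS]]), ignoring a timezone tail."""
    ts = ts.strip()
    for tzsep in ("+", "-"):
        # timezone offsets only follow a full date-time; keep bare dates intact
        if tzsep in ts[8:]:
            ts = ts[: 8 + ts[8:].index(tzsep)]
    ts = ts.split(".")[0]
    for fmt in ("%Y%m%d%H%M%S", "%Y%m%d%H%M", "%Y%m%d"):
        try:
            return datetime.strptime(ts, fmt)
        except ValueError:
            continue
    raise Hl7Error(f"unparseable HL7 timestamp {ts!r}")


def format_hl7_timestamp(dt: datetime) -> str:
    return dt.strftime("%Y%m%d%H%M%S")


@dataclass(frozen=True)
class LabResult:
    """One numeric observation extracted from an OBX segment."""

    message_id: str
    patient_id: str
    lab_type: str
    value: float
    unit: str
    observed_at: datetime
    reference_range: Optional[tuple[float, float]] = None
    lab_name: str = ""
    encounter_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise Hl7Error("patient_id must be non-empty")


@dataclass(frozen=True)
class SkippedObservation:
    """An OBX segment that did not yield a numeric LabResult."""

    message_id: str
    obx_index: int
    reason: str
    raw: str = ""


@dataclass(frozen=True)
class ParsedOru:
    """Parse outcome for one ORU-R01 message."""

    message_id: str
    patient_id: str
    results: tuple[LabResult, ...]
    skipped: tuple[SkippedObservation, ...]

    @property
    def n_obx(self) -> int:
        return len(self.results) + len(self.skipped)


def _split_segments(message: str) -> list[list[str]]:
    text = message.replace(MLLP_START, "").replace(MLLP_END, "")
    segments = []
    for line in text.replace("\r\n", "\r").replace("\n", "\r").split("\r"):
        line = line.strip("\r\n ")
        if line:
            segments.append(line.split(FIELD_SEP))
    return segments


def _component(value: str, idx: int = 0) -> str:
    parts = value.split(COMPONENT_SEP)
    return parts[idx] if idx < len(parts) else ""


def _parse_range(raw: str) -> Optional[tuple[float, float]]:
    """OBX-7 as ``low-high``; any other syntax (e.g. ``<5``) is absent."""
    raw = raw.strip()
    if not raw or raw.count("-") != 1 or raw.startswith("-"):
        return None
    lo_s, hi_s = raw.split("-")
    try:
        lo, hi = float(lo_s), float(hi_s)
    except ValueError:
        return None
    return (lo, hi) if lo < hi else None


def parse_oru(message: str) -> ParsedOru:
    """Parse one ORU-R01 message into LabResults plus a skipped list.

    Only numeric (or numerically parseable) OBX values become results;
    every other OBX is reported as skipped with a reason, so no
    observation is silently invented or dropped.
    """
    segments = _split_segments(message)
    if not segments or segments[0][0] != "MSH":
        raise Hl7Error("message must begin with an MSH segment")
    msh = segments[0]
    # MSH-1 is the field separator itself, so list index n holds MSH-(n+1)
    msg_type = msh[8] if len(msh) > 8 else ""
    if not msg_type.replace("^", " ").startswith("ORU"):
        raise Hl7Error(f"unsupported message type {msg_type!r} (expected ORU^R01)")
    message_id = msh[9] if len(msh) > 9 else ""
    msh_time = msh[6] if len(msh) > 6 else ""

    patient_id = ""
    encounter_hint: Optional[str] = None
    obr_time = ""
    results: list[LabResult] = []
    skipped: list[SkippedObservation] = []
    obx_index = 0
    for seg in segments[1:]:
        sid = seg[0]
        if sid == "PID":
            if len(seg) <= 3 or not _component(seg[3]).strip():
                raise Hl7Error("PID segment carries no patient identifier (PID-3)")
            patient_id = _component(seg[3]).strip()
        elif sid == "PV1":
            if len(seg) > 19 and seg[19].strip():
                encounter_hint = seg[19].strip()
        elif sid == "OBR":
            obr_time = seg[7] if len(seg) > 7 else ""
        elif sid == "OBX":
            obx_index += 1
            raw = FIELD_SEP.join(seg)
            if not patient_id:
                skipped.append(SkippedObservation(message_id, obx_index,
                                                 "OBX before PID", raw))
                continue
            value_type = seg[2] if len(seg) > 2 else ""
            lab_type = _component(seg[3]) if len(seg) > 3 else ""
            lab_name = _component(seg[3], 1) if len(seg) > 3 else ""
            value_raw = seg[5] if len(seg) > 5 else ""
            unit = _component(seg[6]) if len(seg) > 6 else ""
            range_raw = seg[7] if len(seg) > 7 else ""
            obs_time = seg[14] if len(seg) > 14 else ""
            if not lab_type:
                skipped.append(SkippedObservation(message_id, obx_index,
                                                 "missing observation identifier (OBX-3)", raw))
                continue
            try:
                value = float(value_raw)
            except ValueError:
                reason = (
                    f"non-numeric value {value_raw!r}"
                    if value_type in ("NM", "SN", "")
                    else f"non-numeric value type {value_type!r}"
                )
                skipped.append(SkippedObservation(message_id, obx_index, reason, raw))
                continue
            ts_raw = obs_time or obr_time or msh_time
            try:
                observed_at = parse_hl7_timestamp(ts_raw)
            except Hl7Error:
                skipped.append(SkippedObservation(message_id, obx_index,
                                                 f"unparseable timestamp {ts_raw!r}", raw))
                continue
            results.append(
                LabResult(
                    message_id=message_id,
                    patient_id=patient_id,
                    lab_type=lab_type,
                    value=value,
                    unit=unit,
                    observed_at=observed_at,
                    reference_range=_parse_range(range_raw),
                    lab_name=lab_name,
                    encounter_hint=encounter_hint,
                )
            )
    if not patient_id:
        raise Hl7Error("message carries no PID segment")
    return ParsedOru(
        message_id=message_id,
        patient_id=patient_id,
        results=tuple(results),
        skipped=tuple(skipped),
    )


def parse_oru_file(text: str) -> list[ParsedOru]:
    """Parse a file holding one or more ORU messages (MLLP or plain text)."""
    text = text.replace(MLLP_START, "").replace(MLLP_END, "")
    chunks: list[list[str]] = []
    for line in text.replace("\r\n", "\r").replace("\n", "\r").split("\r"):
        if line.startswith("MSH"):
            chunks.append([line])
        elif line.strip() and chunks:
            chunks[-1].append(line)
    return [parse_oru("\r".join(chunk)) for chunk in chunks]


def _fmt_num(x: float) -> str:
    return format(x, "g")


def render_oru(
    results: Sequence[LabResult],
    *,
    sending_app: str = "AECAP",
    skipped_raw: Sequence[str] = (),
) -> str:
    """Render LabResults of one patient back into an ORU-R01 message.

    Inverse of :func:`parse_oru` for the captured fields (round-trip safe).
    All results must share message_id and patient_id.
    """
    if not results:
        raise Hl7Error("cannot render an ORU message with no results")
    ids = {(r.message_id, r.patient_id) for r in results}
    if len(ids) > 1:
        raise Hl7Error("all results in one message must share message_id/patient_id")
    first = results[0]
    now = format_hl7_timestamp(first.observed_at)
    lines = [
        f"MSH|^~\\&|{sending_app}|LAB|AERS|SITE|{now}||ORU^R01|{first.message_id}|P|2.5",
        f"PID|1||{first.patient_id}||DOE^JANE",
    ]
    if first.encounter_hint:
        lines.append("PV1|1|O|||||||||||||||||" + first.encounter_hint)
    lines.append(f"OBR|1|||PANEL^Laboratory panel|||{now}")
    idx = 0
    for r in results:
        idx += 1
        rng = (
            f"{_fmt_num(r.reference_range[0])}-{_fmt_num(r.reference_range[1])}"
            if r.reference_range
            else ""
        )
        name = f"^{r.lab_name}" if r.lab_name else ""
        lines.append(
            f"OBX|{idx}|NM|{r.lab_type}{name}|1|{_fmt_num(r.value)}|{r.unit}|{rng}"
            f"|||||||{format_hl7_timestamp(r.observed_at)}"
        )
    for raw in skipped_raw:
        idx += 1
        lines.append(raw)
    return "\r".join(lines) + "\r"


@dataclass(frozen=True)
class StudyBoundResult:
    """A lab result matched to a registered participant on one study."""

    result: LabResult
    participant_id: str
    study_id: str


def filter_to_participants(
    results: Iterable[LabResult], registry
) -> tuple[list[StudyBoundResult], list[LabResult]]:
    """Keep results belonging to registered study participants.

    The MRN in PID-3 is matched exactly (after whitespace trim) against the
    registry; a participant enrolled in several studies yields one
    study-bound copy per enrollment.  Non-participant results are returned
    in the discarded list and never graded.
    """
    matched: list[StudyBoundResult] = []
    discarded: list[LabResult] = []
    for result in results:
        participant = registry.lookup_by_mrn(result.patient_id)
        if participant is None or not participant.enrolled_studies:
            discarded.append(result)
            continue
        for study_id in participant.enrolled_studies:
            matched.append(
                StudyBoundResult(
                    result=result,
                    participant_id=participant.participant_id,
                    study_id=study_id,
                )
            )
    return matched, discarded


DOCUMENT_TYPE_LABELS = {
    "office_visit_ae": "Office Visit Adverse Event",
    "lab_based_ae": "Lab Based Adverse Event",
}


def render_ae_document_message(document) -> str:
    """Render a signed AE document as an MDM^T02-like HL7 message.

    The document type field carries the note type under which the document
    is filed ("Lab Based Adverse Event" for lab-sourced AEs).  Rendering is
    deterministic: byte-identical across calls on the same document.
    """
    if not document.signed:
        raise Hl7Error("document must be provider-signed before rendering")
    label = DOCUMENT_TYPE_LABELS[document.document_type]
    ts = format_hl7_timestamp(document.created_at)
    lines = [
        f"MSH|^~\\&|AECAP|AERS|EPIC|SITE|{ts}||MDM^T02|{document.document_id}|P|2.5",
        f"PID|1||{document.participant_id}",
        f"PV1|1|O|||||||||||||||||{document.csn}",
        f"TXA|1|{label}|TX|{ts}|{document.provider}||||||{document.document_id}||||||AU",
    ]
    for i, line in enumerate(document.narrative.splitlines(), start=1):
        lines.append(f"OBX|{i}|TX|NOTE^{label}|1|{line}")
    return "\r".join(lines) + "\r"


def results_to_csv(results: Iterable[LabResult], path: Union[str, Path]) -> None:
    """CSV mirror of parsed results (one row per observation)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["message_id", "patient_id", "lab_type", "value", "unit",
             "lln", "uln", "observed_at", "encounter_hint"]
        )
        for r in results:
            lln, uln = ("", "") if r.reference_range is None else r.reference_range
            writer.writerow(
                [r.message_id, r.patient_id, r.lab_type, r.value, r.unit,
                 lln, uln, r.observed_at.isoformat(), r.encounter_hint or ""]
            )
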