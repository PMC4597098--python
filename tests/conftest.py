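from datetime import date, datetime

import pytest

from aecap.catalog import default_catalog
from aecap.grading import default_ranges, default_rules
from aecap.hl7io import LabResult
from aecap.lifecycle import AeTracker, ManualClock
from aecap.registry import Participant, Personnel, Registry, Study

T0 = datetime(2014, 3, 3, 8, 0, 0)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def rules(catalog):
    return default_rules(catalog)


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()


def make_lab(
    value,
    lab_type="K",
    unit="mEq/L",
    reference_range=(3.5, 5.1),
    patient_id="MRN001",
    message_id="MSG1",
    observed_at=T0,
):
    return LabResult(
        message_id=message_id,
        patient_id=patient_id,
        lab_type=lab_type,
        value=value,
        unit=unit,
        observed_at=observed_at,
        reference_range=reference_range,
    )


@pytest.fixture
def registry():
    reg = Registry()
    reg.add_study(Study("S1", "Trial one", agents=("pembrolizumab",)))
    reg.add_study(Study("S2", "Trial two", agents=("carboplatin",)))
    reg.add_participant(Participant("P1", "MRN001", ("S1",)))
    reg.add_participant(Participant("P2", "MRN002", ("S1", "S2")))
    reg.add_personnel(Personnel("dr_a", "provider", ("S1",)))
    reg.add_personnel(Personnel("rn_b", "nurse", ("S1",)))
    reg.add_personnel(Personnel("cc_c", "coordinator", ("S1",)))
    reg.add_personnel(Personnel("dr_d", "provider", ("S2",)))
    reg.record_encounter("P1", "CSN1", date(2014, 3, 3))
    reg.record_encounter("P2", "CSN2", date(2014, 3, 3))
    reg.record_encounter("P2", "CSN3", date(2014, 3, 17))
    return reg


@pytest.fixture
def clock():
    return ManualClock(T0)


@pytest.fixture
def tracker(registry, catalog, clock):
    return AeTracker(registry, catalog, clock)


ORU_FIXTURE = (
    "MSH|^~\\&|EPIC|LAB|MIRTH|CRIS|20140303080000||ORU^R01|MSG0001|P|2.5\r"
    "PID|1||MRN001||DOE^JANE\r"
    "PV1|1|O|||||||||||||||||CSN1\r"
    "OBR|1|||CHEM^Chemistry panel|||20140303073000\r"
    "OBX|1|NM|K^Potassium|1|3.3|mEq/L|3.5-5.1|||||||20140303073000\r"
    "OBX|2|NM|NA^Sodium|1|140|mmol/L|136-145|||||||20140303073000\r"
    "OBX|3|TX|COMMENT^Specimen comment|1|hemolyzed specimen\r"
)


@pytest.fixture
def oru_message():
    return ORU_FIXTURE
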