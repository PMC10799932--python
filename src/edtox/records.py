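"""Core record types for tabular emergency-department EHR extracts.

The unit of analysis throughout the package is the *visit*: one attendance
at the ED, carrying the triage/referral reason text, any specialty chart
notes written during the visit, laboratory results, and discharge
diagnoses.  Patients link visits together for overlap control and
recurrence analysis.
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Specialty(str, enum.Enum):
    """Chart specialties scanned by the free word search."""

    GENERAL_PRACTICE = "general_practice"
    SURGERY = "surgery"
    INTERNAL_MEDICINE = "internal_medicine"
    PULMONOLOGY = "pulmonology"
    NEUROLOGY = "neurology"
    EXTERNAL_REFERRAL = "external_referral"


class Arm(str, enum.Enum):
    """The four independent search arms."""

    REASON = "reason"
    LAB = "lab"
    ICD = "icd"
    FWS = "fws"


ALL_ARMS = (Arm.REASON, Arm.LAB, Arm.ICD, Arm.FWS)


class Intent(str, enum.Enum):
    ACCIDENT = "accident"
    ABUSE = "recreational_abuse"
    SELF_HARM = "self_harm"


class AAICategory(str, enum.Enum):
    """Acute alcohol intoxication severity by blood alcohol concentration."""

    NONE = "none"
    SUBTHRESHOLD = "subthreshold"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


#: pattern for an ICD-10 code: letter + two digits, optional subcode suffix
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9A-Z]{1,4})?$")


def icd10_category(code: str) -> str:
    """Three-character category of an ICD-10 code ('F10.2' -> 'F10')."""
    return code.strip().upper()[:3]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: _dt.date
    sex: Sex


@dataclass(frozen=True)
class ChartEntry:
    specialty: Specialty
    heading: str
    body: str


@dataclass(frozen=True)
class LabResult:
    analyte: str
    value: float
    unit: str
    positive: bool


@dataclass
class VisitRecord:
    visit_id: str
    patient_id: str
    visit_date: _dt.date
    reason_text: str
    charts: list[ChartEntry] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    diagnoses: list[str] = field(default_factory=list)
    left_without_being_seen: bool = False


@dataclass(frozen=True)
class SearchHit:
    """One arm-level match; candidacy per visit is the binary union of hits."""

    visit_id: str
    arm: Arm
    matched_token: str
    location: str


@dataclass
class ConfirmedCase:
    """An adjudicated intoxication visit."""

    visit_id: str
    patient_id: str
    visit_date: _dt.date
    confirmed: bool
    primary_intoxicant: str | None = None
    secondary_intoxicants: list[str] = field(default_factory=list)
    intent: Intent | None = None
    bac_mmol: float | None = None
    bac_permille: float | None = None
    aai_category: AAICategory = AAICategory.NONE
    chronic_use: bool = False
    mental_health_dx: bool = False
    somatic_dx: bool = False
    is_index_visit: bool = False
    arms: frozenset[Arm] = frozenset()

    @property
    def intoxicants(self) -> list[str]:
        if self.primary_intoxicant is None:
            return []
        return [self.primary_intoxicant, *self.secondary_intoxicants]
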