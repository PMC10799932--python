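"""Rule-based adjudication of candidate visits.

The manual chart review behind a retrospective intoxication study applies
stated criteria: documented history of substance use, laboratory findings,
blood alcohol level (in-hospital or from the paramedic report), clinical
signs and symptoms, and response to antidotes.  This module codifies those
criteria as a deterministic rule engine over *structured* evidence fields;
free text is never re-interpreted at this stage — the generator (or a human
abstractor) supplies the evidence table.

Blood alcohol units
-------------------
BAC in mmol/L converts to per mille via the anchor 21.7 mmol/L = 1.00 per
mille.  Acute alcohol intoxication (AAI) requires clinically significant
behavioural/psychological changes (the ``signs_present`` flag) and is graded
on half-open mmol/L intervals:

=============  ====================  ================
category       BAC (mmol/L)          per mille
=============  ====================  ================
subthreshold   [0, 10.9)             [0, 0.50)
mild           [10.9, 21.7)          [0.50, 0.99]
moderate       [21.7, 65.1)          [1.00, 2.99]
severe         [65.1, inf)           >= 3.00
=============  ====================  ================
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import defaults
from .ehr_io import Cohort
from .errors import ConfigError
from .records import AAICategory, Arm, ConfirmedCase, Intent, VisitRecord
from .search import CandidateSet

#: conversion anchor: 21.7 mmol/L of blood ethanol is 1.00 per mille
MMOL_PER_PERMILLE = 21.7
MILD_BAC_MMOL = 10.9
MODERATE_BAC_MMOL = 21.7
SEVERE_BAC_MMOL = 65.1


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mmol_to_permille(bac_mmol: float, *, rounded: bool = True) -> float:
    """Convert blood alcohol from mmol/L to per mille.

    The displayed value is rounded half-up to two decimals; pass
    ``rounded=False`` for the unrounded value used internally.
    """
    if bac_mmol < 0:
        raise ValueError("blood alcohol concentration must be non-negative")
    permille = bac_mmol / MMOL_PER_PERMILLE
    return round_half_up(permille, 2) if rounded else permille


def permille_to_mmol(permille: float) -> float:
    if permille < 0:
        raise ValueError("blood alcohol concentration must be non-negative")
    return permille * MMOL_PER_PERMILLE


def classify_aai(bac_mmol: float | None, signs_present: bool) -> AAICategory:
    """Grade acute alcohol intoxication from BAC and clinical signs.

    Without clinically significant behavioural or psychological changes the
    category is ``none`` regardless of BAC.
    """
    if bac_mmol is None or not signs_present:
        return AAICategory.NONE
    if bac_mmol < 0:
        raise ValueError("blood alcohol concentration must be non-negative")
    if bac_mmol < MILD_BAC_MMOL:
        return AAICategory.SUBTHRESHOLD
    if bac_mmol < MODERATE_BAC_MMOL:
        return AAICategory.MILD
    if bac_mmol < SEVERE_BAC_MMOL:
        return AAICategory.MODERATE
    return AAICategory.SEVERE


# ---------------------------------------------------------------------------
# toxicity ranking

@dataclass(frozen=True)
class ToxicityRanking:
    """Ordered substance significance, most toxicologically significant first.

    Ethanol appears as the pair ``ethanol_high``/``ethanol_low`` so that its
    weight depends on whether the visit's BAC reaches the moderate
    threshold.  Primary-intoxicant selection scores each evidenced substance
    by (symptom-correlated?, toxicity weight) lexicographically — the
    clinical criterion is toxicity *and* correlation to the symptoms in the
    patient report — with ties broken by list order.
    """

    order: tuple[str, ...] = defaults.DEFAULT_TOXICITY_ORDER

    def __post_init__(self):
        expanded = set(self.order)
        required = (set(defaults.SUBSTANCE_CLASSES) - {"ethanol"}) | {
            "ethanol_high", "ethanol_low"}
        if expanded != required:
            missing = required - expanded
            extra = expanded - required
            raise ConfigError(
                f"toxicity ranking must mention every substance class exactly once"
                f" (missing {sorted(missing)}, unknown {sorted(extra)})"
            )

    def weight(self, substance: str, bac_mmol: float | None = None) -> int:
        """Higher weight = more toxicologically significant."""
        if substance == "ethanol":
            key = ("ethanol_high"
                   if bac_mmol is not None and bac_mmol >= MODERATE_BAC_MMOL
                   else "ethanol_low")
        else:
            key = substance
        return len(self.order) - self.order.index(key)


def assign_intoxicants(
    substances: Iterable[str],
    ranking: ToxicityRanking | None = None,
    *,
    bac_mmol: float | None = None,
    symptom_correlated: Iterable[str] = (),
) -> tuple[str, list[str]]:
    """Split the evidenced substances into (primary, secondaries).

    Substances flagged as correlated with the documented symptoms outrank
    those that are incidental findings; within a flag group the toxicity
    weight decides, with deterministic ranking-order tie-breaks.
    """
    ranking = ranking or ToxicityRanking()
    substances = list(dict.fromkeys(substances))
    if not substances:
        raise ValueError("assign_intoxicants requires at least one substance")
    correlated = set(symptom_correlated)
    scored = sorted(
        substances,
        key=lambda s: (s in correlated, ranking.weight(s, bac_mmol)),
        reverse=True,
    )
    return scored[0], scored[1:]


def classify_intent(
    unintentional_exposure: bool,
    self_harm_documented: bool,
    precedence: Sequence[Intent] = (Intent.SELF_HARM, Intent.ACCIDENT),
) -> Intent:
    """Accident / recreational abuse / deliberate self-harm.

    Recreational abuse is the default bucket (unintentional overdoses for
    non-medical purposes, traumas under the influence).  When both flags are
    documented the configured precedence decides (default: self-harm wins —
    the conservative clinical convention).
    """
    flags = {
        Intent.ACCIDENT: unintentional_exposure,
        Intent.SELF_HARM: self_harm_documented,
    }
    for intent in precedence:
        if flags.get(intent):
            return intent
    return Intent.ABUSE


# ---------------------------------------------------------------------------
# evidence & per-visit adjudication

@dataclass
class Evidence:
    """Structured review evidence for one visit."""

    history_of_use: bool = False
    signs_present: bool = False
    antidote_response: bool = False
    antidote_substance: str | None = None
    paramedic_bac_mmol: float | None = None
    unintentional_exposure: bool = False
    self_harm_documented: bool = False
    reported_substances: tuple[str, ...] = ()
    symptom_correlated: tuple[str, ...] = ()
    chronic_use: bool = False
    mental_health_dx: bool = False
    somatic_dx: bool = False


def _lab_substances(visit: VisitRecord, panel: Mapping[str, dict]) -> tuple[set[str], float | None]:
    """Substance classes positively evidenced by labs, and the ethanol BAC."""
    found: set[str] = set()
    bac: float | None = None
    for lab in visit.labs:
        cfg = panel.get(lab.analyte)
        if cfg is None:
            continue
        cls = cfg["substance_class"]
        if cfg.get("kind") == "qualitative":
            if lab.positive:
                found.add(cls)
        elif lab.value > cfg.get("threshold", 0.0):
            found.add(cls)
            if cls == "ethanol":
                mmol = (permille_to_mmol(lab.value)
                        if cfg.get("unit") == "per_mille" else lab.value)
                bac = mmol if bac is None else max(bac, mmol)
    return found, bac


def adjudicate_visit(
    visit: VisitRecord,
    evidence: Evidence | None = None,
    *,
    panel: Mapping[str, dict] | None = None,
    ranking: ToxicityRanking | None = None,
) -> ConfirmedCase:
    """Confirm or reject one candidate visit.

    Confirmation requires at least one of:

    * a positive laboratory finding for a non-ethanol intoxicant;
    * a documented response to an antidote (the substance is then
      considered used);
    * a documented history of substance use together with clinical signs
      of intoxication;
    * ethanol with an AAI grade of at least mild, using the paramedic-report
      BAC when no in-hospital value exists.  A subthreshold BAC confirms
      only with both signs and history and no other intoxicant in play —
      a low level can support the diagnosis when nothing else explains the
      presentation.

    Rejection is a value (``confirmed=False``), not an error.
    """
    evidence = evidence or Evidence()
    panel = panel or defaults.DEFAULT_LAB_PANEL
    ranking = ranking or ToxicityRanking()

    lab_found, lab_bac = _lab_substances(visit, panel)
    bac = lab_bac if lab_bac is not None else evidence.paramedic_bac_mmol

    substances: set[str] = set(lab_found)
    if evidence.antidote_response and evidence.antidote_substance:
        substances.add(evidence.antidote_substance)
    if evidence.history_of_use or evidence.signs_present:
        substances.update(evidence.reported_substances)
    if bac is not None and bac > 0:
        substances.add("ethanol")

    aai = classify_aai(bac, evidence.signs_present)
    non_ethanol_lab = bool(lab_found - {"ethanol"})
    subthreshold_override = (
        aai == AAICategory.SUBTHRESHOLD
        and evidence.signs_present
        and evidence.history_of_use
        and substances <= {"ethanol"}
    )
    confirmed = (
        non_ethanol_lab
        or evidence.antidote_response
        or (evidence.history_of_use and evidence.signs_present)
        or aai in (AAICategory.MILD, AAICategory.MODERATE, AAICategory.SEVERE)
        or subthreshold_override
    )
    if confirmed and not substances:
        confirmed = False  # no attributable intoxicant

    case = ConfirmedCase(
        visit_id=visit.visit_id,
        patient_id=visit.patient_id,
        visit_date=visit.visit_date,
        confirmed=confirmed,
        chronic_use=evidence.chronic_use,
        mental_health_dx=evidence.mental_health_dx,
        somatic_dx=evidence.somatic_dx,
    )
    if not confirmed:
        return case

    primary, secondary = assign_intoxicants(
        sorted(substances), ranking, bac_mmol=bac,
        symptom_correlated=evidence.symptom_correlated,
    )
    case.primary_intoxicant = primary
    case.secondary_intoxicants = secondary
    case.intent = classify_intent(
        evidence.unintentional_exposure, evidence.self_harm_documented
    )
    if bac is not None:
        case.bac_mmol = bac
        case.bac_permille = mmol_to_permille(bac)
        case.aai_category = aai
    return case


def adjudicate_cohort(
    cohort: Cohort,
    candidates: CandidateSet,
    evidence: Mapping[str, Evidence],
    *,
    panel: Mapping[str, dict] | None = None,
    ranking: ToxicityRanking | None = None,
) -> list[ConfirmedCase]:
    """Adjudicate every candidate visit; returns confirmed and rejected cases.

    Deterministic and order-independent: visits are processed in sorted
    visit_id order and each is judged in isolation.
    """
    index = cohort.visit_index()
    cases: list[ConfirmedCase] = []
    for vid in sorted(candidates.candidate_visits):
        case = adjudicate_visit(
            index[vid], evidence.get(vid), panel=panel, ranking=ranking
        )
        case.arms = candidates.visit_arms.get(vid, frozenset())
        cases.append(case)
    confirmed = [c for c in cases if c.confirmed]
    link_recurrence(confirmed)
    return cases


# ---------------------------------------------------------------------------
# recurrence

def link_recurrence(confirmed: Sequence[ConfirmedCase]) -> pd.DataFrame:
    """Patient-level recurrence summary; marks each patient's index visit.

    The index visit is the patient's earliest confirmed visit of the study
    period (ties broken by visit_id).  Buckets: ``one`` / ``two_or_more``.
    """
    by_patient: dict[str, list[ConfirmedCase]] = {}
    for case in confirmed:
        by_patient.setdefault(case.patient_id, []).append(case)
    rows = []
    for patient_id, cases in sorted(by_patient.items()):
        cases.sort(key=lambda c: (c.visit_date, c.visit_id))
        for case in cases:
            case.is_index_visit = False
        cases[0].is_index_visit = True
        rows.append({
            "patient_id": patient_id,
            "index_visit_id": cases[0].visit_id,
            "index_date": cases[0].visit_date.isoformat(),
            "n_visits": len(cases),
            "bucket": "one" if len(cases) == 1 else "two_or_more",
        })
    return pd.DataFrame(rows, columns=["patient_id", "index_visit_id",
                                       "index_date", "n_visits", "bucket"])


# ---------------------------------------------------------------------------
# evidence / case CSV io

EVIDENCE_COLUMNS = [
    "visit_id", "history_of_use", "signs_present", "antidote_response",
    "antidote_substance", "paramedic_bac_mmol", "unintentional_exposure",
    "self_harm_documented", "reported_substances", "symptom_correlated",
    "chronic_use", "mental_health_dx", "somatic_dx",
]


def _split(s: str) -> tuple[str, ...]:
    return tuple(t for t in str(s).split(";") if t) if s else ()


def read_evidence(path) -> dict[str, Evidence]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, Evidence] = {}
    as_bool = lambda s: s.strip().lower() in {"true", "1", "yes"}
    for row in df.itertuples(index=False):
        out[row.visit_id] = Evidence(
            history_of_use=as_bool(row.history_of_use),
            signs_present=as_bool(row.signs_present),
            antidote_response=as_bool(row.antidote_response),
            antidote_substance=row.antidote_substance or None,
            paramedic_bac_mmol=(float(row.paramedic_bac_mmol)
                                if row.paramedic_bac_mmol else None),
            unintentional_exposure=as_bool(row.unintentional_exposure),
            self_harm_documented=as_bool(row.self_harm_documented),
            reported_substances=_split(row.reported_substances),
            symptom_correlated=_split(row.symptom_correlated),
            chronic_use=as_bool(row.chronic_use),
            mental_health_dx=as_bool(row.mental_health_dx),
            somatic_dx=as_bool(row.somatic_dx),
        )
    return out


def write_evidence(evidence: Mapping[str, Evidence], path) -> None:
    rows = []
    for vid, ev in evidence.items():
        rows.append({
            "visit_id": vid,
            "history_of_use": str(ev.history_of_use).lower(),
            "signs_present": str(ev.signs_present).lower(),
            "antidote_response": str(ev.antidote_response).lower(),
            "antidote_substance": ev.antidote_substance or "",
            "paramedic_bac_mmol": ("" if ev.paramedic_bac_mmol is None
                                   else repr(ev.paramedic_bac_mmol)),
            "unintentional_exposure": str(ev.unintentional_exposure).lower(),
            "self_harm_documented": str(ev.self_harm_documented).lower(),
            "reported_substances": ";".join(ev.reported_substances),
            "symptom_correlated": ";".join(ev.symptom_correlated),
            "chronic_use": str(ev.chronic_use).lower(),
            "mental_health_dx": str(ev.mental_health_dx).lower(),
            "somatic_dx": str(ev.somatic_dx).lower(),
        })
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n")


CASE_COLUMNS = [
    "visit_id", "patient_id", "visit_date", "confirmed", "primary_intoxicant",
    "secondary_intoxicants", "intent", "bac_mmol", "bac_permille",
    "aai_category", "chronic_use", "mental_health_dx", "somatic_dx",
    "is_index_visit", "arms",
]


def cases_frame(cases: Sequence[ConfirmedCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        rows.append({
            "visit_id": c.visit_id,
            "patient_id": c.patient_id,
            "visit_date": c.visit_date.isoformat(),
            "confirmed": str(c.confirmed).lower(),
            "primary_intoxicant": c.primary_intoxicant or "",
            "secondary_intoxicants": ";".join(c.secondary_intoxicants),
            "intent": c.intent.value if c.intent else "",
            "bac_mmol": "" if c.bac_mmol is None else repr(c.bac_mmol),
            "bac_permille": "" if c.bac_permille is None else repr(c.bac_permille),
            "aai_category": c.aai_category.value,
            "chronic_use": str(c.chronic_use).lower(),
            "mental_health_dx": str(c.mental_health_dx).lower(),
            "somatic_dx": str(c.somatic_dx).lower(),
            "is_index_visit": str(c.is_index_visit).lower(),
            "arms": ";".join(sorted(a.value for a in c.arms)),
        })
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


def write_cases(cases: Sequence[ConfirmedCase], path) -> None:
    cases_frame(cases).to_csv(path, index=False, lineterminator="\n")


def read_cases(path) -> list[ConfirmedCase]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    as_bool = lambda s: s.strip().lower() in {"true", "1", "yes"}
    out = []
    for row in df.itertuples(index=False):
        out.append(ConfirmedCase(
            visit_id=row.visit_id,
            patient_id=row.patient_id,
            visit_date=_dt.date.fromisoformat(row.visit_date),
            confirmed=as_bool(row.confirmed),
            primary_intoxicant=row.primary_intoxicant or None,
            secondary_intoxicants=list(_split(row.secondary_intoxicants)),
            intent=Intent(row.intent) if row.intent else None,
            bac_mmol=float(row.bac_mmol) if row.bac_mmol else None,
            bac_permille=float(row.bac_permille) if row.bac_permille else None,
            aai_category=AAICategory(row.aai_category),
            chronic_use=as_bool(row.chronic_use),
            mental_health_dx=as_bool(row.mental_health_dx),
            somatic_dx=as_bool(row.somatic_dx),
            is_index_visit=as_bool(row.is_index_visit),
            arms=frozenset(Arm(a) for a in _split(row.arms)),
        ))
    return out
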