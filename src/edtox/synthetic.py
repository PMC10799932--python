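"""Synthetic ED-visit cohorts with latent ground truth.

Two entry points:

:func:`generate_cohort`
    A parametric generator (:class:`GeneratorParams`): per-visit intoxication
    prevalence, per-arm discoverability probabilities with a common-shock
    overlap control, per-arm false-positive rates, and attribute mixes.

:func:`pilot2019`
    A fixed calibration profile emulating one year of a mid-size ED
    (~45,000 visits annually; scaled to 2,000 background visits by default)
    with an exactly planted yield structure: 165 true intoxication visits
    over 131 patients, of which the three traditional arms (reason-for-
    attending, laboratory, ICD-10) can discover 117 visits / 96 patients
    among 222 flagged candidates, while the free word search can discover
    162 visits / 128 patients among 281 flagged candidates; 48 visits
    (35 patients) are discoverable by the free word search alone and 3
    visits (3 patients) by a traditional arm alone.  Counts are planted by
    stratified assignment — counts first, attributes second — so they are
    exact for every seed; only the pairing of attributes with patients and
    dates varies.

Every planted discoverability flag is *realized*: content that the
corresponding search arm provably matches is injected (a keyword into the
reason text, a qualifying laboratory result, an in-spec ICD-10 code, a
lexicon concept into a chart body).  Distractor visits carry near-miss
tokens ("detox", "drugstore", "firearm", "substantial") that must not match
under whole-token/prefix rules.  False-positive candidates carry content
that matches an arm but fails adjudication ("denies alcohol use",
subthreshold ethanol without clinical signs), so that the adjudicator —
not the matcher — rejects them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .adjudicate import Evidence, write_evidence
from .ehr_io import ChartEntry, Cohort, LabResult, write_cohort
from .errors import ParameterError
from .records import PatientRecord, Sex, Specialty, VisitRecord

_YEAR = 2019
_SPECIALTIES = tuple(Specialty)

# ---------------------------------------------------------------------------
# content banks

_REASON_KEYWORD_TEXTS = (
    "suspected intoxication on arrival",
    "impaired consciousness after party",
    "unconsciousness, found outdoors",
    "convulsion witnessed at home",
    "known substance abuse, now agitated",
    "possible intoxicant ingestion",
)

_NEUTRAL_REASONS = (
    "chest pain since morning",
    "head injury after fall",
    "ankle sprain while running",
    "abdominal pain, vomiting",
    "fever and cough",
    "laceration on left hand",
    "lower back pain",
    "shortness of breath",
    "palpitations at rest",
)

#: near-miss reasons: contain stems of keywords inside longer tokens
_DISTRACTOR_REASONS = (
    "collapsed outside drugstore",
    "medication refill request",
)

#: free-word-search snippets keyed by primary substance class — each contains
#: at least one default lexicon concept
_FWS_SNIPPETS: dict[str, tuple[str, ...]] = {
    "ethanol": (
        "patient visibly intoxicated on arrival",
        "smells strongly of alcohol, slurred speech",
        "breath test 1.8 per mille on admission",
        "patient drunk, unsteady gait",
    ),
    "benzodiazepines": (
        "admits taking several benzodiazepine tablets",
        "empty benzodiazepine blister packs found at scene",
    ),
    "amphetamines": (
        "agitated, admits amphetamine use last night",
    ),
    "cannabinoids": (
        "strong smell of cannabis, conjunctival injection",
    ),
    "opioids": (
        "opiates found in pocket, pinpoint pupils",
    ),
    "cocaine": (
        "reports cocaine use earlier tonight",
    ),
    "other_pharmaceuticals": (
        "suspected overdose of paracetamol tablets",
    ),
    "other": (
        "carbon monoxide exposure in house fire",
    ),
}

_NEUTRAL_CHARTS = (
    "wound cleaned and dressed, follow-up in one week",
    "ecg normal, troponin negative, discharged",
    "x-ray shows no fracture, rest advised",
    "blood pressure controlled on current medication",
    "sutures removed, healing well",
)

#: must NOT match any lexicon concept under whole-token/prefix rules
_DISTRACTOR_CHARTS = (
    "referred to detox programme, patient declined",
    "substantial improvement since previous visit",
    "firearm licence medical form completed",
    "gabapentin dose unchanged at review",
    "collapsed outside drugstore, vasovagal episode suspected",
)

#: match a lexicon concept but describe no acute intoxication — adjudication
#: is expected to reject these
_FP_FWS_CHARTS = (
    "patient denies alcohol use today",
    "benzodiazepine taper ongoing, no acute issues",
    "no signs of intoxication were observed",
    "discussed risks of drug interactions with warfarin",
)

_FP_REASONS = (
    "unconsciousness",
    "convulsion",
    "drug prescription renewal",
    "impaired consciousness, hypoglycemia suspected",
)

_FP_ICD_CODES = ("X09", "T59.9", "F10.2", "X45")

_SAFE_ICD_CODES = ("S06.0", "R55", "S52.5", "J06.9", "K29.7", "F32.9", "I10")

_ICD_FOR_CLASS = {
    "ethanol": "F10.0",
    "benzodiazepines": "F13.0",
    "cannabinoids": "F12.0",
    "amphetamines": "F15.0",
    "cocaine": "F14.0",
    "opioids": "F11.0",
    "other_pharmaceuticals": "T50.9",
    "other": "T58",
}


# ---------------------------------------------------------------------------
# result container

@dataclass
class SyntheticResult:
    cohort: Cohort
    ground_truth: pd.DataFrame
    evidence: dict[str, Evidence]

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, d)
        self.ground_truth.to_csv(d / "ground_truth.csv", index=False,
                                 lineterminator="\n")
        write_evidence(self.evidence, d / "evidence.csv")


GROUND_TRUTH_COLUMNS = [
    "visit_id", "is_intoxication", "intoxicants", "intent", "bac_mmol",
    "discoverability", "chronic_use", "mental_health_dx", "somatic_dx",
]


def _gt_row(visit_id, is_intox, intoxicants=(), intent="", bac=None,
            discoverability=(), chronic=False, mental=False, somatic=False):
    return {
        "visit_id": visit_id,
        "is_intoxication": str(bool(is_intox)).lower(),
        "intoxicants": ";".join(intoxicants),
        "intent": intent,
        "bac_mmol": "" if bac is None else repr(float(bac)),
        "discoverability": ";".join(sorted(discoverability)),
        "chronic_use": str(bool(chronic)).lower(),
        "mental_health_dx": str(bool(mental)).lower(),
        "somatic_dx": str(bool(somatic)).lower(),
    }


# ---------------------------------------------------------------------------
# shared realization helpers

def _dates_for(rng: np.random.Generator, n: int) -> list[_dt.date]:
    days = rng.choice(365, size=n, replace=False)
    base = _dt.date(_YEAR, 1, 1)
    return sorted(base + _dt.timedelta(days=int(d)) for d in days)


def _birth_date(rng: np.random.Generator, age_years: float,
                day_pool: Sequence[int] = (1, 2, 3, 4)) -> _dt.date:
    year = _YEAR - int(round(age_years))
    month = int(rng.integers(1, 13))
    day = int(rng.choice(day_pool))
    return _dt.date(year, month, day)


def _chart(rng: np.random.Generator, body: str, heading: str = "ED note",
           specialty: Specialty | None = None) -> ChartEntry:
    if specialty is None:
        specialty = _SPECIALTIES[int(rng.integers(0, len(_SPECIALTIES)))]
    return ChartEntry(specialty=specialty, heading=heading, body=body)


def _pick(rng: np.random.Generator, bank: Sequence[str]) -> str:
    return bank[int(rng.integers(0, len(bank)))]


def _realize_true_visit(
    rng: np.random.Generator,
    visit: VisitRecord,
    disc: frozenset[str],
    primary: str,
    secondaries: tuple[str, ...],
    intent: str,
    bac: float | None,
    flags: Mapping[str, bool],
    *,
    complete_evidence: bool = True,
    icd_override: str | None = None,
    chart_override: str | None = None,
) -> Evidence:
    """Inject arm-matching content for a true intoxication visit."""
    substances = [primary, *secondaries]

    if "reason" in disc:
        visit.reason_text = _pick(rng, _REASON_KEYWORD_TEXTS)
    else:
        visit.reason_text = _pick(rng, _NEUTRAL_REASONS)

    if "fws" in disc:
        body = chart_override or _pick(rng, _FWS_SNIPPETS[primary])
        visit.charts.append(_chart(rng, body))
        if rng.random() < 0.5:
            visit.charts.append(_chart(rng, _pick(rng, _NEUTRAL_CHARTS),
                                       heading="Status"))
    else:
        visit.charts.append(_chart(rng, chart_override
                                   or _pick(rng, _NEUTRAL_CHARTS)))

    lab_bac_recorded = False
    if "lab" in disc:
        if not complete_evidence:
            # documented only by a low alcohol level, nothing else on file
            visit.labs.append(LabResult("ethanol_blood",
                                        float(np.round(rng.uniform(1, 9), 1)),
                                        "mmol_per_L", False))
        else:
            if "ethanol" in substances and bac is not None:
                visit.labs.append(LabResult("ethanol_blood", float(bac),
                                            "mmol_per_L", False))
                lab_bac_recorded = True
            for cls in substances:
                screen = defaults.SCREEN_FOR_CLASS.get(cls)
                if screen is not None:
                    visit.labs.append(LabResult(screen, 1.0,
                                                "qualitative_pos_neg", True))
            if not visit.labs:
                raise ParameterError(
                    f"visit {visit.visit_id}: lab discoverability planted for "
                    f"non-screenable substances {substances}")

    if "icd" in disc:
        if icd_override is not None:
            code = icd_override
        elif intent == "self_harm":
            code = "X69"
        else:
            code = _ICD_FOR_CLASS[primary]
        visit.diagnoses.append(code)
    else:
        if rng.random() < 0.5:
            visit.diagnoses.append(_pick(rng, _SAFE_ICD_CODES))

    if not complete_evidence:
        return Evidence()

    return Evidence(
        history_of_use=True,
        signs_present=True,
        antidote_response=(primary == "benzodiazepines"),
        antidote_substance="benzodiazepines" if primary == "benzodiazepines" else None,
        paramedic_bac_mmol=(float(bac) if (bac is not None and not lab_bac_recorded)
                            else None),
        unintentional_exposure=(intent == "accident"),
        self_harm_documented=(intent == "self_harm"),
        reported_substances=tuple(substances),
        symptom_correlated=(primary,),
        chronic_use=flags.get("chronic_use", False),
        mental_health_dx=flags.get("mental_health_dx", False),
        somatic_dx=flags.get("somatic_dx", False),
    )


def _realize_fp_visit(rng: np.random.Generator, visit: VisitRecord,
                      arms: frozenset[str]) -> None:
    """Content matching the given arms but rejectable at adjudication."""
    visit.reason_text = (_pick(rng, _FP_REASONS) if "reason" in arms
                         else _pick(rng, _NEUTRAL_REASONS))
    if "fws" in arms:
        visit.charts.append(_chart(rng, _pick(rng, _FP_FWS_CHARTS)))
    else:
        visit.charts.append(_chart(rng, _pick(rng, _NEUTRAL_CHARTS)))
    if "lab" in arms:
        visit.labs.append(LabResult("ethanol_blood",
                                    float(np.round(rng.uniform(1, 9), 1)),
                                    "mmol_per_L", False))
    if "icd" in arms:
        visit.diagnoses.append(_pick(rng, _FP_ICD_CODES))


def _realize_background_visit(rng: np.random.Generator, visit: VisitRecord) -> None:
    r = rng.random()
    visit.reason_text = (_pick(rng, _DISTRACTOR_REASONS) if r < 0.1
                         else _pick(rng, _NEUTRAL_REASONS))
    body = (_pick(rng, _DISTRACTOR_CHARTS) if rng.random() < 0.15
            else _pick(rng, _NEUTRAL_CHARTS))
    visit.charts.append(_chart(rng, body))
    if rng.random() < 0.1:
        # zero measurement: must not hit under the exclusive-zero threshold
        visit.labs.append(LabResult("ethanol_blood", 0.0, "mmol_per_L", False))
    if rng.random() < 0.1:
        visit.labs.append(LabResult("benzodiazepines_urine", 0.0,
                                    "qualitative_pos_neg", False))
    if rng.random() < 0.4:
        visit.diagnoses.append(_pick(rng, _SAFE_ICD_CODES))


# ---------------------------------------------------------------------------
# parametric generator

@dataclass
class GeneratorParams:
    """Knobs of the parametric cohort generator.

    ``arm_overlap_rho`` is a common-shock correlation: with probability rho
    all four arms share one latent uniform draw (so the joint hit probability
    of two arms is ``rho*min(pa, pb) + (1-rho)*pa*pb``); otherwise the arms
    draw independently.
    """

    n_patients: int = 200
    mean_visits_per_patient: float = 1.2
    intoxication_prevalence: float = 0.08
    arm_probs: dict = field(default_factory=lambda: {
        "reason": 0.5, "lab": 0.55, "icd": 0.5, "fws": 0.85})
    arm_overlap_rho: float = 0.25
    false_positive_rates: dict = field(default_factory=lambda: {
        "reason": 0.02, "lab": 0.015, "icd": 0.01, "fws": 0.03})
    sex_ratio_male: float = 0.72
    intent_mix: dict = field(default_factory=lambda: {
        "accident": 6 / 165, "recreational_abuse": 124 / 165,
        "self_harm": 35 / 165})
    intoxicant_mix: dict = field(default_factory=lambda: {
        "ethanol": 111 / 165, "benzodiazepines": 16 / 165,
        "other_pharmaceuticals": 14 / 165, "cannabinoids": 7 / 165,
        "amphetamines": 8 / 165, "opioids": 3 / 165, "cocaine": 1 / 165,
        "other": 5 / 165})
    secondary_prob: float = 0.3
    bac_lognorm_mu: float = 3.55
    bac_lognorm_sigma: float = 0.45
    evidence_completeness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ParameterError("n_patients must be positive")
        if self.mean_visits_per_patient < 1:
            raise ParameterError("mean_visits_per_patient must be >= 1")
        probs = {
            "intoxication_prevalence": self.intoxication_prevalence,
            "arm_overlap_rho": self.arm_overlap_rho,
            "sex_ratio_male": self.sex_ratio_male,
            "evidence_completeness": self.evidence_completeness,
            "secondary_prob": self.secondary_prob,
            **{f"arm_probs[{k}]": v for k, v in self.arm_probs.items()},
            **{f"false_positive_rates[{k}]": v
               for k, v in self.false_positive_rates.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ParameterError(f"{name} = {p} is outside [0, 1]")
        for name, mix in (("intent_mix", self.intent_mix),
                          ("intoxicant_mix", self.intoxicant_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1")


def generate_cohort(params: GeneratorParams) -> SyntheticResult:
    """Sample a cohort under *params*; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    cohort = Cohort()
    gt_rows: list[dict] = []
    evidence: dict[str, Evidence] = {}
    classes = list(params.intoxicant_mix)
    class_p = np.array([params.intoxicant_mix[c] for c in classes])
    intents = list(params.intent_mix)
    intent_p = np.array([params.intent_mix[i] for i in intents])
    arm_names = ("reason", "lab", "icd", "fws")

    vid = 0
    for pidx in range(params.n_patients):
        patient_id = f"P{pidx + 1:05d}"
        sex = Sex.MALE if rng.random() < params.sex_ratio_male else Sex.FEMALE
        age = float(np.clip(rng.normal(46, 18), 18, 90))
        cohort.patients[patient_id] = PatientRecord(
            patient_id, _birth_date(rng, age, day_pool=range(1, 29)), sex)
        n_visits = 1 + int(rng.poisson(params.mean_visits_per_patient - 1))
        n_visits = min(n_visits, 365)
        chronic = bool(rng.random() < 0.5)
        mental = bool(rng.random() < 0.35)
        somatic = bool(rng.random() < 0.6)
        for date in _dates_for(rng, n_visits):
            vid += 1
            visit = VisitRecord(f"V{vid:06d}", patient_id, date, "")
            cohort.visits.append(visit)
            if rng.random() < params.intoxication_prevalence:
                # latent true case: sample discoverability (common shock)
                shared = rng.random() < params.arm_overlap_rho
                u_common = rng.random()
                draws = {a: (u_common if shared else rng.random())
                         for a in arm_names}
                disc = frozenset(a for a in arm_names
                                 if draws[a] < params.arm_probs.get(a, 0.0))
                primary = classes[int(rng.choice(len(classes), p=class_p))]
                secondaries: tuple[str, ...] = ()
                if rng.random() < params.secondary_prob:
                    others = [c for c in classes if c != primary and c != "other"]
                    secondaries = (others[int(rng.integers(0, len(others)))],)
                substances = [primary, *secondaries]
                bac = None
                if "ethanol" in substances:
                    bac = float(np.round(np.exp(
                        rng.normal(params.bac_lognorm_mu,
                                   params.bac_lognorm_sigma)), 1))
                intent = intents[int(rng.choice(len(intents), p=intent_p))]
                # lab discoverability needs something to measure
                if "lab" in disc and "ethanol" not in substances and not any(
                        c in defaults.SCREEN_FOR_CLASS for c in substances):
                    disc = disc - {"lab"}
                complete = rng.random() < params.evidence_completeness
                ev = _realize_true_visit(
                    rng, visit, disc, primary, secondaries, intent, bac,
                    {"chronic_use": chronic, "mental_health_dx": mental,
                     "somatic_dx": somatic},
                    complete_evidence=complete)
                evidence[visit.visit_id] = ev
                gt_rows.append(_gt_row(
                    visit.visit_id, True, substances, intent, bac, disc,
                    chronic, mental, somatic))
            else:
                fp_arms = frozenset(
                    a for a in arm_names
                    if rng.random() < params.false_positive_rates.get(a, 0.0))
                if fp_arms:
                    _realize_fp_visit(rng, visit, fp_arms)
                else:
                    _realize_background_visit(rng, visit)
                evidence[visit.visit_id] = Evidence()
                gt_rows.append(_gt_row(visit.visit_id, False,
                                       discoverability=fp_arms))

    ground_truth = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    return SyntheticResult(cohort, ground_truth, evidence)


# ---------------------------------------------------------------------------
# pilot2019 calibration profile

# per-patient plan: (group, sex, n_visits) x count
_PILOT_PATIENT_PLAN = (
    # group A: discoverable by a traditional arm AND the free word search
    ("A", Sex.MALE, 1, 58), ("A", Sex.MALE, 2, 10),
    ("A", Sex.FEMALE, 1, 15), ("A", Sex.FEMALE, 2, 9), ("A", Sex.FEMALE, 3, 1),
    # group B: discoverable only by the free word search
    ("B", Sex.MALE, 1, 18), ("B", Sex.MALE, 2, 6),
    ("B", Sex.FEMALE, 1, 5), ("B", Sex.FEMALE, 2, 5), ("B", Sex.FEMALE, 3, 1),
)

# intoxicant profiles for group A visits: (primary, secondaries) x count
_PILOT_A_PROFILES = (
    (("ethanol", ()), 41),
    (("ethanol", ("benzodiazepines",)), 4),
    (("ethanol", ("other_pharmaceuticals",)), 8),
    (("ethanol", ("cannabinoids",)), 9),
    (("ethanol", ("amphetamines",)), 6),
    (("ethanol", ("opioids",)), 2),
    (("benzodiazepines", ()), 2),
    (("benzodiazepines", ("ethanol",)), 5),
    (("benzodiazepines", ("other_pharmaceuticals",)), 4),
    (("benzodiazepines", ("amphetamines",)), 2),
    (("other_pharmaceuticals", ()), 3),      # +1 planted dementia accident
    (("other_pharmaceuticals", ("ethanol",)), 3),
    (("other_pharmaceuticals", ("benzodiazepines",)), 3),
    (("other_pharmaceuticals", ("cannabinoids",)), 1),
    (("other_pharmaceuticals", ("amphetamines",)), 1),
    (("cannabinoids", ()), 3),
    (("cannabinoids", ("ethanol",)), 1),
    (("cannabinoids", ("other_pharmaceuticals",)), 2),
    (("amphetamines", ("other_pharmaceuticals",)), 2),
    (("amphetamines", ("ethanol",)), 1),
    (("amphetamines", ("cocaine",)), 1),
    (("amphetamines", ("cannabinoids",)), 1),
    (("opioids", ("other_pharmaceuticals",)), 2),
    (("opioids", ("amphetamines",)), 1),
    (("cocaine", ()), 1),
)
# the four remaining "other" profiles and the dementia case are planted
# explicitly (they carry the accident intent)

# intoxicant profiles for group B (free-word-search-only) visits
_PILOT_B_PROFILES = (
    (("ethanol", ()), 39),
    (("ethanol", ("benzodiazepines",)), 1),
    (("benzodiazepines", ()), 2),
    (("benzodiazepines", ("ethanol",)), 1),
    (("other_pharmaceuticals", ()), 1),
    (("other_pharmaceuticals", ("cannabinoids",)), 1),
    (("cannabinoids", ()), 1),
    (("amphetamines", ()), 2),
)

# arm combinations for group A visits (every combination includes fws and at
# least one traditional arm); four of these are reserved for the planted
# accidents before shuffling
_PILOT_A_COMBOS = (
    (frozenset({"reason", "fws"}), 30),
    (frozenset({"lab", "fws"}), 28),
    (frozenset({"icd", "fws"}), 22),
    (frozenset({"reason", "lab", "fws"}), 12),
    (frozenset({"reason", "icd", "fws"}), 8),
    (frozenset({"lab", "icd", "fws"}), 7),
    (frozenset({"reason", "lab", "icd", "fws"}), 7),
)

# false-positive candidates: arm -> count of planted rejectable candidates
_PILOT_FP_TRADITIONAL = {"reason": 40, "lab": 35, "icd": 30}
_PILOT_FP_FWS = 119

# patient-level concomitant-problem quotas (men, women)
_PILOT_FLAG_QUOTAS = {
    "chronic_use": (50, 20),
    "mental_health_dx": (30, 18),
    "somatic_dx": (51, 26),
}

_PILOT_SEVERE_AAI = {"men": 9, "women": 4}   # 13 severe cases in total
_PILOT_MEDIAN_BAC = {"men": 43.6, "women": 31.2}


def _expand_counts(spec) -> list:
    out = []
    for item, count in spec:
        out.extend([item] * count)
    return out


def _bac_values(rng: np.random.Generator, n: int, median: float,
                n_severe: int, fixed_below: Sequence[float] = ()) -> list[float]:
    """n positive values with the exact sample median and n_severe >= 65.1."""
    if n == 0:
        return []
    if n == 1:
        return [median]
    if n % 2 == 1:
        n_below = n_above = (n - 1) // 2
        mids = [median]
    else:
        n_below = n_above = (n - 2) // 2
        mids = [median, median]
    n_severe = min(n_severe, n_above)
    fixed_below = list(fixed_below)[:n_below]
    below = fixed_below + [
        float(np.round(v, 1))
        for v in rng.uniform(11.0, median - 0.6, n_below - len(fixed_below))
    ]
    above = [float(np.round(v, 1))
             for v in rng.uniform(median + 0.6, 64.4, n_above - n_severe)]
    severe = [float(np.round(v, 1)) for v in rng.uniform(66.0, 105.0, n_severe)]
    return below + mids + above + severe


def pilot2019(seed: int = 1, total_visits: int = 2000) -> SyntheticResult:
    """Build the fixed calibration cohort (see module docstring)."""
    n_planted = 165 + sum(_PILOT_FP_TRADITIONAL.values()) + _PILOT_FP_FWS
    if total_visits < n_planted:
        raise ParameterError(
            f"total_visits must be at least {n_planted} to hold the planted "
            f"candidate structure")
    rng = np.random.default_rng(seed)
    cohort = Cohort()
    gt_rows: list[dict] = []
    evidence: dict[str, Evidence] = {}

    # -- patients ----------------------------------------------------------
    plan = _expand_counts([((g, s, n), c) for g, s, n, c in _PILOT_PATIENT_PLAN])
    patients: list[dict] = []   # group, sex, visit slots
    pid = 0
    for group, sex, n_visits in plan:
        pid += 1
        patients.append({"patient_id": f"P{pid:05d}", "group": group,
                         "sex": sex, "n_visits": n_visits})
    # group C: three patients found by a single traditional arm each
    c_specs = [
        {"label": "snakebite", "sex": Sex.MALE},
        {"label": "ethanol_trauma", "sex": Sex.MALE},
        {"label": "multidrug_confusion", "sex": Sex.FEMALE},
    ]
    for spec in c_specs:
        pid += 1
        patients.append({"patient_id": f"P{pid:05d}", "group": "C",
                         "sex": spec["sex"], "n_visits": 1,
                         "label": spec["label"]})

    # concomitant-problem flags at patient level, by sex quota
    males = [p for p in patients if p["sex"] == Sex.MALE]
    females = [p for p in patients if p["sex"] == Sex.FEMALE]
    assert len(males) == 94 and len(females) == 37
    for flag, (n_m, n_w) in _PILOT_FLAG_QUOTAS.items():
        for pool, quota in ((males, n_m), (females, n_w)):
            chosen = rng.choice(len(pool), size=quota, replace=False)
            chosen = set(int(i) for i in chosen)
            for i, p in enumerate(pool):
                p[flag] = p.get(flag, False) or (i in chosen)

    # register patients and expand visit slots
    slots: list[dict] = []
    vid = 0
    for p in patients:
        mean_age, sd_age = (44.4, 17.3) if p["sex"] == Sex.MALE else (50.7, 20.0)
        age = float(np.clip(rng.normal(mean_age, sd_age), 18, 90))
        cohort.patients[p["patient_id"]] = PatientRecord(
            p["patient_id"], _birth_date(rng, age), p["sex"])
        for date in _dates_for(rng, p["n_visits"]):
            vid += 1
            slots.append({"visit_id": f"V{vid:06d}", "patient": p,
                          "date": date})
    assert len(slots) == 165

    a_slots = [s for s in slots if s["patient"]["group"] == "A"]
    b_slots = [s for s in slots if s["patient"]["group"] == "B"]
    c_slots = [s for s in slots if s["patient"]["group"] == "C"]
    assert (len(a_slots), len(b_slots), len(c_slots)) == (114, 48, 3)

    # -- plant the six accidents ------------------------------------------
    # carbon-monoxide/fire exposures ("other" class): 2 male + 2 female,
    # non-laboratory combinations; one male dementia medication accident
    a_male = [s for s in a_slots if s["patient"]["sex"] == Sex.MALE]
    a_female = [s for s in a_slots if s["patient"]["sex"] == Sex.FEMALE]
    special = {}
    pick_m = rng.choice(len(a_male), size=3, replace=False)
    pick_f = rng.choice(len(a_female), size=2, replace=False)
    co_slots = [a_male[int(pick_m[0])], a_male[int(pick_m[1])],
                a_female[int(pick_f[0])], a_female[int(pick_f[1])]]
    dementia_slot = a_male[int(pick_m[2])]
    for s, combo in zip(co_slots, (frozenset({"reason", "fws"}),
                                   frozenset({"reason", "fws"}),
                                   frozenset({"icd", "fws"}),
                                   frozenset({"icd", "fws"}))):
        special[s["visit_id"]] = {
            "profile": ("other", ()), "combo": combo, "intent": "accident"}
    special[dementia_slot["visit_id"]] = {
        "profile": ("other_pharmaceuticals", ()),
        "combo": frozenset({"reason", "lab", "fws"}), "intent": "accident"}

    # -- assign remaining profiles and combinations in group A -------------
    rest_a = [s for s in a_slots if s["visit_id"] not in special]
    profiles_a = _expand_counts(_PILOT_A_PROFILES)
    combos_a = _expand_counts(_PILOT_A_COMBOS)
    # remove the combinations consumed by the planted accidents
    for s in special.values():
        combos_a.remove(s["combo"])
    assert len(rest_a) == len(profiles_a) == len(combos_a) == 109
    order = rng.permutation(len(rest_a))
    profiles_a = [profiles_a[int(i)] for i in order]
    order = rng.permutation(len(rest_a))
    combos_a = [combos_a[int(i)] for i in order]

    # -- group B: free-word-search only ------------------------------------
    profiles_b = _expand_counts(_PILOT_B_PROFILES)
    assert len(profiles_b) == len(b_slots) == 48
    order = rng.permutation(len(b_slots))
    profiles_b = [profiles_b[int(i)] for i in order]

    # -- assemble per-visit specs ------------------------------------------
    visit_specs: list[dict] = []
    for s, profile, combo in zip(rest_a, profiles_a, combos_a):
        visit_specs.append({**s, "profile": profile, "disc": combo})
    for vid_, sp in special.items():
        slot = next(s for s in a_slots if s["visit_id"] == vid_)
        visit_specs.append({**slot, "profile": sp["profile"],
                            "disc": sp["combo"], "intent": sp["intent"]})
    for s, profile in zip(b_slots, profiles_b):
        visit_specs.append({**s, "profile": profile,
                            "disc": frozenset({"fws"})})
    for s in c_slots:
        label = s["patient"]["label"]
        if label == "snakebite":
            visit_specs.append({**s, "profile": ("other", ()),
                                "disc": frozenset({"icd"}),
                                "intent": "accident",
                                "icd_override": "T63.0",
                                "chart_override":
                                    "bitten by a viper while gardening, leg "
                                    "swollen, kept for observation"})
        elif label == "ethanol_trauma":
            visit_specs.append({**s, "profile": ("ethanol", ()),
                                "disc": frozenset({"lab"}),
                                "intent": "recreational_abuse",
                                "bac": 34.1,   # 1.57 per mille
                                "chart_override":
                                    "fell from a ladder, wrist fracture "
                                    "reduced and cast applied"})
        else:
            visit_specs.append({
                **s,
                "profile": ("amphetamines", ("cannabinoids", "benzodiazepines")),
                "disc": frozenset({"lab"}), "intent": "recreational_abuse",
                "chart_override":
                    "undetermined confusion, disoriented, admitted for "
                    "observation"})

    # -- intents ------------------------------------------------------------
    # visit-level quotas: accidents 4 male / 2 female (planted above),
    # self-harm 13 male / 22 female, remainder recreational abuse
    for quota, sex in ((13, Sex.MALE), (22, Sex.FEMALE)):
        eligible = [v for v in visit_specs
                    if v["patient"]["sex"] == sex and "intent" not in v]
        chosen = rng.choice(len(eligible), size=quota, replace=False)
        for i in set(int(i) for i in chosen):
            eligible[i]["intent"] = "self_harm"
    for v in visit_specs:
        v.setdefault("intent", "recreational_abuse")

    # -- blood alcohol values ------------------------------------------------
    # exact planted medians among ethanol-primary visits per sex, with the
    # planted severe-AAI counts; ethanol-secondary visits get low values
    for sex, label in ((Sex.MALE, "men"), (Sex.FEMALE, "women")):
        ep = [v for v in visit_specs
              if v["patient"]["sex"] == sex and v["profile"][0] == "ethanol"]
        fixed = [v for v in ep if "bac" in v]
        free = [v for v in ep if "bac" not in v]
        values = _bac_values(rng, len(ep), _PILOT_MEDIAN_BAC[label],
                             _PILOT_SEVERE_AAI[label],
                             fixed_below=[v["bac"] for v in fixed])
        # the leading values are the fixed ones, in order
        values_free = values[len(fixed):]
        order = rng.permutation(len(values_free))
        for v, i in zip(free, order):
            v["bac"] = values_free[int(i)]
    for v in visit_specs:
        if "ethanol" in v["profile"][1]:
            v["bac"] = float(np.round(rng.uniform(4.0, 18.0), 1))
        v.setdefault("bac", None)

    # -- realize true visits -------------------------------------------------
    visit_specs.sort(key=lambda v: v["visit_id"])
    for v in visit_specs:
        p = v["patient"]
        visit = VisitRecord(v["visit_id"], p["patient_id"], v["date"], "")
        primary, secondaries = v["profile"]
        flags = {k: p.get(k, False) for k in _PILOT_FLAG_QUOTAS}
        ev = _realize_true_visit(
            rng, visit, v["disc"], primary, secondaries, v["intent"],
            v["bac"], flags,
            icd_override=v.get("icd_override"),
            chart_override=v.get("chart_override"),
        )
        cohort.visits.append(visit)
        evidence[visit.visit_id] = ev
        gt_rows.append(_gt_row(
            visit.visit_id, True, [primary, *secondaries], v["intent"],
            v["bac"], v["disc"], flags["chronic_use"],
            flags["mental_health_dx"], flags["somatic_dx"]))

    # four of the free-word-search-only visits end with the patient leaving
    # without being seen
    lwbs = rng.choice(len(b_slots), size=4, replace=False)
    lwbs_ids = {b_slots[int(i)]["visit_id"] for i in lwbs}
    for visit in cohort.visits:
        if visit.visit_id in lwbs_ids:
            visit.left_without_being_seen = True

    # -- false-positive candidates ------------------------------------------
    fp_plan = [frozenset({arm}) for arm, n in _PILOT_FP_TRADITIONAL.items()
               for _ in range(n)]
    fp_plan += [frozenset({"fws"})] * _PILOT_FP_FWS
    for arms in fp_plan:
        pid += 1
        vid += 1
        patient_id = f"P{pid:05d}"
        sex = Sex.MALE if rng.random() < 0.6 else Sex.FEMALE
        cohort.patients[patient_id] = PatientRecord(
            patient_id, _birth_date(rng, float(rng.uniform(18, 90))), sex)
        visit = VisitRecord(f"V{vid:06d}", patient_id,
                            _dates_for(rng, 1)[0], "")
        _realize_fp_visit(rng, visit, arms)
        cohort.visits.append(visit)
        evidence[visit.visit_id] = Evidence()
        gt_rows.append(_gt_row(visit.visit_id, False, discoverability=arms))

    # -- background ----------------------------------------------------------
    n_background = total_visits - len(cohort.visits)
    for _ in range(n_background):
        pid += 1
        vid += 1
        patient_id = f"P{pid:05d}"
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        cohort.patients[patient_id] = PatientRecord(
            patient_id, _birth_date(rng, float(rng.uniform(18, 90))), sex)
        visit = VisitRecord(f"V{vid:06d}", patient_id,
                            _dates_for(rng, 1)[0], "")
        _realize_background_visit(rng, visit)
        cohort.visits.append(visit)
        evidence[visit.visit_id] = Evidence()
        gt_rows.append(_gt_row(visit.visit_id, False))

    ground_truth = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    return SyntheticResult(cohort, ground_truth, evidence)
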