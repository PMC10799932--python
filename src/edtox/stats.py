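"""Yield and profile statistics: Venn regions, incremental yield, tables, chi-square.

Percentage convention: integer percentages rounded half-up, with the
denominators the source tables use — visits for intent and intoxicant rows,
patients for recurrence and concomitant-problem rows.  Zero denominators
omit the percentage (``None``) but keep the count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import defaults
from .adjudicate import link_recurrence, round_half_up
from .ehr_io import Cohort
from .errors import EdtoxError
from .records import ALL_ARMS, Arm, ConfirmedCase, Intent, Sex
from .search import CandidateSet


def pct(n: int, d: int) -> int | None:
    """Integer percentage, half-up; ``None`` when the denominator is zero."""
    if d == 0:
        return None
    return int(round_half_up(100.0 * n / d))


# ---------------------------------------------------------------------------
# incremental yield

@dataclass(frozen=True)
class IncrementalYield:
    new_arm: str
    n_only_new: int
    n_baseline: int
    percent_exact: float | None

    @property
    def percent(self) -> int | None:
        """Half-up integer percentage; ``None`` when the baseline is empty."""
        if self.percent_exact is None:
            return None
        return int(round_half_up(self.percent_exact))


def incremental_yield(
    sets_by_arm: Mapping[Arm | str, set],
    new_arm: Arm | str,
) -> IncrementalYield:
    """Percent growth of the union when *new_arm* is added to the others.

    ``100 * |found only by new_arm| / |union of the other arms|``.  With an
    empty baseline the increase is undefined and reported as ``None`` rather
    than infinity.
    """
    key = new_arm.value if isinstance(new_arm, Arm) else new_arm
    named = { (a.value if isinstance(a, Arm) else a): set(s)
              for a, s in sets_by_arm.items() }
    if key not in named:
        raise KeyError(f"{key!r} not among arms {sorted(named)}")
    baseline: set = set().union(*(s for a, s in named.items() if a != key)) \
        if len(named) > 1 else set()
    only_new = named[key] - baseline
    exact = 100.0 * len(only_new) / len(baseline) if baseline else None
    return IncrementalYield(key, len(only_new), len(baseline), exact)


# ---------------------------------------------------------------------------
# Venn bookkeeping

def patient_venn_regions(
    cases: Sequence[ConfirmedCase],
) -> dict[frozenset[Arm], set[str]]:
    """Partition confirmed patients by the union of arms over their visits."""
    arms_by_patient: dict[str, set[Arm]] = {}
    for case in cases:
        if case.confirmed:
            arms_by_patient.setdefault(case.patient_id, set()).update(case.arms)
    regions: dict[frozenset[Arm], set[str]] = {}
    for patient, arms in arms_by_patient.items():
        regions.setdefault(frozenset(arms), set()).add(patient)
    return regions


def build_yield_report(
    candidates: CandidateSet,
    cases: Sequence[ConfirmedCase],
    new_arm: Arm = Arm.FWS,
) -> dict:
    """Per-arm candidate/confirmed counts, Venn regions, incremental yield."""
    confirmed = [c for c in cases if c.confirmed]

    cand_visits_by_arm = {arm: set() for arm in ALL_ARMS}
    cand_patients_by_arm = {arm: set() for arm in ALL_ARMS}
    for vid, arms in candidates.visit_arms.items():
        for arm in arms:
            cand_visits_by_arm[arm].add(vid)
            cand_patients_by_arm[arm].add(candidates.visit_patient[vid])

    conf_visits_by_arm = {arm: set() for arm in ALL_ARMS}
    conf_patients_by_arm = {arm: set() for arm in ALL_ARMS}
    for case in confirmed:
        for arm in case.arms:
            conf_visits_by_arm[arm].add(case.visit_id)
            conf_patients_by_arm[arm].add(case.patient_id)

    visit_regions = {
        "+".join(sorted(a.value for a in region)): sorted(vids)
        for region, vids in candidates.venn_regions.items()
    }
    conf_patient_regions = {
        "+".join(sorted(a.value for a in region)): sorted(pids)
        for region, pids in patient_venn_regions(confirmed).items()
    }

    inc = incremental_yield(conf_patients_by_arm, new_arm)
    report = {
        "per_arm": {
            arm.value: {
                "candidate_visits": len(cand_visits_by_arm[arm]),
                "candidate_patients": len(cand_patients_by_arm[arm]),
                "confirmed_visits": len(conf_visits_by_arm[arm]),
                "confirmed_patients": len(conf_patients_by_arm[arm]),
            }
            for arm in ALL_ARMS
        },
        "totals": {
            "candidate_visits": len(candidates.candidate_visits),
            "candidate_patients": len(candidates.candidate_patients),
            "confirmed_visits": len({c.visit_id for c in confirmed}),
            "confirmed_patients": len({c.patient_id for c in confirmed}),
        },
        "candidate_visit_regions": {k: len(v) for k, v in visit_regions.items()},
        "confirmed_patient_regions": {k: len(v) for k, v in conf_patient_regions.items()},
        "only_by_arm": {
            arm.value: {
                "candidate_visits": len(candidates.venn_regions.get(frozenset({arm}), ())),
                "confirmed_patients": len(
                    patient_venn_regions(confirmed).get(frozenset({arm}), ())),
            }
            for arm in ALL_ARMS
        },
        "incremental_yield": {
            "new_arm": inc.new_arm,
            "only_new_patients": inc.n_only_new,
            "baseline_patients": inc.n_baseline,
            "percent": inc.percent,
            "percent_exact": inc.percent_exact,
        },
    }
    return report


# ---------------------------------------------------------------------------
# profile & intoxicant tables

def _age_at(birth_date, on_date) -> float:
    return (on_date - birth_date).days / 365.25


def profile_table(cases: Sequence[ConfirmedCase], cohort: Cohort) -> dict:
    """Patient-profile report: sex, intent, recurrence, concomitant problems.

    Counts and integer percentages at the conventional denominators; median
    age with IQR (linear-interpolation quantiles) by sex at the index visit.
    """
    confirmed = [c for c in cases if c.confirmed]
    sex_of = {pid: p.sex for pid, p in cohort.patients.items()}

    patients = sorted({c.patient_id for c in confirmed})
    visits = confirmed
    men = [p for p in patients if sex_of[p] == Sex.MALE]
    women = [p for p in patients if sex_of[p] == Sex.FEMALE]
    men_visits = [c for c in visits if sex_of[c.patient_id] == Sex.MALE]
    women_visits = [c for c in visits if sex_of[c.patient_id] == Sex.FEMALE]

    def _by_sex_counts(total, m, w, denom_t, denom_m, denom_w):
        return {
            "total": {"n": total, "pct": pct(total, denom_t)},
            "men": {"n": m, "pct": pct(m, denom_m)},
            "women": {"n": w, "pct": pct(w, denom_w)},
        }

    table: dict = {
        "patients": _by_sex_counts(len(patients), len(men), len(women),
                                   len(patients), len(patients), len(patients)),
        "visits": _by_sex_counts(len(visits), len(men_visits), len(women_visits),
                                 len(visits), len(visits), len(visits)),
    }

    # intent, denominated in visits per column
    intents = {}
    for intent in Intent:
        n_t = sum(1 for c in visits if c.intent == intent)
        n_m = sum(1 for c in men_visits if c.intent == intent)
        n_w = sum(1 for c in women_visits if c.intent == intent)
        intents[intent.value] = _by_sex_counts(
            n_t, n_m, n_w, len(visits), len(men_visits), len(women_visits))
    table["intent"] = intents

    # recurrence, denominated in patients per column
    recurrence = link_recurrence(confirmed)
    buckets = {}
    for bucket in ("one", "two_or_more"):
        sub = recurrence[recurrence["bucket"] == bucket]["patient_id"]
        n_t = len(sub)
        n_m = sum(1 for p in sub if sex_of[p] == Sex.MALE)
        n_w = n_t - n_m
        buckets[bucket] = _by_sex_counts(
            n_t, n_m, n_w, len(patients), len(men), len(women))
    table["recurrence"] = buckets

    # concomitant problems, patient level (flag true on any confirmed visit)
    flags = {"mental_health_dx": {}, "chronic_use": {}, "somatic_dx": {}}
    by_patient: dict[str, list[ConfirmedCase]] = {}
    for c in confirmed:
        by_patient.setdefault(c.patient_id, []).append(c)
    for name in flags:
        pos = {p for p, cs in by_patient.items() if any(getattr(c, name) for c in cs)}
        n_t = len(pos)
        n_m = sum(1 for p in pos if sex_of[p] == Sex.MALE)
        flags[name] = _by_sex_counts(
            n_t, n_m, n_t - n_m, len(patients), len(men), len(women))
    table["concomitant"] = flags

    # age at index visit, by sex
    recurrence_idx = dict(zip(recurrence["patient_id"], recurrence["index_date"]))
    def _ages(pids):
        out = []
        for p in pids:
            rec = cohort.patients.get(p)
            if rec is None or p not in recurrence_idx:
                continue
            import datetime as _dt
            out.append(_age_at(rec.birth_date,
                               _dt.date.fromisoformat(recurrence_idx[p])))
        return np.asarray(out)

    ages = {}
    for label, pids in (("total", patients), ("men", men), ("women", women)):
        a = _ages(pids)
        if len(a) == 0:
            ages[label] = None
            continue
        ages[label] = {
            "median": float(np.median(a)),
            "iqr": [float(np.percentile(a, 25)), float(np.percentile(a, 75))],
        }
    table["age"] = ages

    # median BAC (mmol/L and per mille) among ethanol-primary visits, by sex
    def _bacs(cs):
        return np.asarray([c.bac_mmol for c in cs
                           if c.primary_intoxicant == "ethanol"
                           and c.bac_mmol is not None])
    bac = {}
    for label, cs in (("total", visits), ("men", men_visits), ("women", women_visits)):
        vals = _bacs(cs)
        bac[label] = None if len(vals) == 0 else float(np.median(vals))
    table["median_bac_mmol_ethanol_primary"] = bac
    return table


def intoxicant_table(cases: Sequence[ConfirmedCase]) -> pd.DataFrame:
    """Per substance class: primary/secondary/total counts and percentages.

    A visit contributes at most once per class per column; percentages are of
    total confirmed visits.
    """
    confirmed = [c for c in cases if c.confirmed]
    n_visits = len(confirmed)
    rows = []
    for cls in defaults.SUBSTANCE_CLASSES:
        primary = sum(1 for c in confirmed if c.primary_intoxicant == cls)
        secondary = sum(1 for c in confirmed if cls in c.secondary_intoxicants)
        total = sum(1 for c in confirmed
                    if c.primary_intoxicant == cls or cls in c.secondary_intoxicants)
        rows.append({
            "substance": cls,
            "primary_n": primary, "primary_pct": pct(primary, n_visits),
            "secondary_n": secondary, "secondary_pct": pct(secondary, n_visits),
            "total_n": total, "total_pct": pct(total, n_visits),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pearson chi-square

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square(table, continuity_correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    The statistic is the familiar sum of (O-E)^2/E over cells with
    df = (r-1)(c-1); the p-value is the upper tail of the chi-square
    distribution.  Yates continuity correction is off by default and
    available by flag.  A zero expected cell raises, with the standard
    advice to merge sparse categories.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or min(observed.shape) < 2:
        raise EdtoxError("contingency table must be at least 2x2")
    if (observed < 0).any():
        raise EdtoxError("contingency table counts must be non-negative")
    expected = _sps.contingency.expected_freq(observed)
    if (expected <= 0).any():
        raise EdtoxError(
            "zero expected count: merge sparse categories before testing")
    res = _sps.chi2_contingency(observed, correction=continuity_correction)
    return ChiSquareResult(statistic=float(res.statistic),
                           df=int(res.dof), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# evaluation against synthetic ground truth

def evaluate_against_truth(
    candidates: CandidateSet,
    cases: Sequence[ConfirmedCase],
    ground_truth: pd.DataFrame,
) -> dict:
    """Per-arm sensitivity/PPV and adjudicator sensitivity/specificity.

    ``ground_truth`` is the generator's table (one row per visit with
    ``is_intoxication`` and the planted per-arm ``discoverability`` mask).
    """
    gt = ground_truth.copy()
    truth = {str(r.visit_id): str(r.is_intoxication).lower() == "true"
             for r in gt.itertuples(index=False)}
    true_visits = {v for v, t in truth.items() if t}

    per_arm = {}
    for arm in ALL_ARMS:
        flagged = {vid for vid, arms in candidates.visit_arms.items()
                   if arm in arms}
        tp = len(flagged & true_visits)
        per_arm[arm.value] = {
            "candidates": len(flagged),
            "true_flagged": tp,
            "ppv": tp / len(flagged) if flagged else None,
            "sensitivity": tp / len(true_visits) if true_visits else None,
        }

    confirmed_ids = {c.visit_id for c in cases if c.confirmed}
    rejected_ids = {c.visit_id for c in cases if not c.confirmed}
    tp = len(confirmed_ids & true_visits)
    fn = len({v for v in candidates.candidate_visits if truth.get(v, False)} - confirmed_ids)
    tn = len(rejected_ids - true_visits)
    fp = len(confirmed_ids - true_visits)
    adjudicator = {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "confirmed": len(confirmed_ids),
        "rejected": len(rejected_ids),
    }
    return {"per_arm": per_arm, "adjudicator": adjudicator}
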