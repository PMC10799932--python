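"""The four search arms and their combination into a deduplicated candidate set.

Matching rules
--------------
Text is Unicode-casefolded and split into tokens at non-alphanumeric
characters.  Non-wildcard concepts match whole tokens only ("drug" does not
match "drugstore"); wildcard concepts match any token beginning with the
surface ("intox*" matches "intoxicated"); multi-word surfaces match as
contiguous token phrases ("per mille", "impaired consciousness").  Negation
is deliberately not handled here — "denies alcohol use" is a hit, and the
adjudication stage is responsible for rejecting it, mirroring a manual
chart review after an automated screen.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import defaults
from .ehr_io import Cohort, Lexicon, Concept, default_lexicon, expand_code_spec, default_code_spec
from .errors import ConfigError
from .records import ALL_ARMS, Arm, SearchHit, Specialty, VisitRecord, icd10_category


def tokenize(text: str) -> list[str]:
    """Casefolded alphanumeric tokens of *text*."""
    tokens: list[str] = []
    current: list[str] = []
    for ch in text.casefold():
        if ch.isalnum():
            current.append(ch)
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return tokens


def _phrase_matches(tokens: Sequence[str], phrase: Sequence[str], wildcard_last: bool) -> bool:
    n = len(phrase)
    if n == 0 or n > len(tokens):
        return False
    for i in range(len(tokens) - n + 1):
        window = tokens[i:i + n]
        head_ok = all(window[j] == phrase[j] for j in range(n - 1))
        if not head_ok:
            continue
        last, pat = window[n - 1], phrase[n - 1]
        if (last.startswith(pat) if wildcard_last else last == pat):
            return True
    return False


def concept_matches(tokens: Sequence[str], concept: Concept) -> str | None:
    """Return the matching surface/variant if *concept* occurs in *tokens*."""
    for literal, wildcard in [(concept.surface, concept.prefix_wildcard)] + [
        (v, False) for v in concept.variants
    ]:
        if _phrase_matches(tokens, tokenize(literal), wildcard):
            return literal
    return None


# ---------------------------------------------------------------------------
# arms

def reason_search(
    cohort: Cohort,
    keywords: Sequence[str] | None = None,
    mode: str = "token",
) -> list[SearchHit]:
    """Arm 1: keywords against the triage/referral reason text.

    ``mode='token'`` (default) requires whole-token phrase matches;
    ``mode='substring'`` accepts raw substring containment.
    """
    if keywords is None:
        keywords = defaults.DEFAULT_REASON_KEYWORDS
    if not keywords:
        raise ConfigError("reason_search requires a non-empty keyword list")
    if mode not in {"token", "substring"}:
        raise ConfigError(f"unknown reason-search mode {mode!r}")
    hits: list[SearchHit] = []
    folded = [(kw, kw.casefold(), tokenize(kw)) for kw in keywords]
    for visit in cohort.visits:
        text = visit.reason_text
        tokens = tokenize(text) if mode == "token" else None
        lowered = text.casefold() if mode == "substring" else None
        for kw, kw_folded, kw_tokens in folded:
            matched = (
                _phrase_matches(tokens, kw_tokens, False)
                if mode == "token"
                else kw_folded in lowered
            )
            if matched:
                hits.append(SearchHit(visit.visit_id, Arm.REASON, kw, "reason_text"))
    return hits


def lab_search(
    cohort: Cohort,
    panel: Mapping[str, dict] | Sequence[str] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> list[SearchHit]:
    """Arm 2: laboratory results against the analyte panel.

    A qualitative analyte hits when flagged positive; a quantitative one when
    its value strictly exceeds the configured reporting threshold (default 0,
    so any measurable ethanol is a hit).
    """
    if panel is None:
        panel_cfg = defaults.DEFAULT_LAB_PANEL
    elif isinstance(panel, Mapping):
        panel_cfg = dict(panel)
    else:
        unknown = sorted(set(panel) - set(defaults.DEFAULT_LAB_PANEL))
        if unknown:
            raise ConfigError(f"unknown analyte token(s) in panel: {unknown}")
        panel_cfg = {a: defaults.DEFAULT_LAB_PANEL[a] for a in panel}
    if not panel_cfg:
        raise ConfigError("lab_search requires a non-empty panel")
    thresholds = dict(thresholds or {})
    hits: list[SearchHit] = []
    for visit in cohort.visits:
        for lab in visit.labs:
            cfg = panel_cfg.get(lab.analyte)
            if cfg is None:
                continue
            if cfg.get("kind") == "qualitative":
                matched = lab.positive
            else:
                thr = thresholds.get(lab.analyte, cfg.get("threshold", 0.0))
                matched = lab.value > thr
            if matched:
                hits.append(
                    SearchHit(visit.visit_id, Arm.LAB, lab.analyte, f"lab:{lab.analyte}")
                )
    return hits


def icd_search(
    cohort: Cohort,
    categories: Iterable[str] | None = None,
) -> list[SearchHit]:
    """Arm 3: discharge diagnoses against the expanded ICD-10 category set.

    A diagnosis hits when its three-character category is in the set;
    subcodes match their category (F10.2 matches F10).
    """
    cats = frozenset(categories) if categories is not None else expand_code_spec(default_code_spec())
    hits: list[SearchHit] = []
    for visit in cohort.visits:
        for code in visit.diagnoses:
            cat = icd10_category(code)
            if cat in cats:
                hits.append(SearchHit(visit.visit_id, Arm.ICD, cat, f"diagnosis:{code}"))
    return hits


def free_word_search(
    cohort: Cohort,
    lexicon: Lexicon | None = None,
    specialties: Iterable[Specialty] | None = None,
) -> list[SearchHit]:
    """Arm 4: wildcard lexicon against chart headings and bodies.

    One hit per (visit, concept); all chart specialties are scanned by
    default.
    """
    lexicon = lexicon or default_lexicon()
    included = frozenset(specialties) if specialties is not None else frozenset(Specialty)
    hits: list[SearchHit] = []
    for visit in cohort.visits:
        matched_concepts: dict[Concept, tuple[str, str]] = {}
        for chart in visit.charts:
            if chart.specialty not in included:
                continue
            tokens = tokenize(chart.heading) + tokenize(chart.body)
            for concept in lexicon.concepts:
                if concept in matched_concepts:
                    continue
                token = concept_matches(tokens, concept)
                if token is not None:
                    matched_concepts[concept] = (token, f"chart:{chart.specialty.value}")
        for concept, (token, location) in matched_concepts.items():
            hits.append(SearchHit(visit.visit_id, Arm.FWS, token, location))
    return hits


def run_arms(
    cohort: Cohort,
    arms: Sequence[Arm] = ALL_ARMS,
    *,
    keywords=None,
    panel=None,
    thresholds=None,
    categories=None,
    lexicon=None,
    specialties=None,
    reason_mode: str = "token",
) -> dict[Arm, list[SearchHit]]:
    """Run the requested arms and return their hit lists keyed by arm."""
    runners = {
        Arm.REASON: lambda: reason_search(cohort, keywords, mode=reason_mode),
        Arm.LAB: lambda: lab_search(cohort, panel, thresholds),
        Arm.ICD: lambda: icd_search(cohort, categories),
        Arm.FWS: lambda: free_word_search(cohort, lexicon, specialties),
    }
    return {arm: runners[arm]() for arm in arms}


# ---------------------------------------------------------------------------
# combination

@dataclass
class CandidateSet:
    """Deduplicated union of arm hits with Venn-region bookkeeping.

    Visits are deduplicated on (patient_id, calendar date) — the overlap
    control key — keeping the union of hits under a canonical visit_id (the
    lexicographically smallest of the collapsed rows).  ``venn_regions``
    partitions ``candidate_visits``: a visit sits in region S iff the set of
    arms that hit it is exactly S.
    """

    hits: list[SearchHit] = field(default_factory=list)
    candidate_visits: set[str] = field(default_factory=set)
    candidate_patients: set[str] = field(default_factory=set)
    venn_regions: dict[frozenset[Arm], set[str]] = field(default_factory=dict)
    visit_arms: dict[str, frozenset[Arm]] = field(default_factory=dict)
    #: original visit_id -> canonical visit_id after (patient, date) dedup
    dedup_map: dict[str, str] = field(default_factory=dict)
    #: canonical visit_id -> patient_id
    visit_patient: dict[str, str] = field(default_factory=dict)

    def arms_for(self, visit_id: str) -> frozenset[Arm]:
        return self.visit_arms.get(self.dedup_map.get(visit_id, visit_id), frozenset())


def combine_arms(
    hit_lists: Iterable[list[SearchHit]] | Mapping[Arm, list[SearchHit]],
    cohort: Cohort,
) -> CandidateSet:
    """Union the arm hit lists into a :class:`CandidateSet`."""
    if isinstance(hit_lists, Mapping):
        all_hits = [h for lst in hit_lists.values() for h in lst]
    else:
        all_hits = [h for lst in hit_lists for h in lst]

    index = cohort.visit_index()
    for hit in all_hits:
        if hit.visit_id not in index:
            raise KeyError(f"hit references unknown visit_id {hit.visit_id!r}")

    # canonical id per (patient, date) among hit visits
    by_key: dict[tuple[str, str], list[str]] = defaultdict(list)
    for vid in sorted({h.visit_id for h in all_hits}):
        visit = index[vid]
        by_key[(visit.patient_id, visit.visit_date.isoformat())].append(vid)

    result = CandidateSet(hits=list(all_hits))
    for (patient_id, _date), vids in by_key.items():
        canonical = min(vids)
        for vid in vids:
            result.dedup_map[vid] = canonical
        result.candidate_visits.add(canonical)
        result.candidate_patients.add(patient_id)
        result.visit_patient[canonical] = patient_id

    arms_by_visit: dict[str, set[Arm]] = defaultdict(set)
    for hit in all_hits:
        arms_by_visit[result.dedup_map[hit.visit_id]].add(hit.arm)
    result.visit_arms = {vid: frozenset(arms) for vid, arms in arms_by_visit.items()}

    regions: dict[frozenset[Arm], set[str]] = defaultdict(set)
    for vid, arms in result.visit_arms.items():
        regions[arms].add(vid)
    result.venn_regions = dict(regions)
    return result


def search_cohort(cohort: Cohort, arms: Sequence[Arm] = ALL_ARMS, **kwargs) -> CandidateSet:
    """Run the requested arms and combine them in one call."""
    return combine_arms(run_arms(cohort, arms, **kwargs), cohort)


# ---------------------------------------------------------------------------
# candidate CSV io

def candidates_frame(candidates: CandidateSet, cohort: Cohort):
    """One row per deduplicated candidate visit."""
    import pandas as pd

    index = cohort.visit_index()
    tokens: dict[str, list[str]] = defaultdict(list)
    for hit in candidates.hits:
        canonical = candidates.dedup_map.get(hit.visit_id, hit.visit_id)
        if hit.matched_token not in tokens[canonical]:
            tokens[canonical].append(hit.matched_token)
    rows = []
    for vid in sorted(candidates.candidate_visits):
        visit = index[vid]
        rows.append({
            "visit_id": vid,
            "patient_id": visit.patient_id,
            "visit_date": visit.visit_date.isoformat(),
            "arms": ";".join(sorted(a.value for a in candidates.visit_arms[vid])),
            "matched_tokens": ";".join(tokens[vid]),
        })
    return pd.DataFrame(
        rows, columns=["visit_id", "patient_id", "visit_date", "arms",
                       "matched_tokens"])


def write_candidates(candidates: CandidateSet, cohort: Cohort, path) -> None:
    candidates_frame(candidates, cohort).to_csv(path, index=False,
                                                lineterminator="\n")


def read_candidates(path) -> CandidateSet:
    """Rebuild a (hit-less) candidate set from a candidates.csv file."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    result = CandidateSet()
    for row in df.itertuples(index=False):
        arms = frozenset(Arm(a) for a in row.arms.split(";") if a)
        result.candidate_visits.add(row.visit_id)
        result.candidate_patients.add(row.patient_id)
        result.visit_arms[row.visit_id] = arms
        result.visit_patient[row.visit_id] = row.patient_id
        result.dedup_map[row.visit_id] = row.visit_id
    regions: dict[frozenset[Arm], set[str]] = defaultdict(set)
    for vid, arms in result.visit_arms.items():
        regions[arms].add(vid)
    result.venn_regions = dict(regions)
    return result
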