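"""Search arms, matching rules, combination and Venn bookkeeping."""

import datetime
import re

import pytest
from hypothesis import given, strategies as stx

import edtox
from edtox import search as se
from edtox.ehr_io import Cohort, default_lexicon, expand_code_spec, default_code_spec, parse_lexicon
from edtox.records import (
    ALL_ARMS, Arm, ChartEntry, LabResult, PatientRecord, Sex, Specialty,
    VisitRecord,
)

D = datetime.date


def _cohort(visits):
    patients = {
        v.patient_id: PatientRecord(v.patient_id, D(1970, 1, 1), Sex.MALE)
        for v in visits
    }
    return Cohort(patients=patients, visits=list(visits))


def _visit(vid, pid="P1", date=D(2019, 6, 1), reason="", charts=(), labs=(),
           diagnoses=()):
    return VisitRecord(vid, pid, date, reason, list(charts), list(labs),
                       list(diagnoses))


def _chart(body, specialty=Specialty.SURGERY, heading="ED note"):
    return ChartEntry(specialty, heading, body)


# ---------------------------------------------------------------------------
# independent brute-force oracle (regex with explicit alnum boundaries)

def naive_match(text: str, literal: str, wildcard: bool) -> bool:
    words = [re.escape(w) for w in re.findall(r"[^\W_]+", literal.casefold())]
    if not words:
        return False
    body = r"[^a-z0-9]+".join(words)
    tail = r"[a-z0-9]*" if wildcard else ""
    pattern = r"(?<![a-z0-9])" + body + tail + r"(?![a-z0-9])"
    return re.search(pattern, text.casefold()) is not None


def naive_arm_hits(cohort, arm):
    """Scan-every-field reference matcher for one arm."""
    out = set()
    categories = expand_code_spec(default_code_spec())
    lexicon = default_lexicon()
    from edtox import defaults
    for v in cohort.visits:
        if arm is Arm.REASON:
            for kw in defaults.DEFAULT_REASON_KEYWORDS:
                if naive_match(v.reason_text, kw, False):
                    out.add(v.visit_id)
        elif arm is Arm.LAB:
            for lab in v.labs:
                cfg = defaults.DEFAULT_LAB_PANEL.get(lab.analyte)
                if cfg is None:
                    continue
                hit = (lab.positive if cfg["kind"] == "qualitative"
                       else lab.value > cfg.get("threshold", 0.0))
                if hit:
                    out.add(v.visit_id)
        elif arm is Arm.ICD:
            for code in v.diagnoses:
                if code.strip().upper()[:3] in categories:
                    out.add(v.visit_id)
        elif arm is Arm.FWS:
            for chart in v.charts:
                text = chart.heading + " . " + chart.body
                for c in lexicon.concepts:
                    if naive_match(text, c.surface, c.prefix_wildcard) or any(
                            naive_match(text, var, False) for var in c.variants):
                        out.add(v.visit_id)
    return out


# ---------------------------------------------------------------------------
# reason arm

class TestReasonSearch:
    def test_keyword_hit(self):
        cohort = _cohort([_visit("V1", reason="brought in, suspected intoxication")])
        hits = se.reason_search(cohort)
        assert [(h.visit_id, h.matched_token) for h in hits] == [("V1", "intoxication")]

    def test_empty_reason_text_no_hits(self):
        cohort = _cohort([_visit("V1", reason="")])
        assert se.reason_search(cohort) == []

    def test_whole_word_does_not_match_inside_longer_token(self):
        cohort = _cohort([_visit("V1", reason="drugstore errand gone wrong")])
        assert se.reason_search(cohort) == []
        # sanity: the substring mode does match
        assert len(se.reason_search(cohort, mode="substring")) == 1

    def test_multiword_keyword_matches_as_phrase(self):
        yes = _cohort([_visit("V1", reason="known substance abuse")])
        no = _cohort([_visit("V2", reason="substance misuse, abuse ruled out")])
        assert len(se.reason_search(yes)) == 1
        assert se.reason_search(no) == []

    def test_casefolding(self):
        cohort = _cohort([_visit("V1", reason="SUSPECTED INTOXICATION")])
        assert len(se.reason_search(cohort)) == 1


# ---------------------------------------------------------------------------
# lab arm

class TestLabSearch:
    def test_quantitative_ethanol_hit(self):
        cohort = _cohort([_visit("V1", labs=[
            LabResult("ethanol_blood", 43.6, "mmol_per_L", False)])])
        hits = se.lab_search(cohort)
        assert [(h.visit_id, h.matched_token) for h in hits] == [("V1", "ethanol_blood")]

    def test_negative_screen_no_hit(self):
        cohort = _cohort([_visit("V1", labs=[
            LabResult("benzodiazepines_urine", 0.0, "qualitative_pos_neg", False)])])
        assert se.lab_search(cohort) == []

    def test_zero_value_excluded_under_exclusive_threshold(self):
        cohort = _cohort([_visit("V1", labs=[
            LabResult("ethanol_blood", 0.0, "mmol_per_L", False)])])
        assert se.lab_search(cohort) == []

    def test_unknown_panel_analyte_is_config_error(self):
        from edtox.errors import ConfigError
        cohort = _cohort([_visit("V1")])
        with pytest.raises(ConfigError):
            se.lab_search(cohort, panel=["unobtainium_serum"])

    def test_custom_threshold(self):
        cohort = _cohort([_visit("V1", labs=[
            LabResult("ethanol_blood", 5.0, "mmol_per_L", False)])])
        assert se.lab_search(cohort, thresholds={"ethanol_blood": 10.0}) == []


# ---------------------------------------------------------------------------
# icd arm

class TestIcdSearch:
    @pytest.mark.parametrize("code, expect", [
        ("F10.0", True),   # subcode matches its category
        ("X69", True),
        ("T35", False),    # adjacent non-member
        ("S06.0", False),
    ])
    def test_membership(self, code, expect):
        cohort = _cohort([_visit("V1", diagnoses=[code])])
        hits = se.icd_search(cohort)
        assert bool(hits) is expect


# ---------------------------------------------------------------------------
# free word search

class TestFreeWordSearch:
    def test_prefix_wildcard(self):
        cohort = _cohort([_visit("V1", charts=[_chart("pt intoxicated on arrival")])])
        hits = se.free_word_search(cohort)
        assert len(hits) == 1 and hits[0].matched_token == "intox"

    def test_wildcard_requires_token_start(self):
        cohort = _cohort([_visit("V1", charts=[_chart("referred to detox programme")])])
        assert se.free_word_search(cohort) == []

    def test_no_lexicon_tokens_no_hits(self):
        cohort = _cohort([_visit("V1", charts=[_chart("sutures removed, healing well")])])
        assert se.free_word_search(cohort) == []

    def test_another_wildcard_concept(self):
        cohort = _cohort([_visit("V1", charts=[_chart("hypoglycemia corrected")])])
        hits = se.free_word_search(cohort)
        assert [h.matched_token for h in hits] == ["hypoglycem"]

    def test_phrase_concept_contiguous_only(self):
        yes = _cohort([_visit("V1", charts=[_chart("reading 2.1 per mille")])])
        no = _cohort([_visit("V2", charts=[_chart("per the nurse, one mille feuille eaten")])])
        assert len(se.free_word_search(yes)) == 1
        assert se.free_word_search(no) == []

    def test_specialty_filter(self):
        cohort = _cohort([_visit("V1", charts=[
            _chart("patient drunk", specialty=Specialty.NEUROLOGY)])])
        assert se.free_word_search(cohort, specialties={Specialty.SURGERY}) == []
        assert len(se.free_word_search(cohort, specialties={Specialty.NEUROLOGY})) == 1

    def test_one_hit_per_concept_per_visit(self):
        cohort = _cohort([_visit("V1", charts=[
            _chart("drunk, clearly drunk"), _chart("still drunk")])])
        assert len(se.free_word_search(cohort)) == 1

    def test_heading_is_scanned(self):
        cohort = _cohort([_visit("V1", charts=[
            ChartEntry(Specialty.SURGERY, "Alcohol history", "unremarkable")])])
        assert len(se.free_word_search(cohort)) == 1


# ---------------------------------------------------------------------------
# token matching properties

@given(stx.text(alphabet=stx.characters(max_codepoint=0x2ff), max_size=60))
def test_tokenize_produces_casefolded_alnum_tokens(text):
    for token in se.tokenize(text):
        assert token
        assert all(ch.isalnum() for ch in token)
        assert token == token.casefold()


@given(stx.lists(stx.sampled_from(["drunk", "detox", "drugstore", "fire",
                                   "firearm", "alcohol", "intoxicated",
                                   "substantial", "gamma"]),
                 min_size=1, max_size=8))
def test_matcher_agrees_with_regex_oracle_on_token_soup(words):
    text = " ".join(words)
    cohort = _cohort([_visit("V1", charts=[_chart(text)])])
    got = {h.matched_token for h in se.free_word_search(cohort)}
    lexicon = default_lexicon()
    expected = set()
    for c in lexicon.concepts:
        if naive_match(text, c.surface, c.prefix_wildcard):
            expected.add(c.surface)
        for var in c.variants:
            if naive_match(text, var, False):
                expected.add(var)
    assert got == expected


def test_arms_agree_with_bruteforce_oracle_on_small_cohorts(tiny_cohort):
    cohort = tiny_cohort.cohort
    hits = se.run_arms(cohort)
    for arm in ALL_ARMS:
        assert {h.visit_id for h in hits[arm]} == naive_arm_hits(cohort, arm)


# ---------------------------------------------------------------------------
# combination

class TestCombineArms:
    def test_single_arm_goes_to_singleton_region(self):
        cohort = _cohort([_visit("V1", reason="suspected intoxication")])
        cs = se.search_cohort(cohort)
        assert cs.venn_regions == {frozenset({Arm.REASON}): {"V1"}}

    def test_same_patient_same_date_rows_collapse(self):
        visits = [
            _visit("V1", pid="P1", date=D(2019, 5, 2),
                   reason="suspected intoxication"),
            _visit("V2", pid="P1", date=D(2019, 5, 2), diagnoses=["F10.0"]),
        ]
        cs = se.search_cohort(_cohort(visits))
        assert cs.candidate_visits == {"V1"}
        assert cs.visit_arms["V1"] == frozenset({Arm.REASON, Arm.ICD})
        assert cs.dedup_map["V2"] == "V1"

    def test_regions_partition_candidates(self, pilot_run):
        cs = pilot_run.candidates
        total = sum(len(v) for v in cs.venn_regions.values())
        assert total == len(cs.candidate_visits)
        union = set().union(*cs.venn_regions.values())
        assert union == cs.candidate_visits

    def test_combination_order_invariance(self, tiny_cohort):
        cohort = tiny_cohort.cohort
        hits = se.run_arms(cohort)
        lists = [hits[a] for a in ALL_ARMS]
        forward = se.combine_arms(lists, cohort)
        backward = se.combine_arms(list(reversed(lists)), cohort)
        assert forward.visit_arms == backward.visit_arms
        assert forward.venn_regions == backward.venn_regions

    def test_adding_an_arm_is_monotone(self, pilot_run):
        cohort = pilot_run.cohort
        arms: list[Arm] = []
        prev_v = prev_p = 0
        for arm in ALL_ARMS:
            arms.append(arm)
            cs = se.search_cohort(cohort, arms=arms)
            assert len(cs.candidate_visits) >= prev_v
            assert len(cs.candidate_patients) >= prev_p
            prev_v, prev_p = len(cs.candidate_visits), len(cs.candidate_patients)

    def test_unknown_visit_in_hits_rejected(self):
        cohort = _cohort([_visit("V1")])
        from edtox.records import SearchHit
        with pytest.raises(KeyError):
            se.combine_arms([[SearchHit("V9", Arm.REASON, "x", "reason_text")]],
                            cohort)
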