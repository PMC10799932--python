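"""Unit conversion, AAI grading, adjudication rules, intent and recurrence."""

import datetime

import pytest
from hypothesis import given, strategies as stx

from edtox import adjudicate as adj
from edtox.records import AAICategory, Intent, LabResult, VisitRecord

D = datetime.date


def _visit(vid="V1", pid="P1", date=D(2019, 6, 1), labs=()):
    return VisitRecord(vid, pid, date, "", labs=list(labs))


class TestBacConversion:
    @pytest.mark.parametrize("mmol, permille", [
        (65.1, 3.00),
        (43.6, 2.01),
        (31.2, 1.44),
        (10.9, 0.50),
        (0.0, 0.00),
        (34.1, 1.57),
    ])
    def test_printed_anchor_pairs(self, mmol, permille):
        assert adj.mmol_to_permille(mmol) == permille

    def test_unrounded_value_available(self):
        assert adj.mmol_to_permille(21.7, rounded=False) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            adj.mmol_to_permille(-1.0)

    @given(stx.floats(min_value=0, max_value=200, allow_nan=False))
    def test_round_trip(self, mmol):
        back = adj.permille_to_mmol(adj.mmol_to_permille(mmol, rounded=False))
        assert back == pytest.approx(mmol, abs=1e-9)


class TestRounding:
    @pytest.mark.parametrize("x, nd, expected", [
        (2.005, 2, 2.01),     # half-up, where bankers' rounding would give 2.0
        (0.5, 0, 1.0),
        (1.5, 0, 2.0),
        (84.5, 0, 85.0),
        (36.458, 0, 36.0),
    ])
    def test_half_up(self, x, nd, expected):
        assert adj.round_half_up(x, nd) == expected


class TestClassifyAai:
    @pytest.mark.parametrize("bac, expected", [
        (0.0, AAICategory.SUBTHRESHOLD),
        (10.8, AAICategory.SUBTHRESHOLD),
        (10.9, AAICategory.MILD),
        (21.6, AAICategory.MILD),
        (21.7, AAICategory.MODERATE),
        (43.6, AAICategory.MODERATE),
        (65.0, AAICategory.MODERATE),
        (65.1, AAICategory.SEVERE),
        (70.0, AAICategory.SEVERE),
    ])
    def test_interval_boundaries_with_signs(self, bac, expected):
        assert adj.classify_aai(bac, signs_present=True) == expected

    def test_signs_required(self):
        assert adj.classify_aai(43.6, signs_present=False) == AAICategory.NONE

    def test_missing_bac_is_none(self):
        assert adj.classify_aai(None, signs_present=True) == AAICategory.NONE

    @pytest.mark.parametrize("mmol, permille_lo", [(10.9, 0.50), (65.1, 3.00)])
    def test_category_boundaries_consistent_across_units(self, mmol, permille_lo):
        # the mmol/L boundary converts exactly onto the per-mille label
        assert adj.mmol_to_permille(mmol) == permille_lo


class TestAssignIntoxicants:
    def test_singleton(self):
        assert adj.assign_intoxicants(["ethanol"]) == ("ethanol", [])

    def test_high_bac_ethanol_outranks_cannabinoids(self):
        primary, secondary = adj.assign_intoxicants(
            ["cannabinoids", "ethanol"], bac_mmol=45.0)
        assert primary == "ethanol"
        assert secondary == ["cannabinoids"]

    def test_low_bac_ethanol_ranks_below_cannabinoids(self):
        primary, _ = adj.assign_intoxicants(["cannabinoids", "ethanol"],
                                            bac_mmol=5.0)
        assert primary == "cannabinoids"

    def test_symptom_correlation_dominates_toxicity(self):
        primary, secondary = adj.assign_intoxicants(
            ["opioids", "ethanol"], bac_mmol=80.0,
            symptom_correlated=["ethanol"])
        assert primary == "ethanol"
        assert secondary == ["opioids"]

    def test_empty_evidence_is_contract_violation(self):
        with pytest.raises(ValueError):
            adj.assign_intoxicants([])

    def test_ranking_must_cover_every_class(self):
        from edtox.errors import ConfigError
        with pytest.raises(ConfigError):
            adj.ToxicityRanking(order=("opioids", "ethanol_high"))


class TestClassifyIntent:
    @pytest.mark.parametrize("unint, harm, expected", [
        (True, False, Intent.ACCIDENT),
        (False, True, Intent.SELF_HARM),
        (False, False, Intent.ABUSE),
        (True, True, Intent.SELF_HARM),   # precedence when flags conflict
    ])
    def test_buckets(self, unint, harm, expected):
        assert adj.classify_intent(unint, harm) == expected


class TestAdjudicateVisit:
    def test_antidote_response_confirms(self):
        visit = _visit(labs=[LabResult("benzodiazepines_urine", 1.0,
                                       "qualitative_pos_neg", True)])
        ev = adj.Evidence(antidote_response=True,
                          antidote_substance="benzodiazepines")
        case = adj.adjudicate_visit(visit, ev)
        assert case.confirmed
        assert case.primary_intoxicant == "benzodiazepines"

    def test_no_evidence_rejected(self):
        case = adj.adjudicate_visit(_visit(), adj.Evidence())
        assert not case.confirmed

    def test_paramedic_bac_fallback_confirms_moderate_aai(self):
        ev = adj.Evidence(signs_present=True, paramedic_bac_mmol=40.0)
        case = adj.adjudicate_visit(_visit(), ev)
        assert case.confirmed
        assert case.aai_category == AAICategory.MODERATE
        assert case.bac_mmol == 40.0
        assert case.bac_permille == 1.84

    def test_in_hospital_bac_preferred_over_paramedic(self):
        visit = _visit(labs=[LabResult("ethanol_blood", 50.0, "mmol_per_L", False)])
        ev = adj.Evidence(signs_present=True, paramedic_bac_mmol=30.0)
        case = adj.adjudicate_visit(visit, ev)
        assert case.bac_mmol == 50.0

    def test_subthreshold_ethanol_alone_rejected_without_history(self):
        visit = _visit(labs=[LabResult("ethanol_blood", 5.0, "mmol_per_L", False)])
        case = adj.adjudicate_visit(visit, adj.Evidence(signs_present=True))
        assert not case.confirmed

    def test_subthreshold_override_with_history_and_signs(self):
        visit = _visit(labs=[LabResult("ethanol_blood", 5.0, "mmol_per_L", False)])
        ev = adj.Evidence(signs_present=True, history_of_use=True,
                          reported_substances=("ethanol",))
        case = adj.adjudicate_visit(visit, ev)
        assert case.confirmed
        assert case.primary_intoxicant == "ethanol"

    def test_denied_use_without_signs_rejected(self):
        # matched by the free word search, but review finds nothing acute
        case = adj.adjudicate_visit(_visit(), adj.Evidence(history_of_use=True))
        assert not case.confirmed

    def test_non_ethanol_positive_lab_confirms(self):
        visit = _visit(labs=[LabResult("amphetamines_urine", 1.0,
                                       "qualitative_pos_neg", True)])
        case = adj.adjudicate_visit(visit, adj.Evidence())
        assert case.confirmed
        assert case.primary_intoxicant == "amphetamines"


class TestRecurrence:
    def _case(self, vid, pid, date):
        from edtox.records import ConfirmedCase
        return ConfirmedCase(vid, pid, date, confirmed=True)

    def test_single_visit_is_index(self):
        cases = [self._case("V1", "P1", D(2019, 3, 3))]
        table = adj.link_recurrence(cases)
        assert table.loc[0, "bucket"] == "one"
        assert cases[0].is_index_visit

    def test_earliest_visit_is_index(self):
        cases = [self._case("V2", "P1", D(2019, 8, 9)),
                 self._case("V1", "P1", D(2019, 3, 3))]
        table = adj.link_recurrence(cases)
        assert table.loc[0, "index_visit_id"] == "V1"
        assert table.loc[0, "bucket"] == "two_or_more"

    def test_date_tie_broken_by_visit_id(self):
        cases = [self._case("V9", "P1", D(2019, 3, 3)),
                 self._case("V2", "P1", D(2019, 3, 3))]
        table = adj.link_recurrence(cases)
        assert table.loc[0, "index_visit_id"] == "V2"


def test_adjudication_is_order_independent(pilot_run):
    import random

    cohort, candidates = pilot_run.cohort, pilot_run.candidates
    evidence = pilot_run.result.evidence
    baseline = {(c.visit_id, c.confirmed, c.primary_intoxicant)
                for c in pilot_run.cases}
    shuffled_ids = sorted(candidates.candidate_visits)
    random.Random(0).shuffle(shuffled_ids)
    index = cohort.visit_index()
    redo = {
        (vid,
         adj.adjudicate_visit(index[vid], evidence.get(vid)).confirmed,
         adj.adjudicate_visit(index[vid], evidence.get(vid)).primary_intoxicant)
        for vid in shuffled_ids
    }
    assert redo == baseline
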