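"""Five-criterion case definition, weak-evidence grading, and the verdict map."""

import itertools
from datetime import date, datetime, time, timedelta

import pytest

from sirvanlp.case_classification import (
    PatientEvidence,
    aggregate_findings,
    classify_case,
    evaluate_case_definition,
    evaluate_weak_evidence,
    verdict_from_flags,
)
from sirvanlp.cohort import DiagnosisRecord, IndexEvent, VaccinationRecord
from sirvanlp.note_indexing import ConceptMention
from sirvanlp.relation_extraction import AnatomicFinding, CausalFinding, TemporalFinding
from sirvanlp.terminology import SemanticClass

INDEX = date(2017, 4, 1)


def _event(arm="left", vaccine="flu"):
    return IndexEvent(
        vaccination=VaccinationRecord(
            patient_id="p1",
            admin_datetime=datetime.combine(INDEX, time(9, 0)),
            vaccine_name=vaccine,
            route="IM",
            site_laterality=arm,
            in_facility=True,
            patient_birth_date=date(1960, 1, 1),
        )
    )


def _mention(span=(0, 4), sent=0):
    return ConceptMention(
        entry_id="sym_pain",
        semantic_class=SemanticClass.SHOULDER_SYMPTOM,
        char_span=span,
        sentence_index=sent,
    )


def _dt(day):
    return datetime.combine(INDEX + timedelta(days=day), time(11, 0))


def _anat(day=45, laterality="left", resolved=False, note_id=None):
    return AnatomicFinding(
        injury_mention=_mention(),
        laterality=laterality,
        body_location="shoulder",
        region="shoulder",
        resolved=resolved,
        note_id=note_id or f"n{day}",
        note_datetime=_dt(day),
    )


def _temp(day=45, offset=2, duration=42, resolved=False):
    return TemporalFinding(
        injury_mention=_mention(),
        onset_date=INDEX + timedelta(days=offset) if offset is not None else None,
        onset_day_offset=offset,
        duration_days=duration,
        resolved=resolved,
        note_id=f"n{day}",
        note_datetime=_dt(day),
    )


def _caus(day=45, cause="vaccination", scope="intra_sentence", vaccine_name="flu"):
    return CausalFinding(
        injury_mention=_mention(),
        cause_type=cause,
        cause_mention=_mention(span=(10, 14)),
        trigger="trg_002",
        scope=scope,
        vaccine_name=vaccine_name if cause == "vaccination" else None,
        note_id=f"n{day}",
        note_datetime=_dt(day),
    )


def _evidence(anatomic=(), temporal=(), causal=(), codes=(), arm="left", vaccine="flu"):
    return PatientEvidence(
        index_event=_event(arm, vaccine),
        anatomic=list(anatomic),
        temporal=list(temporal),
        causal=list(causal),
        code_timeline=list(codes),
    )


class TestCaseDefinition:
    def test_textbook_positive_meets_all_five(self):
        r = evaluate_case_definition(
            _evidence(anatomic=[_anat()], temporal=[_temp()], causal=[_caus()])
        )
        assert r.flags() == (True,) * 5

    def test_other_cause_defeats_c4(self):
        r = evaluate_case_definition(
            _evidence(
                anatomic=[_anat()],
                temporal=[_temp()],
                causal=[_caus(), _caus(cause="accident")],
            )
        )
        assert not r.c4_vaccination_cause_no_other

    def test_unknown_cause_does_not_defeat_c4(self):
        r = evaluate_case_definition(
            _evidence(
                anatomic=[_anat()],
                temporal=[_temp()],
                causal=[_caus(), _caus(cause="unknown")],
            )
        )
        assert r.c4_vaccination_cause_no_other

    def test_any_onset_in_window_satisfies_c3(self):
        r = evaluate_case_definition(
            _evidence(
                anatomic=[_anat()],
                temporal=[_temp(offset=45, duration=None), _temp(offset=3, duration=None)],
                causal=[_caus()],
            )
        )
        assert r.c3_onset_within_7d

    def test_unknown_laterality_fails_c2_bilateral_passes(self):
        r_unknown = evaluate_case_definition(
            _evidence(anatomic=[_anat(laterality="unknown")], temporal=[_temp()],
                      causal=[_caus()])
        )
        assert not r_unknown.c2_laterality_match
        r_bilat = evaluate_case_definition(
            _evidence(anatomic=[_anat(laterality="bilateral")], temporal=[_temp()],
                      causal=[_caus()])
        )
        assert r_bilat.c2_laterality_match

    def test_resolved_only_findings_fail_c1(self):
        r = evaluate_case_definition(
            _evidence(anatomic=[_anat(resolved=True)], temporal=[_temp(resolved=True)],
                      causal=[_caus()])
        )
        assert not r.c1_injury_confirmed

    def test_c5_from_code_persistence_alone(self):
        codes = [
            DiagnosisRecord(
                patient_id="p1", date=INDEX + timedelta(days=60),
                icd10cm_code="M75.42", code_laterality="left",
                encounter_id="e1", group="A",
            )
        ]
        r = evaluate_case_definition(
            _evidence(
                anatomic=[_anat(day=10)],
                temporal=[_temp(day=10, offset=2, duration=8)],
                causal=[_caus(day=10)],
                codes=codes,
            )
        )
        assert r.c5_duration_gt_30d

    def test_empty_evidence_all_false_except_nothing(self):
        r = evaluate_case_definition(_evidence())
        assert r.flags() == (False,) * 5


class TestWeakEvidence:
    def test_cross_sentence_early_note_trips_w1_w2(self):
        ev = _evidence(
            anatomic=[_anat(day=20), _anat(day=45)],
            temporal=[_temp(day=20, offset=2, duration=18)],
            causal=[_caus(day=20, scope="cross_sentence")],
        )
        w = evaluate_weak_evidence(ev, evaluate_case_definition(ev))
        assert w.flags() == (True, True, False)
        assert classify_case(ev).verdict == "possible"

    def test_intra_late_matching_vaccine_all_false(self):
        ev = _evidence(anatomic=[_anat()], temporal=[_temp()], causal=[_caus(day=40)])
        w = evaluate_weak_evidence(ev, evaluate_case_definition(ev))
        assert w.flags() == (False, False, False)
        assert classify_case(ev).verdict == "definite"

    def test_vaccine_mismatch_trips_w3(self):
        ev = _evidence(
            anatomic=[_anat()],
            temporal=[_temp()],
            causal=[_caus(vaccine_name="flu")],
            vaccine="zoster",
        )
        w = evaluate_weak_evidence(ev, evaluate_case_definition(ev))
        assert w.flags() == (False, False, True)
        assert classify_case(ev).verdict == "probable"

    def test_generic_vaccine_name_is_not_a_mismatch(self):
        ev = _evidence(
            anatomic=[_anat()],
            temporal=[_temp()],
            causal=[_caus(vaccine_name=None)],
            vaccine="zoster",
        )
        w = evaluate_weak_evidence(ev, evaluate_case_definition(ev))
        assert not w.w3_vaccine_mismatch

    def test_no_vaccination_cause_all_false(self):
        ev = _evidence(anatomic=[_anat()], causal=[_caus(cause="accident")])
        assert evaluate_weak_evidence(ev).flags() == (False, False, False)

    def test_late_attribution_clears_w2(self):
        ev = _evidence(
            anatomic=[_anat()],
            temporal=[_temp()],
            causal=[_caus(day=20), _caus(day=40)],
        )
        w = evaluate_weak_evidence(ev, evaluate_case_definition(ev))
        assert not w.w2_cause_only_within_30d


class TestVerdictMap:
    def test_exhaustive_criterion_combinations(self):
        """All 2^8 combinations of 5 case-definition and 3 weak criteria map
        to the specified verdict (negative unless all five; else by weak count)."""
        for case_flags in itertools.product([False, True], repeat=5):
            for weak_flags in itertools.product([False, True], repeat=3):
                got = verdict_from_flags(case_flags, weak_flags)
                if not all(case_flags):
                    assert got == "negative"
                else:
                    n = sum(weak_flags)
                    expected = {0: "definite", 1: "probable"}.get(n, "possible")
                    assert got == expected

    def test_weak_criterion_monotone_toward_weaker_verdicts(self):
        order = {"definite": 0, "probable": 1, "possible": 2}
        for weak in itertools.product([False, True], repeat=3):
            v = verdict_from_flags((True,) * 5, weak)
            for i in range(3):
                if not weak[i]:
                    flipped = list(weak)
                    flipped[i] = True
                    v2 = verdict_from_flags((True,) * 5, tuple(flipped))
                    assert order[v2] >= order[v]


class TestAggregation:
    def test_union_semantics_across_notes(self):
        ev = aggregate_findings(
            _event(), [_anat(day=10)], [_temp(day=40)], [_caus(day=10)]
        )
        assert len(ev.anatomic) == 1 and len(ev.temporal) == 1 and len(ev.causal) == 1

    def test_findings_outside_window_dropped(self):
        ev = aggregate_findings(_event(), [_anat(day=200)], [], [])
        assert ev.anatomic == []

    def test_conflicting_lateralities_all_retained(self):
        ev = aggregate_findings(
            _event(),
            [_anat(day=10, laterality="left"), _anat(day=20, laterality="right"),
             _anat(day=30, laterality="bilateral")],
            [], [],
        )
        assert sorted(f.laterality for f in ev.anatomic) == [
            "bilateral", "left", "right"
        ]

    def test_zero_findings_classified_negative(self):
        ev = aggregate_findings(_event(), [], [], [])
        assert classify_case(ev).verdict == "negative"

    def test_negated_only_note_never_changes_verdict(self, make_note, lexicon):
        from sirvanlp.relation_extraction import (
            extract_anatomic,
            extract_causal,
            extract_temporal,
        )

        base = _evidence(anatomic=[_anat()], temporal=[_temp()], causal=[_caus()])
        before = classify_case(base).verdict
        idx = make_note("Denies any shoulder pain. No injury or trauma.")
        extra_anat = extract_anatomic(idx, lexicon)
        extra_temp = extract_temporal(idx, index_date=INDEX)
        extra_caus = extract_causal(idx, lexicon)
        assert extra_anat == [] and extra_temp == [] and extra_caus == []
        combined = _evidence(
            anatomic=[_anat()] + extra_anat,
            temporal=[_temp()] + extra_temp,
            causal=[_caus()] + extra_caus,
        )
        assert classify_case(combined).verdict == before
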