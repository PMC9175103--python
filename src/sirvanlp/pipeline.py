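"""End-to-end orchestration: cohort -> index -> extract -> classify -> report.

Produces one case row per index event surviving the structured funnel, a
funnel flow table, and a summary of NLP component yields (shoulder injury
identified, laterality identified/mismatch, cause identified with and
without unknown, onset identified, duration >30 days, and SIRVA cases by
verdict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta

from sirvanlp.case_classification import (
    CaseClassification,
    PatientEvidence,
    aggregate_findings,
    classify_case,
)
from sirvanlp.cohort import (
    DiagnosisRecord,
    EncounterRecord,
    IndexEvent,
    MembershipInterval,
    VaccinationRecord,
    funnel_report,
    run_funnel,
)
from sirvanlp.note_indexing import ClinicalNote, IndexedNote, index_note
from sirvanlp.relation_extraction import (
    extract_anatomic,
    extract_causal,
    extract_temporal,
)
from sirvanlp.terminology import Lexicon, default_lexicon

logger = logging.getLogger("sirvanlp")


@dataclass
class CaseRow:
    patient_id: str
    index_date: str
    verdict: str
    case_flags: tuple[bool, ...]
    weak_flags: tuple[bool, bool, bool]
    supporting_notes: list[str]
    classification: CaseClassification


@dataclass
class PipelineResult:
    events: list[IndexEvent]
    cases: list[CaseRow]
    funnel: dict[str, int]
    summary: dict[str, float | int]
    evidence: dict[str, PatientEvidence] = field(default_factory=dict)


def _pct(n: int, d: int) -> float:
    from sirvanlp.metrics import round_half_up

    return round_half_up(100.0 * n / d) if d else 0.0


def run_pipeline(
    vaccinations: list[VaccinationRecord],
    memberships: list[MembershipInterval],
    encounters: list[EncounterRecord],
    diagnoses: list[DiagnosisRecord],
    notes: list[ClinicalNote],
    lexicon: Lexicon | None = None,
    subpopulation: bool = False,
    strict_anatomy: bool = True,
    window_days: int = 180,
) -> PipelineResult:
    """Run the full pipeline over in-memory tables and notes."""
    lexicon = lexicon or default_lexicon()
    events = run_funnel(
        vaccinations, memberships, encounters, diagnoses, subpopulation=subpopulation
    )
    included = [e for e in events if e.decision == "included"]
    logger.info("funnel: %d events in, %d included", len(events), len(included))

    notes_by_patient: dict[str, list[ClinicalNote]] = {}
    for n in notes:
        notes_by_patient.setdefault(n.patient_id, []).append(n)
    dx_by_patient: dict[str, list[DiagnosisRecord]] = {}
    for d in diagnoses:
        if d.group:
            dx_by_patient.setdefault(d.patient_id, []).append(d)

    cases: list[CaseRow] = []
    evidence_map: dict[str, PatientEvidence] = {}
    n_injury = n_lat = n_lat_mismatch = 0
    n_cause_incl = n_cause_excl = n_onset = n_duration = 0

    for event in included:
        idx = event.index_date
        lo, hi = idx, idx + timedelta(days=window_days)
        anatomic, temporal, causal = [], [], []
        for note in sorted(
            notes_by_patient.get(event.patient_id, []), key=lambda n: n.note_id
        ):
            if not (lo <= note.note_datetime.date() <= hi):
                continue
            indexed: IndexedNote = index_note(note, lexicon)
            anatomic.extend(extract_anatomic(indexed, lexicon))
            temporal.extend(extract_temporal(indexed, index_date=idx))
            causal.extend(
                extract_causal(indexed, lexicon, strict_anatomy=strict_anatomy)
            )
        evidence = aggregate_findings(
            event,
            anatomic,
            temporal,
            causal,
            code_timeline=dx_by_patient.get(event.patient_id, []),
            window_days=window_days,
        )
        evidence_map[event.patient_id] = evidence
        cls = classify_case(evidence)

        if anatomic:
            n_injury += 1
            lats = {f.laterality for f in anatomic} - {"unknown"}
            if lats:
                n_lat += 1
                arm = event.vaccination.site_laterality
                if not any(l == arm or l == "bilateral" for l in lats):
                    n_lat_mismatch += 1
            if causal:
                n_cause_incl += 1
                if any(f.cause_type != "unknown" for f in causal):
                    n_cause_excl += 1
            if any(
                f.onset_day_offset is not None or f.onset_date is not None
                for f in temporal
            ):
                n_onset += 1
            if cls.case_def.c5_duration_gt_30d:
                n_duration += 1

        supporting = sorted(
            {nid for ids in cls.case_def.supporting.values() for nid in ids}
        )
        cases.append(
            CaseRow(
                patient_id=event.patient_id,
                index_date=idx.isoformat(),
                verdict=cls.verdict,
                case_flags=cls.case_def.flags(),
                weak_flags=cls.weak.flags(),
                supporting_notes=supporting,
                classification=cls,
            )
        )

    verdicts = [c.verdict for c in cases]
    n_presumptive = len(included)
    summary = {
        "n_presumptive": n_presumptive,
        "shoulder_injury_identified": n_injury,
        "shoulder_injury_identified_pct": _pct(n_injury, n_presumptive),
        "laterality_identified": n_lat,
        "laterality_identified_pct_of_injury": _pct(n_lat, n_injury),
        "laterality_mismatch": n_lat_mismatch,
        "cause_identified_incl_unknown": n_cause_incl,
        "cause_identified_excl_unknown": n_cause_excl,
        "onset_identified": n_onset,
        "onset_identified_pct_of_injury": _pct(n_onset, n_injury),
        "duration_gt_30d": n_duration,
        "sirva_cases": sum(1 for v in verdicts if v != "negative"),
        "definite": verdicts.count("definite"),
        "probable": verdicts.count("probable"),
        "possible": verdicts.count("possible"),
        "negative": verdicts.count("negative"),
    }
    return PipelineResult(
        events=events,
        cases=cases,
        funnel=funnel_report(events),
        summary=summary,
        evidence=evidence_map,
    )


def cases_to_rows(result: PipelineResult) -> list[dict]:
    """Delimited-table view: one row per index event with per-criterion flags."""
    rows = []
    for c in result.cases:
        c1, c2, c3, c4, c5 = c.case_flags
        w1, w2, w3 = c.weak_flags
        rows.append(
            {
                "patient_id": c.patient_id,
                "index_date": c.index_date,
                "verdict": c.verdict,
                "c1_injury_confirmed": c1,
                "c2_laterality_match": c2,
                "c3_onset_within_7d": c3,
                "c4_vaccination_cause_no_other": c4,
                "c5_duration_gt_30d": c5,
                "w1_cross_sentence_only": w1,
                "w2_cause_only_within_30d": w2,
                "w3_vaccine_mismatch": w3,
                "supporting_notes": ";".join(c.supporting_notes),
            }
        )
    return rows


def explain_case(result: PipelineResult, patient_id: str) -> dict:
    """Full evidence chain for one case (for --explain)."""
    ev = result.evidence.get(patient_id)
    if ev is None:
        return {"patient_id": patient_id, "error": "not in included cohort"}
    row = next((c for c in result.cases if c.patient_id == patient_id), None)
    return {
        "patient_id": patient_id,
        "index_date": ev.index_date.isoformat(),
        "verdict": row.verdict if row else None,
        "anatomic": [
            {
                "note_id": f.note_id,
                "text_span": list(f.injury_mention.char_span),
                "laterality": f.laterality,
                "body_location": f.body_location,
                "resolved": f.resolved,
            }
            for f in ev.anatomic
        ],
        "temporal": [
            {
                "note_id": f.note_id,
                "onset_date": f.onset_date.isoformat() if f.onset_date else None,
                "onset_day_offset": f.onset_day_offset,
                "duration_days": f.duration_days,
                "resolved": f.resolved,
            }
            for f in ev.temporal
        ],
        "causal": [
            {
                "note_id": f.note_id,
                "cause_type": f.cause_type,
                "scope": f.scope,
                "trigger": f.trigger,
                "vaccine_name": f.vaccine_name,
            }
            for f in ev.causal
        ],
        "supporting": row.classification.case_def.supporting if row else {},
    }
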