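"""Patient-level SIRVA case classification.

All findings extracted from a patient's notes in days 0-180 after a
vaccination are pooled (maximum-sensitivity aggregation: every candidate
onset and cause is retained) and scored against the five-criterion case
definition:

  c1  a shoulder injury is confirmed by non-negated, non-resolved signs,
      symptoms, or diagnosis;
  c2  the injury laterality matches the vaccinated arm (bilateral counts as
      matching; unknown fails);
  c3  some candidate onset falls within days 0-7 after vaccination;
  c4  vaccination is an identified cause and no non-vaccination cause
      (accident / work / other medical condition / exercise / daily
      activity) is present — an unknown cause does not disqualify;
  c5  the injury lasted more than 30 days after vaccination (an extracted
      duration, an injury finding in a note dated >30 days post-index, or a
      laterality-matched diagnosis code in days 31-180).

A case meeting all five is then graded by three weak-evidence criteria:
  w1  the vaccination cause was found only by cross-sentence search;
  w2  every vaccination attribution comes from a note dated <= 30 days
      post-vaccination (none later);
  w3  the vaccine named in a note mismatches the vaccination record.

Verdict: negative if any of c1-c5 fails; otherwise definite (0 weak
criteria met), probable (exactly 1), or possible (2 or more).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

from sirvanlp.cohort import DiagnosisRecord, IndexEvent, _laterality_matches
from sirvanlp.relation_extraction import (
    AnatomicFinding,
    CausalFinding,
    TemporalFinding,
)

OTHER_CAUSE_TYPES = frozenset(
    {"accident", "work", "other_medical_condition", "exercise", "daily_activity"}
)


@dataclass
class PatientEvidence:
    """All findings for one vaccination event, pooled across notes in days 0-180."""

    index_event: IndexEvent
    anatomic: list[AnatomicFinding] = field(default_factory=list)
    temporal: list[TemporalFinding] = field(default_factory=list)
    causal: list[CausalFinding] = field(default_factory=list)
    code_timeline: list[DiagnosisRecord] = field(default_factory=list)

    @property
    def index_date(self) -> date:
        return self.index_event.index_date


@dataclass
class CaseDefinitionResult:
    c1_injury_confirmed: bool
    c2_laterality_match: bool
    c3_onset_within_7d: bool
    c4_vaccination_cause_no_other: bool
    c5_duration_gt_30d: bool
    supporting: dict[str, list[str]] = field(default_factory=dict)

    def all_met(self) -> bool:
        return (
            self.c1_injury_confirmed
            and self.c2_laterality_match
            and self.c3_onset_within_7d
            and self.c4_vaccination_cause_no_other
            and self.c5_duration_gt_30d
        )

    def flags(self) -> tuple[bool, ...]:
        return (
            self.c1_injury_confirmed,
            self.c2_laterality_match,
            self.c3_onset_within_7d,
            self.c4_vaccination_cause_no_other,
            self.c5_duration_gt_30d,
        )


@dataclass
class WeakEvidenceResult:
    w1_cross_sentence_only: bool
    w2_cause_only_within_30d: bool
    w3_vaccine_mismatch: bool

    def count(self) -> int:
        return sum(
            (self.w1_cross_sentence_only, self.w2_cause_only_within_30d,
             self.w3_vaccine_mismatch)
        )

    def flags(self) -> tuple[bool, bool, bool]:
        return (
            self.w1_cross_sentence_only,
            self.w2_cause_only_within_30d,
            self.w3_vaccine_mismatch,
        )


@dataclass
class CaseClassification:
    verdict: str  # definite | probable | possible | negative
    case_def: CaseDefinitionResult
    weak: WeakEvidenceResult


def _in_window(evidence_date: date, index: date, lo: int = 0, hi: int = 180) -> bool:
    k = (evidence_date - index).days
    return lo <= k <= hi


def aggregate_findings(
    index_event: IndexEvent,
    anatomic: list[AnatomicFinding],
    temporal: list[TemporalFinding],
    causal: list[CausalFinding],
    code_timeline: list[DiagnosisRecord] | None = None,
    window_days: int = 180,
) -> PatientEvidence:
    """Pool per-note findings for one vaccination event.

    Findings outside days 0..``window_days`` of the index date are dropped;
    everything else is retained — including conflicting lateralities and
    multiple candidate onsets — so the audit trail is complete and the
    maximum-sensitivity onset rule can operate at evaluation time.
    """
    idx = index_event.index_date

    def keep(f) -> bool:
        return _in_window(f.note_datetime.date(), idx, 0, window_days)

    return PatientEvidence(
        index_event=index_event,
        anatomic=[f for f in anatomic if keep(f)],
        temporal=[f for f in temporal if keep(f)],
        causal=[f for f in causal if keep(f)],
        code_timeline=list(code_timeline or []),
    )


def _resolved_keys(evidence: PatientEvidence) -> set:
    keys = set()
    for f in evidence.anatomic:
        if f.resolved:
            keys.add((f.note_id, f.injury_mention.key()))
    for f in evidence.temporal:
        if f.resolved:
            keys.add((f.note_id, f.injury_mention.key()))
    return keys


def evaluate_case_definition(evidence: PatientEvidence) -> CaseDefinitionResult:
    """Apply the five-criterion case definition to pooled evidence."""
    idx = evidence.index_date
    arm = evidence.index_event.vaccination.site_laterality
    resolved = _resolved_keys(evidence)

    active = [
        f
        for f in evidence.anatomic
        if (f.note_id, f.injury_mention.key()) not in resolved
    ]
    c1 = bool(active)
    supporting: dict[str, list[str]] = {"c1": [f.note_id for f in active]}

    matching = [
        f
        for f in active
        if f.laterality == arm or f.laterality == "bilateral"
    ]
    c2 = bool(matching)
    supporting["c2"] = [f.note_id for f in matching]

    # Maximum-sensitivity onset rule: ANY candidate onset in [0, 7] suffices.
    onsets = []
    for f in evidence.temporal:
        if f.onset_day_offset is not None:
            onsets.append((f.onset_day_offset, f.note_id))
        elif f.onset_date is not None:
            onsets.append(((f.onset_date - idx).days, f.note_id))
    hits = [nid for off, nid in onsets if 0 <= off <= 7]
    c3 = bool(hits)
    supporting["c3"] = hits

    vax_causes = [f for f in evidence.causal if f.cause_type == "vaccination"]
    other_causes = [f for f in evidence.causal if f.cause_type in OTHER_CAUSE_TYPES]
    c4 = bool(vax_causes) and not other_causes
    supporting["c4"] = [f.note_id for f in vax_causes]

    duration_hits: list[str] = []
    for f in evidence.temporal:
        if f.duration_days is not None and f.duration_days > 30 and not f.resolved:
            duration_hits.append(f.note_id)
    for f in active:
        if (f.note_datetime.date() - idx).days > 30:
            duration_hits.append(f.note_id)
    for d in evidence.code_timeline:
        k = (d.date - idx).days
        if 31 <= k <= 180 and _laterality_matches(d.code_laterality, arm):
            duration_hits.append(d.encounter_id)
    c5 = bool(duration_hits)
    supporting["c5"] = duration_hits

    return CaseDefinitionResult(
        c1_injury_confirmed=c1,
        c2_laterality_match=c2,
        c3_onset_within_7d=c3,
        c4_vaccination_cause_no_other=c4,
        c5_duration_gt_30d=c5,
        supporting=supporting,
    )


def evaluate_weak_evidence(
    evidence: PatientEvidence,
    case_def: CaseDefinitionResult | None = None,
) -> WeakEvidenceResult:
    """Apply the three weak-evidence criteria.

    Only meaningful when a vaccination cause exists (c4 true); otherwise the
    all-false result is returned.
    """
    vax_causes = [f for f in evidence.causal if f.cause_type == "vaccination"]
    if not vax_causes or (case_def is not None and not case_def.all_met()):
        return WeakEvidenceResult(False, False, False)
    idx = evidence.index_date

    w1 = all(f.scope == "cross_sentence" for f in vax_causes)
    w2 = all((f.note_datetime.date() - idx).days <= 30 for f in vax_causes)

    recorded = evidence.index_event.vaccination.vaccine_name
    w3 = any(
        f.vaccine_name is not None and recorded and f.vaccine_name != recorded
        for f in vax_causes
    )
    return WeakEvidenceResult(w1, w2, w3)


def classify_case(evidence: PatientEvidence) -> CaseClassification:
    """Negative unless all five case-definition criteria hold; otherwise
    definite / probable / possible by the number of weak criteria met
    (0 / 1 / >=2)."""
    case_def = evaluate_case_definition(evidence)
    weak = evaluate_weak_evidence(evidence, case_def)
    if not case_def.all_met():
        verdict = "negative"
    else:
        n = weak.count()
        verdict = "definite" if n == 0 else ("probable" if n == 1 else "possible")
    return CaseClassification(verdict=verdict, case_def=case_def, weak=weak)


def verdict_from_flags(case_flags: tuple[bool, ...], weak_flags: tuple[bool, ...]) -> str:
    """Verdict implied by raw criterion booleans (specification form)."""
    if not all(case_flags):
        return "negative"
    n = sum(weak_flags)
    return "definite" if n == 0 else ("probable" if n == 1 else "possible")
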