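"""Structured-data cohort funnel.

Selects eligible vaccinations (intramuscular arm injections at a facility,
age >= 3, continuous membership 180 days either side of the index date),
identifies presumptive shoulder injuries from laterality-matched ICD-10-CM
codes in the follow-up window with a clean 180-day lookback, applies the
day-0 encounter rules that screen out pre-existing conditions, and finally
the four training/validation subpopulation criteria.  Every excluded event
records exactly one first-failing reason, and stage counts are reported as
a funnel table.

Day arithmetic: day k = index date + k calendar days; windows are inclusive
at both ends ("days 31 to 180" = [31, 180]; "within 180 days before" =
[-180, -1]).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from importlib import resources


@dataclass(frozen=True)
class VaccinationRecord:
    patient_id: str
    admin_datetime: datetime
    vaccine_name: str  # normalized product name ("flu", "tdap", ...)
    route: str  # "IM" expected
    site_laterality: str  # left | right | unknown
    in_facility: bool
    patient_birth_date: date

    @property
    def index_date(self) -> date:
        return self.admin_datetime.date()


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: date
    icd10cm_code: str
    code_laterality: str  # left | right | bilateral | none
    encounter_id: str
    group: str  # A | B | C | D | "" (not a shoulder code)


@dataclass(frozen=True)
class EncounterRecord:
    encounter_id: str
    patient_id: str
    datetime: datetime
    type: str  # office | urgent_care | emergency | virtual | other


@dataclass(frozen=True)
class MembershipInterval:
    patient_id: str
    start_date: date
    end_date: date


@dataclass
class IndexEvent:
    vaccination: VaccinationRecord
    decision: str = "included"  # included | excluded
    exclusion_reason: str | None = None
    stage_flags: dict = field(default_factory=dict)

    @property
    def patient_id(self) -> str:
        return self.vaccination.patient_id

    @property
    def index_date(self) -> date:
        return self.vaccination.index_date

    def exclude(self, reason: str) -> None:
        if self.decision == "included":
            self.decision = "excluded"
            self.exclusion_reason = reason

    def day_of(self, d: date) -> int:
        return (d - self.index_date).days


# ---------------------------------------------------------------------------
# Code groups

@dataclass(frozen=True)
class CodeGroupRule:
    code_prefix: str
    group: str  # A | B | C | D
    laterality_char_position: int  # 0-based index of laterality digit; -1 none


def load_code_groups(path=None) -> list[CodeGroupRule]:
    """Load the shoulder code list (prefix, group, laterality digit position).

    The shipped default is a documented, editable stand-in built from
    ICD-10-CM shoulder chapters (M75.* lesions, M25.51* pain, S4x.* external
    injuries) with laterality decoded from the code's laterality character.
    """
    if path is None:
        ref = resources.files("sirvanlp.data").joinpath("code_groups.csv")
        with resources.as_file(ref) as p:
            return load_code_groups(p)
    rules = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                CodeGroupRule(
                    code_prefix=row["code_prefix"],
                    group=row["group"],
                    laterality_char_position=int(row["laterality_char_position"]),
                )
            )
    return rules


_LATERALITY_DIGIT = {"1": "right", "2": "left", "3": "bilateral"}


def classify_code(code: str, rules: list[CodeGroupRule]) -> tuple[str, str]:
    """Return (group, laterality) for an ICD-10-CM code; group "" if unlisted.

    The longest matching prefix wins; laterality is decoded from the code's
    laterality character per ICD-10-CM convention (1=right, 2=left,
    3=bilateral, other/missing=none).
    """
    compact = code.replace(".", "")
    best: CodeGroupRule | None = None
    for r in rules:
        if compact.startswith(r.code_prefix.replace(".", "")):
            if best is None or len(r.code_prefix) > len(best.code_prefix):
                best = r
    if best is None:
        return ("", "none")
    lat = "none"
    pos = best.laterality_char_position
    if 0 <= pos < len(compact):
        lat = _LATERALITY_DIGIT.get(compact[pos], "none")
    return (best.group, lat)


def _laterality_matches(code_lat: str, vax_lat: str) -> bool:
    return code_lat == vax_lat or code_lat == "bilateral"


# ---------------------------------------------------------------------------
# Funnel stages

def _age_years(birth: date, on: date) -> int:
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def select_eligible_vaccinations(
    vaccinations: list[VaccinationRecord],
    memberships: list[MembershipInterval],
    min_age_years: int = 3,
) -> list[IndexEvent]:
    """Stage 1: intramuscular arm injections at a facility, age >= 3,
    membership covering [index-180, index+180]."""
    by_patient: dict[str, list[MembershipInterval]] = {}
    for m in memberships:
        by_patient.setdefault(m.patient_id, []).append(m)
    events = []
    for v in vaccinations:
        e = IndexEvent(vaccination=v)
        idx = v.index_date
        if v.route.upper() != "IM":
            e.exclude("route")
        elif not v.in_facility:
            e.exclude("setting")
        elif v.site_laterality not in ("left", "right"):
            e.exclude("no_laterality")
        elif _age_years(v.patient_birth_date, idx) < min_age_years:
            e.exclude("age")
        else:
            lo, hi = idx - timedelta(days=180), idx + timedelta(days=180)
            covered = any(
                m.start_date <= lo and m.end_date >= hi
                for m in by_patient.get(v.patient_id, [])
            )
            if not covered:
                e.exclude("membership")
        e.stage_flags["eligible"] = e.decision == "included"
        events.append(e)
    return events


def identify_presumptive_injury(
    events: list[IndexEvent],
    diagnoses: list[DiagnosisRecord],
) -> list[IndexEvent]:
    """Stage 2: laterality-matched shoulder code in days 0-180, no shoulder
    code in days -180..-1, and a laterality-matched code in days 31-180."""
    by_patient: dict[str, list[DiagnosisRecord]] = {}
    for d in diagnoses:
        if d.group:
            by_patient.setdefault(d.patient_id, []).append(d)
    for e in events:
        if e.decision == "excluded":
            continue
        codes = by_patient.get(e.patient_id, [])
        vax_lat = e.vaccination.site_laterality
        days = [(e.day_of(d.date), d) for d in codes]
        if any(-180 <= k <= -1 for k, _ in days):
            e.exclude("prior_shoulder")
        elif not any(
            0 <= k <= 180 and _laterality_matches(d.code_laterality, vax_lat)
            for k, d in days
        ):
            e.exclude("no_followup_code")
        elif not any(
            31 <= k <= 180 and _laterality_matches(d.code_laterality, vax_lat)
            for k, d in days
        ):
            e.exclude("no_31_180_code")
        e.stage_flags["presumptive"] = e.decision == "included"
    return events


def apply_day0_rules(
    event: IndexEvent,
    encounters: list[EncounterRecord],
    diagnoses: list[DiagnosisRecord],
) -> IndexEvent:
    """Stage 3: events with a day-0 shoulder code survive only when there
    are >= 2 timestamped day-0 encounters, the first carries no shoulder
    code and does not precede the vaccination, and a later encounter is an
    urgent-care / emergency / virtual visit."""
    if event.decision == "excluded":
        return event
    idx = event.index_date
    day0_codes = [
        d
        for d in diagnoses
        if d.patient_id == event.patient_id and d.group and d.date == idx
    ]
    if not day0_codes:
        event.stage_flags["day0"] = True
        return event
    day0_encs = [
        en
        for en in encounters
        if en.patient_id == event.patient_id and en.datetime.date() == idx
    ]
    if any(en.datetime is None for en in day0_encs):
        event.exclude("unordered_day0")
    elif len(day0_encs) < 2:
        event.exclude("day0_single_encounter")
    else:
        day0_encs.sort(key=lambda en: en.datetime)
        first = day0_encs[0]
        coded_encounters = {d.encounter_id for d in day0_codes}
        if first.encounter_id in coded_encounters:
            event.exclude("day0_first_encounter_coded")
        elif first.datetime < event.vaccination.admin_datetime:
            event.exclude("day0_encounter_before_vaccination")
        elif not any(
            en.type in ("urgent_care", "emergency", "virtual")
            for en in day0_encs[1:]
        ):
            event.exclude("day0_no_acute_visit")
    event.stage_flags["day0"] = event.decision == "included"
    return event


def apply_subpopulation_criteria(
    events: list[IndexEvent],
    diagnoses: list[DiagnosisRecord],
) -> list[IndexEvent]:
    """Stage 4 (training/validation subpopulation): no external-injury
    (group D) code within +/-180 days, no shoulder code on day 0, a shoulder
    code in days 1-30, and shoulder codes on >= 2 distinct dates in days
    31-180."""
    by_patient: dict[str, list[DiagnosisRecord]] = {}
    for d in diagnoses:
        if d.group:
            by_patient.setdefault(d.patient_id, []).append(d)
    for e in events:
        if e.decision == "excluded":
            continue
        codes = by_patient.get(e.patient_id, [])
        days = [(e.day_of(d.date), d) for d in codes]
        dates_31_180 = {d.date for k, d in days if 31 <= k <= 180}
        if any(d.group == "D" and -180 <= k <= 180 for k, d in days):
            e.exclude("external_injury")
        elif any(k == 0 for k, _ in days):
            e.exclude("day0_code")
        elif not any(1 <= k <= 30 for k, _ in days):
            e.exclude("no_1_30_code")
        elif len(dates_31_180) < 2:
            e.exclude("single_31_180_date")
        e.stage_flags["subpopulation"] = e.decision == "included"
    return events


def run_funnel(
    vaccinations: list[VaccinationRecord],
    memberships: list[MembershipInterval],
    encounters: list[EncounterRecord],
    diagnoses: list[DiagnosisRecord],
    subpopulation: bool = False,
    min_age_years: int = 3,
) -> list[IndexEvent]:
    """Run the full structured-data funnel in stage order."""
    events = select_eligible_vaccinations(vaccinations, memberships, min_age_years)
    events = identify_presumptive_injury(events, diagnoses)
    for e in events:
        apply_day0_rules(e, encounters, diagnoses)
    if subpopulation:
        events = apply_subpopulation_criteria(events, diagnoses)
    return events


def funnel_report(events: list[IndexEvent]) -> dict[str, int]:
    """Stage-count flow table: inputs, survivors per stage, exclusion reasons."""
    report: dict[str, int] = {"input": len(events)}
    for stage in ("eligible", "presumptive", "day0", "subpopulation"):
        n = sum(1 for e in events if e.stage_flags.get(stage))
        if any(stage in e.stage_flags for e in events):
            report[stage] = n
    report["included"] = sum(1 for e in events if e.decision == "included")
    for e in events:
        if e.exclusion_reason:
            report[f"excluded_{e.exclusion_reason}"] = (
                report.get(f"excluded_{e.exclusion_reason}", 0) + 1
            )
    return report
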