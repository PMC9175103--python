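"""Synthetic EHR population generator with token-level ground truth.

Generates structured tables (vaccinations, encounters, diagnoses,
membership) plus clinical notes built from template grammars with
slot-filled lexicon terms, so every patient's expected verdict, onset,
cause types, laterality, and gold mention spans are exact by construction.
Scenarios cover every discrimination the pipeline must make: the three
weak-evidence downgrades (cross-sentence-only causality, attribution only
within 30 days, vaccine-name mismatch), each single-criterion failure mode
of the case definition, and cohort-level exclusions.

Generation is grammar-based rather than free-form so that gold labels are
exact; it makes no attempt at realistic clinical discourse.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

from sirvanlp.cohort import (
    DiagnosisRecord,
    EncounterRecord,
    MembershipInterval,
    VaccinationRecord,
    classify_code,
    load_code_groups,
)
from sirvanlp.note_indexing import ClinicalNote

SCENARIOS = (
    "definite",
    "probable_w1",
    "probable_w2",
    "probable_w3",
    "possible",
    "negative_no_onset",
    "negative_other_cause",
    "negative_negated",
    "negative_laterality",
    "negative_short_duration",
    "non_case_control",
)

#: Verdict implied by each scenario once the patient passes the cohort
#: funnel; None means the patient is excluded by the funnel itself.
EXPECTED_VERDICT = {
    "definite": "definite",
    "probable_w1": "probable",
    "probable_w2": "probable",
    "probable_w3": "probable",
    "possible": "possible",
    "negative_no_onset": "negative",
    "negative_other_cause": "negative",
    "negative_negated": "negative",
    "negative_laterality": "negative",
    "negative_short_duration": "negative",
    "non_case_control": None,
}

EXPECTED_WEAK = {
    "definite": (False, False, False),
    "probable_w1": (True, False, False),
    "probable_w2": (False, True, False),
    "probable_w3": (False, False, True),
    "possible": (True, True, False),
}

EXPECTED_EXCLUSION = {"non_case_control": "prior_shoulder"}

#: Scenario mix approximating the strata proportions of a screened
#: presumptive population (positives dominate because the synthetic
#: population emulates the NLP-flagged stratum, not raw vaccinations).
DEFAULT_MIX = {
    "definite": 291,
    "probable_w1": 64,
    "probable_w2": 41,
    "probable_w3": 19,
    "possible": 52,
    "negative_no_onset": 26,
    "negative_other_cause": 26,
    "negative_negated": 26,
    "negative_laterality": 26,
    "negative_short_duration": 26,
    "non_case_control": 30,
}

_PRODUCT_PHRASES = {
    "flu": ["flu vaccine", "flu shot", "influenza vaccine"],
    "tdap": ["tdap", "tetanus shot"],
    "zoster": ["shingles vaccine", "shingrix"],
    "pneumococcal": ["pneumonia vaccine", "pneumovax"],
}
_PRODUCTS = sorted(_PRODUCT_PHRASES)

_OTHER_CAUSE_PHRASES = [
    "lifting groceries",
    "vacuuming",
    "moving furniture",
    "side sleeping",
]

_DISTRACTORS = [
    "Return if pain worsens or does not improve.",
    "Denies fever or chills.",
    "Medication list reviewed and reconciled.",
    "Vital signs stable.",
    "Hx of right knee pain, resolved.",
    "Allergies: none known.",
]


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.scenario_id!r}")


@dataclass
class GoldSpan:
    note_id: str
    label: str  # symptom | laterality | location | cause | vaccine | temporal
    start: int
    end: int
    text: str


@dataclass
class PatientTruth:
    patient_id: str
    scenario: str
    expected_verdict: str | None
    expected_weak: tuple[bool, bool, bool] | None
    expected_exclusion_reason: str | None
    expected_onset_offset: int | None
    expected_cause_types: tuple[str, ...]
    expected_laterality: str | None
    gold_spans: list[GoldSpan] = field(default_factory=list)


@dataclass
class SyntheticPopulation:
    vaccinations: list[VaccinationRecord]
    memberships: list[MembershipInterval]
    encounters: list[EncounterRecord]
    diagnoses: list[DiagnosisRecord]
    notes: list[ClinicalNote]
    truth: dict[str, PatientTruth]


# ---------------------------------------------------------------------------
# Note grammar

class _NoteBuilder:
    """Concatenates template parts while recording labeled slot offsets."""

    def __init__(self, note_id: str):
        self.note_id = note_id
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[GoldSpan] = []

    def add(self, text: str, label: str | None = None) -> "_NoteBuilder":
        if label:
            self.spans.append(
                GoldSpan(self.note_id, label, self.length, self.length + len(text), text)
            )
        self.parts.append(text)
        self.length += len(text)
        return self

    def text(self) -> str:
        return "".join(self.parts)


def _duration_phrase(days: int, rng: random.Random) -> str:
    if days % 7 == 0 and days >= 14:
        n = days // 7
        return rng.choice([f"for {n} weeks", f"for the last {n} weeks", f"× {n} weeks"])
    return rng.choice([f"for {days} days", f"× {days} days"])


def generate_note(
    scenario: str,
    ctx: dict,
    rng: random.Random,
) -> list[tuple[int, str, list[GoldSpan]]]:
    """Build the note set for one patient.

    ``ctx`` carries patient_id, side word, vaccine phrase (and mismatch
    phrase for probable_w3).  Returns a list of (day offset, text, gold
    spans) tuples.
    """
    side = ctx["side"].capitalize()
    vax = ctx["vax_phrase"]
    pid = ctx["patient_id"]
    notes: list[tuple[int, str, list[GoldSpan]]] = []

    def builder(day: int) -> _NoteBuilder:
        return _NoteBuilder(f"{pid}-n{day}")

    def persistence_note(day: int) -> None:
        b = builder(day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" persists, still limited with overhead reach.")
        notes.append((day, b.text(), b.spans))

    late_day = rng.choice([44, 45, 51, 52])
    onset = late_day - 7 * (late_day // 7)  # duration in whole weeks
    late_dur = late_day - onset
    early_day = rng.choice([14, 16])
    early_onset = rng.choice([1, 2])
    early_dur = early_day - early_onset

    if scenario == "definite":
        b = builder(late_day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(late_dur, rng), "temporal").add(" ")
        b.add(rng.choice(["due to", "caused by", "s/p"]), "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = onset

    elif scenario == "probable_w1":
        b = builder(late_day)
        b.add("Patient requesting an appointment for evaluation for ")
        b.add(ctx["side"], "laterality").add(" ")
        b.add("arm", "location").add(" ")
        b.add("pain", "symptom").add(". States experiencing ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(late_dur, rng), "temporal").add(" ")
        b.add("s/p", "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = onset

    elif scenario == "probable_w2":
        b = builder(early_day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(early_dur, rng), "temporal").add(" ")
        b.add("due to", "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((early_day, b.text(), b.spans))
        persistence_note(late_day)
        ctx["onset"] = early_onset

    elif scenario == "probable_w3":
        b = builder(late_day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(late_dur, rng), "temporal").add(" ")
        b.add("due to", "trigger").add(" ")
        b.add(ctx["mismatch_phrase"], "vaccine").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = onset

    elif scenario == "possible":
        b = builder(early_day)
        b.add("Patient requesting an appointment for evaluation for ")
        b.add(ctx["side"], "laterality").add(" ")
        b.add("arm", "location").add(" ")
        b.add("pain", "symptom").add(". States experiencing ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(early_dur, rng), "temporal").add(" ")
        b.add("s/p", "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((early_day, b.text(), b.spans))
        persistence_note(late_day)
        ctx["onset"] = early_onset

    elif scenario == "negative_no_onset":
        # Duration places onset well outside the 7-day window.
        b = builder(late_day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(f"for {late_day - 20} days", "temporal").add(" ")
        b.add("due to", "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = 20

    elif scenario == "negative_other_cause":
        b = builder(late_day)
        b.add(side, "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(late_dur, rng), "temporal").add(" ")
        b.add("due to", "trigger").add(" ")
        b.add(vax, "vaccine").add(". States ")
        b.add(ctx["side"], "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add("began after", "trigger").add(" ")
        b.add(rng.choice(_OTHER_CAUSE_PHRASES), "cause").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = onset

    elif scenario == "negative_negated":
        b = builder(late_day)
        b.add("Followup visit. Denies any ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "negated_symptom").add(". No ")
        b.add("injury", "negated_cause").add(" or ")
        b.add("trauma", "negated_cause").add(".")
        notes.append((late_day, b.text(), b.spans))

    elif scenario == "negative_laterality":
        other = "right" if ctx["side"] == "left" else "left"
        b = builder(late_day)
        b.add(other.capitalize(), "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "symptom").add(" ")
        b.add(_duration_phrase(late_dur, rng), "temporal").add(" ")
        b.add("due to", "trigger").add(" ")
        b.add(vax, "vaccine").add(".")
        notes.append((late_day, b.text(), b.spans))
        ctx["onset"] = onset

    elif scenario == "negative_short_duration":
        b = builder(40)
        b.add("In the past ")
        b.add(ctx["side"], "laterality").add(" ")
        b.add("shoulder", "location").add(" ")
        b.add("pain", "resolved_symptom").add(" ")
        b.add("lasting a few days", "temporal").add(" but resolved.")
        notes.append((40, b.text(), b.spans))

    elif scenario == "non_case_control":
        b = builder(10)
        b.add("Routine visit for hypertension. Medication refilled.")
        notes.append((10, b.text(), b.spans))

    else:  # pragma: no cover
        raise ScenarioError(scenario)
    return notes


# ---------------------------------------------------------------------------
# Structured data per patient

_LAT_DIGIT = {"right": "1", "left": "2"}


def _structured_for(
    scenario: str,
    pid: str,
    index_date: date,
    side: str,
    code_rules,
) -> tuple[list[EncounterRecord], list[DiagnosisRecord]]:
    digit = _LAT_DIGIT[side]
    encounters: list[EncounterRecord] = []
    diagnoses: list[DiagnosisRecord] = []

    def visit(day: int, code: str, etype: str = "office") -> None:
        eid = f"{pid}-e{day}"
        d = index_date + timedelta(days=day)
        encounters.append(
            EncounterRecord(
                encounter_id=eid,
                patient_id=pid,
                datetime=datetime.combine(d, time(10, 0)),
                type=etype,
            )
        )
        group, lat = classify_code(code, code_rules)
        diagnoses.append(
            DiagnosisRecord(
                patient_id=pid,
                date=d,
                icd10cm_code=code,
                code_laterality=lat,
                encounter_id=eid,
                group=group,
            )
        )

    # Cohort-passing stream: shoulder pain code in days 1-30, shoulder
    # lesion codes on two distinct dates in days 31-180.
    visit(5, f"M25.51{digit}", "urgent_care")
    visit(40, f"M75.4{digit}")
    visit(90, f"M75.4{digit}")
    if scenario == "non_case_control":
        visit(-60, f"M75.4{digit}")  # prior shoulder condition -> excluded
    return encounters, diagnoses


# ---------------------------------------------------------------------------
# Population generation

def generate_population(
    specs: list[ScenarioSpec] | None = None,
    seed: int = 0,
) -> SyntheticPopulation:
    """Generate a synthetic population; byte-identical for a fixed seed."""
    if specs is None:
        specs = [ScenarioSpec(s, n) for s, n in DEFAULT_MIX.items()]
    rng = random.Random(seed)
    code_rules = load_code_groups()

    vaccinations, memberships, encounters, diagnoses, notes = [], [], [], [], []
    truth: dict[str, PatientTruth] = {}
    counter = 0
    for spec in specs:
        srng = random.Random(
            (zlib.crc32(spec.scenario_id.encode()) + 7919 * seed + spec.seed)
            & 0x7FFFFFFF
        )
        for _ in range(spec.n):
            counter += 1
            pid = f"P{counter:05d}"
            side = srng.choice(["left", "right"])
            product = srng.choice(_PRODUCTS)
            index_date = date(2016, 4, 1) + timedelta(days=srng.randrange(0, 600))
            birth = date(1940 + srng.randrange(0, 60), 1 + srng.randrange(0, 12), 1 + srng.randrange(0, 28))
            vaccinations.append(
                VaccinationRecord(
                    patient_id=pid,
                    admin_datetime=datetime.combine(index_date, time(9, 0)),
                    vaccine_name=product,
                    route="IM",
                    site_laterality=side,
                    in_facility=True,
                    patient_birth_date=birth,
                )
            )
            memberships.append(
                MembershipInterval(
                    patient_id=pid,
                    start_date=index_date - timedelta(days=200),
                    end_date=index_date + timedelta(days=200),
                )
            )
            enc, dx = _structured_for(spec.scenario_id, pid, index_date, side, code_rules)
            encounters.extend(enc)
            diagnoses.extend(dx)

            mismatch = srng.choice([p for p in _PRODUCTS if p != product])
            ctx = {
                "patient_id": pid,
                "side": side,
                "vax_phrase": srng.choice(_PRODUCT_PHRASES[product]),
                "mismatch_phrase": srng.choice(_PRODUCT_PHRASES[mismatch]),
                "onset": None,
            }
            spans: list[GoldSpan] = []
            cause_types: list[str] = []
            if spec.scenario_id in (
                "definite", "probable_w1", "probable_w2", "probable_w3",
                "possible", "negative_no_onset", "negative_other_cause",
                "negative_laterality",
            ):
                cause_types.append("vaccination")
            if spec.scenario_id == "negative_other_cause":
                cause_types.append("daily_activity")
            for day, text, gold in generate_note(spec.scenario_id, ctx, srng):
                nid = f"{pid}-n{day}"
                notes.append(
                    ClinicalNote(
                        note_id=nid,
                        patient_id=pid,
                        note_datetime=datetime.combine(
                            index_date + timedelta(days=day), time(11, 0)
                        ),
                        text=text,
                    )
                )
                spans.extend(gold)
            truth[pid] = PatientTruth(
                patient_id=pid,
                scenario=spec.scenario_id,
                expected_verdict=EXPECTED_VERDICT[spec.scenario_id],
                expected_weak=EXPECTED_WEAK.get(spec.scenario_id),
                expected_exclusion_reason=EXPECTED_EXCLUSION.get(spec.scenario_id),
                expected_onset_offset=ctx["onset"],
                expected_cause_types=tuple(cause_types),
                expected_laterality=(
                    None
                    if spec.scenario_id in ("negative_negated", "non_case_control")
                    else (
                        "right"
                        if spec.scenario_id == "negative_laterality" and side == "left"
                        else (
                            "left"
                            if spec.scenario_id == "negative_laterality"
                            else side
                        )
                    )
                ),
                gold_spans=spans,
            )
    return SyntheticPopulation(
        vaccinations=vaccinations,
        memberships=memberships,
        encounters=encounters,
        diagnoses=diagnoses,
        notes=notes,
        truth=truth,
    )


def inject_distractors(
    notes: list[ClinicalNote],
    rate: float,
    seed: int = 0,
) -> list[ClinicalNote]:
    """Append verdict-neutral distractor sentences to a fraction of notes.

    Distractors are hypothetical advice, negated review-of-systems lines,
    resolved other-site symptoms, and administrative filler; they are
    appended after the existing text so gold spans keep their offsets.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = random.Random(seed)
    out = []
    for note in notes:
        if rate > 0 and rng.random() < rate:
            extra = " " + " ".join(rng.sample(_DISTRACTORS, k=rng.choice([1, 2])))
            out.append(
                ClinicalNote(
                    note_id=note.note_id,
                    patient_id=note.patient_id,
                    note_datetime=note.note_datetime,
                    text=note.text + extra,
                )
            )
        else:
            out.append(note)
    return out


# ---------------------------------------------------------------------------
# File output

def write_population(pop: SyntheticPopulation, out_dir) -> dict[str, str]:
    """Write the four structured tables, notes JSONL and truth JSONL."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vdf = pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "admin_datetime": v.admin_datetime.isoformat(),
                "vaccine_name": v.vaccine_name,
                "route": v.route,
                "site_laterality": v.site_laterality,
                "in_facility": int(v.in_facility),
                "patient_birth_date": v.patient_birth_date.isoformat(),
            }
            for v in pop.vaccinations
        ]
    )
    paths["vaccinations"] = str(out / "vaccinations.csv")
    vdf.to_csv(paths["vaccinations"], index=False)

    mdf = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "start_date": m.start_date.isoformat(),
                "end_date": m.end_date.isoformat(),
            }
            for m in pop.memberships
        ]
    )
    paths["membership"] = str(out / "membership.csv")
    mdf.to_csv(paths["membership"], index=False)

    edf = pd.DataFrame(
        [
            {
                "encounter_id": e.encounter_id,
                "patient_id": e.patient_id,
                "datetime": e.datetime.isoformat(),
                "type": e.type,
            }
            for e in pop.encounters
        ]
    )
    paths["encounters"] = str(out / "encounters.csv")
    edf.to_csv(paths["encounters"], index=False)

    ddf = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "date": d.date.isoformat(),
                "icd10cm_code": d.icd10cm_code,
                "code_laterality": d.code_laterality,
                "encounter_id": d.encounter_id,
                "group": d.group,
            }
            for d in pop.diagnoses
        ]
    )
    paths["diagnoses"] = str(out / "diagnoses.csv")
    ddf.to_csv(paths["diagnoses"], index=False)

    paths["notes"] = str(out / "notes.jsonl")
    with open(paths["notes"], "w", encoding="utf-8") as fh:
        for n in pop.notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "note_datetime": n.note_datetime.isoformat(),
                        "text": n.text,
                    }
                )
                + "\n"
            )

    paths["truth"] = str(out / "truth.jsonl")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for t in pop.truth.values():
            fh.write(
                json.dumps(
                    {
                        "patient_id": t.patient_id,
                        "scenario": t.scenario,
                        "expected_verdict": t.expected_verdict,
                        "expected_weak": t.expected_weak,
                        "expected_exclusion_reason": t.expected_exclusion_reason,
                        "expected_onset_offset": t.expected_onset_offset,
                        "expected_cause_types": list(t.expected_cause_types),
                        "expected_laterality": t.expected_laterality,
                        "gold_spans": [
                            {
                                "note_id": g.note_id,
                                "label": g.label,
                                "start": g.start,
                                "end": g.end,
                                "text": g.text,
                            }
                            for g in t.gold_spans
                        ],
                    }
                )
                + "\n"
            )
    return paths
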