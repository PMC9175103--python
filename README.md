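# sirvanlp

Rule-based clinical NLP for finding **shoulder injury related to vaccine
administration (SIRVA)** in electronic health record (EHR) data.

SIRVA — shoulder pain and limited range of motion after an intramuscular
vaccine injected into the upper arm — has no dedicated diagnosis code, and
shoulder complaints are among the most common musculoskeletal problems, so
the condition is effectively invisible to structured-data queries. Finding
the rare true cases (on the order of 1 per 10,000 vaccinations) otherwise
requires chart review at scale. `sirvanlp` is aimed at vaccine-safety and
pharmacovigilance researchers who need automated, auditable case
ascertainment from a combination of structured EHR tables and free-text
clinical notes.

## What it does

The pipeline has four stages:

1. **Cohort funnel** (structured data): eligible vaccinations
   (intramuscular arm injections at a facility, age ≥ 3, continuous
   membership 180 days either side of the index date = vaccination day),
   then presumptive shoulder injury (a laterality-matched shoulder
   diagnosis code in days 0–180, a clean 180-day lookback, and a code in
   days 31–180 to screen out transient local reactions), with special
   day-0 encounter rules to exclude pre-existing conditions. Every excluded
   record carries its first-failing reason.
2. **Note indexing**: section detection, sentence segmentation (protecting
   clinical shorthand like `s/p` and `b/l`), tokenization, longest-match
   lexicon concept matching, and NegEx/ConText-style context scoping that
   flags mentions as negated, uncertain, or hypothetical.
3. **Relation extraction**: a distance-based relation engine grounds
   ordered/nested item patterns subject to word-distance and
   sentence-window constraints (default cross-sentence window: 4 sentences
   / 50 intervening words). On top of it, three extractors produce
   *anatomic* findings (laterality, body location), *temporal* findings
   (onset and duration, normalized with week = 7 d, month = 30 d,
   year = 365 d; yearless dates resolved toward the note date), and
   *causal* findings classed into seven cause types: vaccination, accident,
   work, other medical condition, exercise, daily activity, unknown.
4. **Case classification**: findings from all notes in days 0–180 are
   pooled per vaccination and scored against a five-criterion case
   definition — (c1) injury confirmed by non-negated, non-resolved signs or
   diagnosis, (c2) laterality matches the vaccinated arm, (c3) some
   candidate onset within days 0–7, (c4) vaccination identified as a cause
   with no competing non-vaccination cause, (c5) duration > 30 days.
   Positive cases are graded **definite / probable / possible** by three
   weak-evidence criteria: cause found only cross-sentence (w1), cause
   attributed only within 30 days of vaccination (w2), vaccine name in the
   note mismatching the vaccination record (w3) — 0, 1, or ≥ 2 criteria
   met, respectively.

Because real EHR data cannot be redistributed, the package ships a
grammar-based **synthetic EHR generator** that emits structured tables and
notes with token-level gold annotations for eleven scenarios (each verdict
tier plus targeted failure modes), so the full pipeline is testable offline
with known ground truth.

## Worked example

```python
from datetime import date, datetime
from sirvanlp import index_note, extract_anatomic, extract_temporal, extract_causal
from sirvanlp.note_indexing import ClinicalNote
from sirvanlp.terminology import default_lexicon

lexicon = default_lexicon()
note = ClinicalNote(
    note_id="n1", patient_id="p1",
    note_datetime=datetime(2017, 5, 15, 10, 0),
    text=("Patient requesting an appointment for evaluation for left arm pain. "
          "States experiencing pain × 1 month s/p flu vaccine."),
)
indexed = index_note(note, lexicon)
index_date = date(2017, 4, 12)  # vaccination day

for f in extract_anatomic(indexed, lexicon):
    print("anatomic:", indexed.mention_text(f.injury_mention), f.laterality, f.body_location)
for f in extract_temporal(indexed, index_date=index_date):
    print("temporal: onset", f.onset_date, "= day", f.onset_day_offset,
          "| duration", f.duration_days, "days")
for f in extract_causal(indexed, lexicon):
    print("causal:", f.cause_type, "|", f.scope, "| vaccine:", f.vaccine_name)
```

prints

```
anatomic: pain left arm
anatomic: pain unknown None
temporal: onset 2017-04-15 = day 3 | duration 30 days
causal: vaccination | cross_sentence | vaccine: flu
```

The symptom is left-sided in the arm region; the stated one-month duration
backdates onset to day 3 after vaccination (inside the 0–7-day window); and
the flu vaccine is attributed as the cause — but only by the cross-sentence
search (the bare "pain" in the second sentence carries no anatomic anchor),
so a case built on this note alone would be downgraded from definite.

## Command line

```bash
sirvanlp simulate --out-dir data --seed 3        # synthetic population + truth
sirvanlp cohort   --data-dir data                # funnel flow table
sirvanlp run      --data-dir data --out-dir out  # full pipeline -> cases.csv
sirvanlp evaluate --cases out/cases.csv --truth data/truth.jsonl
sirvanlp explain  --data-dir data --patient P00001
```

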