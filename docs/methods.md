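# Methods

This note documents the models and conventions behind `sirvanlp`: what each
stage assumes, the parameters that matter, what the synthetic data does and
does not emulate, and the design choices made where the design was open.

## Problem framing

SIRVA case-finding is a needle-in-a-haystack task: shoulder complaints are
common, vaccination-attributable ones are rare, and the attribution lives
almost entirely in free text. The pipeline therefore works in two passes —
a structured-data funnel that shrinks the population to "presumptive"
cases cheaply, and an NLP pass that reads the remaining patients' notes
and applies the case definition. The system is deliberately rule-based:
every verdict decomposes into auditable criterion flags backed by concrete
text spans, which matters for chart-review workflows and medicolegal
contexts more than marginal accuracy gains would.

## Cohort funnel

Windows are pure calendar-day arithmetic anchored at the vaccination day
(day 0): "days 31 to 180" means the closed interval [31, 180] and "within
180 days before" means [−180, −1]. Stages run in a fixed order
(eligibility → presumptive injury → day-0 rules → optional subpopulation
criteria) and each excluded record keeps exactly one first-failing reason,
so stage counts form a monotone funnel table.

Operational choices:

- A "shoulder-related visit" in the lookback exclusion is any encounter
  carrying any configured shoulder code (groups A–D); the code list is a
  documented, editable stand-in built on ICD-10-CM conventions (M75.\*
  shoulder lesions → group A, M25.61\* stiffness → B, M25.51\* pain → C,
  S4x.\* external injuries → D) with laterality decoded from the code's
  laterality character (1 = right, 2 = left, 3 = bilateral).
- The day-0 rules require ≥ 2 timestamped day-0 encounters; the
  urgent-care/emergency/virtual requirement and the location of the
  shoulder code are checked independently (the qualifying later encounter
  need not itself carry the code).
- Vaccinations with unknown arm laterality are excluded, not imputed.
- Age at index requires a birth date, carried on the vaccination record.

## Note indexing

Character offsets are 0-based and half-open throughout. Sections start at
line-initial headers ending in ":" or at all-caps lines and run to the
next header; header labels are normalized against a section-header
lexicon. Sentences split at sentence-final punctuation and at newlines
followed by a capitalized or bulleted continuation, protecting a
configurable abbreviation list and decimal numbers. Tokens preserve
internal `/`, `-` and `'` so clinical shorthand (`s/p`, `b/l`, `x-ray`)
survives as single words.

Concept matching is greedy longest-match left-to-right over the whole
lexicon: at each position the longest matching surface wins and shadows
shorter matches starting inside it (so a multiword entry like "rotator
cuff tear" suppresses "rotator cuff"). Matching is case-insensitive except
for entries flagged `exact_token_sequence` (the single-letter laterality
abbreviations "L"/"R", which must not match the letters inside ordinary
words or lowercase text).

Context scoping follows the NegEx/ConText family: pre-cues ("denies",
"no", "without") open a forward scope within the sentence that closes at a
termination cue ("but", "however"), at the sentence end, or after a
window of **5 word tokens** (configurable; a conventional NegEx-style
default — no principled value exists). Post-cues ("ruled out") scope
backward. Uncertainty ("likely", "possible") and hypothetical cues ("if",
"return if") set their own flags by the same mechanism. Scopes never cross
sentence boundaries, and flags are recomputed from cue geometry, so the
operation is idempotent.

## Relation engine

A relation query is an ordered or unordered list of items — semantic-class
constraints or nested sub-queries (nesting supported to depth 3) — plus
three distance constraints: maximum word tokens between textually
consecutive groundings, maximum consecutive sentences for the whole match,
and an optional same-section requirement. Negated mentions never ground an
item. The production engine is a backtracking search with distance
pruning; an intentionally naive brute-force enumerator
(`search_relations_bruteforce`, refusing notes with > 50 mentions) serves
as an independent oracle in tests, and equivalence is asserted over
hundreds of randomized notes and window parameters.

The default cross-sentence window is **4 sentences / 50 intervening
words**, generalized from the method's canonical query shape; both numbers
are per-query configuration, and cross-sentence search stays within one
section by default.

## Extractors

**Anatomic.** Each eligible injury mention (non-negated, non-hypothetical
symptom or diagnosis) takes the nearest laterality and body-location
mention within its sentence (window: 8 word tokens; distance ties prefer
the preceding mention, following English modifier order). Bilateral terms
("b/l", "bilateral", "both") map to `bilateral`. Diagnosis entries with an
implied region (e.g. "subdeltoid bursitis") back-fill a missing explicit
location.

**Temporal.** Expressions in the mention's sentence are normalized with
fixed conventions: week = 7 days, month = 30 days, year = 365 days (no
calendar-aware month lengths; documented, not configurable); a duration of
N days implies onset at note date − N; "since 〈weekday〉" resolves to the
most recent such weekday strictly before the note date; a month/day
without a year is placed in the year nearest the note date, ties breaking
earlier; "today"/"yesterday" resolve against the note date. Expressions
anchored to the vaccination itself ("2 days after the flu shot", "since
immunizations") yield vaccination-relative offsets directly. A mention
preceded in its sentence by a past-resolution cue ("in the past",
"resolved", "history of" — but not after "never") is marked `resolved`;
resolved symptoms never confirm an active injury. Unparseable expressions
produce no finding.

**Causal.** Two query shapes run in order: intra-sentence
(injury … trigger cause) and cross-sentence (injury … nested[trigger
cause]), the nested trigger–cause pair allowed ≤ 3 intervening words. The
cause class of the grounded cause mention gives one of the seven cause
types; a vaccine-class grounding also captures the normalized product name
("flu", "tdap", "zoster", "pneumococcal", …; generic terms like
"vaccination" carry no product). Non-negated unknown-cause statements
("insidious onset") attach to the nearest anchor without requiring a
trigger. Duplicate (anchor, cause) pairs keep the intra-sentence reading.

*Strict anatomy* (default on): a causal anchor must resolve to a
shoulder-region body location (shoulder, arm, deltoid, rotator cuff, or a
diagnosis implying it). This serves two purposes: it stops events from
attaching to non-shoulder complaints ("fell … which worsened her **back**
pain"), and it makes location-less symptom mentions ineligible as anchors,
so an attribution like "pain × 1 month s/p flu vaccine" following a
located mention in an earlier sentence is correctly credited to the
cross-sentence search. The toggle (`strict_anatomy=False`,
`--no-strict-anatomy`) restores the permissive behavior.

## Classification

Aggregation is maximum-sensitivity: all findings from all notes in days
0–180 are pooled, every candidate onset and cause retained, conflicting
lateralities kept with per-finding values. The five criteria and three
weak-evidence criteria are evaluated on the pool; the verdict map is
purely combinatorial (negative unless all five; else definite/probable/
possible by weak count 0/1/≥ 2) and is tested exhaustively over all 2⁸
flag combinations.

Interpretation choices on points the case definition leaves open:

- c2 with only unknown-laterality findings **fails** (conservative);
  bilateral statements **pass** (toggleable in principle — the medicolegal
  definition's "limited to the injected shoulder" reading is unresolved).
- c4: an unknown cause never disqualifies; any non-negated finding of the
  five competing cause types does.
- c5 accepts three kinds of duration evidence: an extracted duration
  > 30 days, an active injury finding in a note dated > 30 days
  post-index, or a laterality-matched diagnosis code in days 31–180.
  Note that a cohort-passing patient always has the third kind, so c5
  cannot fail for funnel survivors; the criterion still matters when the
  classifier is applied outside the funnel.
- w2 is read as: *every* vaccination attribution is dated ≤ 30 days
  post-vaccination (equivalently, none later).
- w3 compares normalized product families; a generic vaccine term or an
  absent name is never a mismatch.

## Synthetic data

The generator emulates the study conditions of a screened presumptive
population, not raw vaccinations: scenario counts default to 291 definite,
64/41/19 probable (one per weak criterion), 52 possible, 26 of each of
five negative modes, and 30 funnel-excluded controls (627 patients,
~720 notes). Full-scale rarity (~1 SIRVA per 10,000 vaccinations) is
impractical at desk scale and is configurable instead. Structured streams
are built to pass (or fail, per scenario) specific funnel stages; notes
are built from template grammars with slot-filled lexicon terms, so gold
spans and expected verdicts are exact by construction. One deliberate
asymmetry: the "short duration" negative scenario is realized as a
*resolved* short-lived symptom (failing the active-injury criterion),
because — as noted above — funnel survivors cannot fail c5 directly.

What this does **not** emulate: realistic clinical discourse, OCR noise,
misspellings, coreference, template boilerplate, copy-forward text, or
adversarial phrasings outside the grammar. Passing the end-to-end recovery
test therefore demonstrates internal consistency of the rules, extractors
and classifier — not performance on real notes, which depends on lexicon
coverage and phrasing diversity the grammar cannot represent. The
distractor injector (hypothetical advice, negated review-of-systems lines,
resolved other-site symptoms) probes robustness only against
constructions the context scoper is designed to reject.

## Evaluation arithmetic

Percentages are rounded half-up at one decimal via exact decimal
arithmetic (float `round()` would round 71.875 → 71.9 only by accident of
binary representation). The default confidence interval is exact
Clopper–Pearson from beta quantiles (lower bound 0 at k = 0, upper bound
1 at k = n); Wilson is available and every result records its method. For
a 4/4 proportion the exact lower bound is 39.8%, and for 96/96 it is
96.2% — slightly different conventions in the literature (mid-P,
normal-approximate, or software-specific intervals) print slightly
different bounds for the same counts.

## Numerical / degenerate-input conventions

- Empty note → zero sections, sentences, mentions; classification of an
  evidence-free patient → negative.
- Zero-denominator metrics are reported as undefined (None), not errors.
- All randomness flows from explicit integer seeds; population generation
  is byte-identical for a fixed seed (per-scenario substreams are derived
  via CRC32, not Python's salted string hash).
- The brute-force oracle refuses notes above its mention cap rather than
  silently degrading.

## Known limitations

- Lexicons are editable reconstructions sized for coverage of the
  documented behaviors, not clinically validated terminologies; fidelity
  to any proprietary source list is unverifiable by design.
- No syntactic parsing: relation search is distance-based, so long
  coordinated sentences can license spurious groundings that a
  chunk-constrained system would reject.
- Temporal normalization handles point and duration expressions, not
  interval algebra or relative chains ("a week after that").
- The classifier is deterministic and unweighted; no probabilistic
  scoring or learned layer over the rule outputs.
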