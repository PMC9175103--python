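"""Distance-constrained relation search and finding extraction.

The relation engine grounds ordered or nested item patterns in an indexed
note subject to three distances: the number of word tokens between
consecutive matched items, the number of consecutive sentences the whole
match may cover, and (optionally) a same-section constraint.  On top of it
sit three extractors that distill matches into findings for shoulder-injury
mentions: anatomic (laterality and body location), temporal (onset and
duration, with resolved-symptom detection), and causal (one of seven cause
types: vaccination, accident, work, other medical condition, exercise,
daily activity, unknown).

Negated mentions never ground a relation item; hypothetical mentions never
anchor a finding.
"""

from __future__ import annotations

import calendar
import itertools
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from importlib import resources
from typing import Callable, Union

from sirvanlp.note_indexing import ConceptMention, IndexedNote
from sirvanlp.terminology import (
    CAUSE_CLASSES,
    CAUSE_TYPE_BY_CLASS,
    INJURY_CLASSES,
    SemanticClass,
)


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class ClassConstraint:
    """A relation item that matches any mention of one of the given classes."""

    classes: frozenset[SemanticClass]


@dataclass
class RelationQuery:
    query_id: str
    items: list[Union[ClassConstraint, "RelationQuery"]]
    ordered: bool = True
    max_sentence_span: int = 1
    max_intervening_words: int = 50
    require_same_section: bool = False

    def validate(self, _depth: int = 1) -> None:
        if _depth > 3:
            raise QueryError(f"query {self.query_id}: nesting depth > 3")
        if not self.items:
            raise QueryError(f"query {self.query_id}: empty item list")
        if self.max_sentence_span < 1:
            raise QueryError(f"query {self.query_id}: max_sentence_span < 1")
        if self.max_intervening_words < 0:
            raise QueryError(f"query {self.query_id}: max_intervening_words < 0")
        for it in self.items:
            if isinstance(it, RelationQuery):
                it.validate(_depth + 1)


Grounding = Union[ConceptMention, "RelationMatch"]


@dataclass
class RelationMatch:
    query_id: str
    groundings: list[Grounding]
    sentence_window: tuple[int, int]
    scope: str  # "intra_sentence" | "cross_sentence"

    def leaf_mentions(self) -> list[ConceptMention]:
        out: list[ConceptMention] = []
        for g in self.groundings:
            if isinstance(g, RelationMatch):
                out.extend(g.leaf_mentions())
            else:
                out.append(g)
        return out

    def key(self) -> tuple:
        return (self.query_id, frozenset(m.key() for m in self.leaf_mentions()))


def _span(g: Grounding) -> tuple[int, int]:
    if isinstance(g, RelationMatch):
        leaves = g.leaf_mentions()
        return (min(m.char_span[0] for m in leaves), max(m.char_span[1] for m in leaves))
    return g.char_span


def _sents(g: Grounding) -> tuple[int, int]:
    if isinstance(g, RelationMatch):
        return g.sentence_window
    return (g.sentence_index, g.sentence_index)


def _default_eligible(m: ConceptMention) -> bool:
    return not m.negated


def _finish(query: RelationQuery, groundings: list[Grounding]) -> RelationMatch:
    lo = min(_sents(g)[0] for g in groundings)
    hi = max(_sents(g)[1] for g in groundings)
    return RelationMatch(
        query_id=query.query_id,
        groundings=list(groundings),
        sentence_window=(lo, hi),
        scope="intra_sentence" if lo == hi else "cross_sentence",
    )


def _pair_ok(indexed: IndexedNote, prev: Grounding, nxt: Grounding, max_words: int) -> bool:
    ps, pe = _span(prev)
    ns, ne = _span(nxt)
    if ns < pe:  # overlapping or preceding
        return False
    return indexed.words_between(pe, ns) <= max_words


def _constraints_ok(
    indexed: IndexedNote, query: RelationQuery, groundings: list[Grounding]
) -> bool:
    ordered = sorted(groundings, key=_span) if not query.ordered else groundings
    for prev, nxt in zip(ordered, ordered[1:]):
        if not _pair_ok(indexed, prev, nxt, query.max_intervening_words):
            return False
    lo = min(_sents(g)[0] for g in groundings)
    hi = max(_sents(g)[1] for g in groundings)
    if hi - lo + 1 > query.max_sentence_span:
        return False
    if query.require_same_section:
        labels = {
            indexed.sentences[s].section_label
            for g in groundings
            for s in range(_sents(g)[0], _sents(g)[1] + 1)
        }
        if len(labels) > 1:
            return False
    leaves = [m.key() for g in groundings for m in _leaf_list(g)]
    return len(leaves) == len(set(leaves))


def _leaf_list(g: Grounding) -> list[ConceptMention]:
    return g.leaf_mentions() if isinstance(g, RelationMatch) else [g]


def _candidates(
    indexed: IndexedNote,
    item: Union[ClassConstraint, RelationQuery],
    eligible: Callable[[ConceptMention], bool],
    engine: Callable,
) -> list[Grounding]:
    if isinstance(item, RelationQuery):
        return list(engine(indexed, item, eligible=eligible))
    return [
        m
        for m in indexed.mentions
        if m.semantic_class in item.classes and eligible(m)
    ]


def search_relations(
    indexed: IndexedNote,
    query: RelationQuery,
    eligible: Callable[[ConceptMention], bool] = _default_eligible,
) -> list[RelationMatch]:
    """Find every grounding of ``query`` in the note.

    Backtracking search over mentions sorted by start offset; for ordered
    queries consecutive items must appear left to right, for unordered
    queries the items may ground in any textual order.  Constraints: at most
    ``max_intervening_words`` word tokens between textually consecutive
    groundings, the whole match inside ``max_sentence_span`` consecutive
    sentences (and one section when required), no mention grounding two
    items, and negated mentions ineligible.
    """
    query.validate()
    cand = [
        sorted(_candidates(indexed, it, eligible, search_relations), key=_span)
        for it in query.items
    ]
    if any(not c for c in cand):
        return []

    out: list[RelationMatch] = []
    seen: set = set()

    def emit(groundings: list[Grounding]) -> None:
        m = _finish(query, groundings)
        if m.key() not in seen:
            seen.add(m.key())
            out.append(m)

    if query.ordered:
        def rec(pos: int, acc: list[Grounding]) -> None:
            if pos == len(query.items):
                if _constraints_ok(indexed, query, acc):
                    emit(acc)
                return
            for g in cand[pos]:
                if acc:
                    if not _pair_ok(indexed, acc[-1], g, query.max_intervening_words):
                        continue
                    lo = min(_sents(x)[0] for x in acc + [g])
                    hi = max(_sents(x)[1] for x in acc + [g])
                    if hi - lo + 1 > query.max_sentence_span:
                        continue
                rec(pos + 1, acc + [g])

        rec(0, [])
    else:
        for combo in itertools.product(*cand):
            if _constraints_ok(indexed, query, list(combo)):
                emit(list(combo))
    return out


def search_relations_bruteforce(
    indexed: IndexedNote,
    query: RelationQuery,
    eligible: Callable[[ConceptMention], bool] = _default_eligible,
    max_mentions: int = 50,
) -> list[RelationMatch]:
    """Reference implementation: enumerate all grounding tuples and filter.

    Test oracle only; refuses notes with more than ``max_mentions`` mentions.
    """
    query.validate()
    if len(indexed.mentions) > max_mentions:
        raise QueryError(
            f"brute-force oracle limited to {max_mentions} mentions "
            f"(note has {len(indexed.mentions)})"
        )
    cand = [
        _candidates(indexed, it, eligible, search_relations_bruteforce)
        for it in query.items
    ]
    out: list[RelationMatch] = []
    seen: set = set()
    for combo in itertools.product(*cand):
        groundings = list(combo)
        if query.ordered:
            spans = [_span(g) for g in groundings]
            if any(n[0] < p[1] for p, n in zip(spans, spans[1:])):
                continue
        if _constraints_ok(indexed, query, groundings):
            m = _finish(query, groundings)
            if m.key() not in seen:
                seen.add(m.key())
                out.append(m)
    return out


# ---------------------------------------------------------------------------
# Query file I/O

def _query_from_obj(obj: dict, where: str) -> RelationQuery:
    items: list[Union[ClassConstraint, RelationQuery]] = []
    for i, it in enumerate(obj.get("items", [])):
        if "query" in it:
            items.append(_query_from_obj(it["query"], f"{where}.items[{i}]"))
        else:
            try:
                items.append(
                    ClassConstraint(frozenset(SemanticClass(c) for c in it["classes"]))
                )
            except (KeyError, ValueError) as exc:
                raise QueryError(f"{where}.items[{i}]: {exc}") from exc
    q = RelationQuery(
        query_id=obj.get("query_id", where),
        items=items,
        ordered=bool(obj.get("ordered", True)),
        max_sentence_span=int(obj.get("max_sentence_span", 1)),
        max_intervening_words=int(obj.get("max_intervening_words", 50)),
        require_same_section=bool(obj.get("require_same_section", True)),
    )
    q.validate()
    return q


def load_queries(path) -> list[RelationQuery]:
    """Load a relation query set from a JSON file (list of query objects)."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [_query_from_obj(obj, f"{path}[{i}]") for i, obj in enumerate(payload)]


def default_queries() -> list[RelationQuery]:
    ref = resources.files("sirvanlp.data").joinpath("queries_default.json")
    with resources.as_file(ref) as path:
        return load_queries(path)


# ---------------------------------------------------------------------------
# Findings

@dataclass
class AnatomicFinding:
    injury_mention: ConceptMention
    laterality: str  # left | right | bilateral | unknown
    body_location: str | None  # location text, or None when unknown
    region: str | None  # "shoulder" | "other" | None (unknown)
    resolved: bool
    note_id: str
    note_datetime: datetime


@dataclass
class TemporalFinding:
    injury_mention: ConceptMention
    onset_date: date | None
    onset_day_offset: int | None
    duration_days: int | None
    resolved: bool
    note_id: str
    note_datetime: datetime

    def __post_init__(self) -> None:
        if (
            self.onset_date is None
            and self.onset_day_offset is None
            and self.duration_days is None
        ):
            raise ValueError("temporal finding with no temporal content")


@dataclass
class CausalFinding:
    injury_mention: ConceptMention
    cause_type: str  # one of the seven cause types
    cause_mention: ConceptMention | None
    trigger: str | None  # entry_id of the grounded causal trigger
    scope: str  # intra_sentence | cross_sentence
    vaccine_name: str | None  # normalized product, None when generic/absent
    note_id: str
    note_datetime: datetime


_LATERALITY_BY_ENTRY = {
    "lat_left": "left",
    "lat_left_abbr": "left",
    "lat_right": "right",
    "lat_right_abbr": "right",
    "lat_bilateral": "bilateral",
}

_RESOLUTION_RE = re.compile(
    r"\b(?:in (?:the )?past|resolved|has resolved|went away|used to have"
    r"|previously had|history of|hx of)\b",
    re.IGNORECASE,
)


def _is_resolved(indexed: IndexedNote, mention: ConceptMention) -> bool:
    """True when a past-resolution cue precedes the mention in its sentence."""
    sent = indexed.sentences[mention.sentence_index]
    prefix = indexed.note.text[sent.char_span[0] : mention.char_span[0]]
    for m in _RESOLUTION_RE.finditer(prefix):
        before = prefix[: m.start()]
        if re.search(r"\bnever\s+$", before, re.IGNORECASE):
            continue
        return True
    return False


def _word_distance(indexed: IndexedNote, a: ConceptMention, b: ConceptMention) -> int:
    if a.char_span[0] <= b.char_span[0]:
        return indexed.words_between(a.char_span[1], b.char_span[0])
    return indexed.words_between(b.char_span[1], a.char_span[0])


def _injury_mentions(indexed: IndexedNote) -> list[ConceptMention]:
    return [
        m
        for m in indexed.mentions
        if m.semantic_class in INJURY_CLASSES
        and not m.negated
        and not m.hypothetical
    ]


def _nearest(
    indexed: IndexedNote,
    target: ConceptMention,
    candidates: list[ConceptMention],
    window: int,
) -> ConceptMention | None:
    """Nearest candidate in the same sentence within ``window`` word tokens;
    ties in distance prefer the candidate preceding the target."""
    best: ConceptMention | None = None
    best_rank: tuple[int, int] | None = None
    for c in candidates:
        if c.sentence_index != target.sentence_index:
            continue
        d = _word_distance(indexed, target, c)
        if d > window:
            continue
        precedes = 0 if c.char_span[0] < target.char_span[0] else 1
        rank = (d, precedes)
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best = c
    return best


def extract_anatomic(
    indexed: IndexedNote,
    lexicon=None,
    window: int = 8,
) -> list[AnatomicFinding]:
    """Attach laterality and body location to each eligible injury mention.

    The nearest laterality and body-location mentions within the same
    sentence (default window: 8 word tokens) are used; bilateral terms map
    to "bilateral"; when a diagnosis entry implies the shoulder region
    (e.g. "rotator cuff tear") the implied location backs up a missing
    explicit one.
    """
    lex = lexicon or getattr(indexed, "_lexicon", None)
    laterality_mentions = [
        m for m in indexed.mentions if m.semantic_class is SemanticClass.LATERALITY
    ]
    location_mentions = [
        m for m in indexed.mentions if m.semantic_class is SemanticClass.BODY_LOCATION
    ]
    findings = []
    for inj in _injury_mentions(indexed):
        lat_m = _nearest(indexed, inj, laterality_mentions, window)
        laterality = _LATERALITY_BY_ENTRY.get(lat_m.entry_id, "unknown") if lat_m else "unknown"
        loc_m = _nearest(indexed, inj, location_mentions, window)
        body_location = None
        region = None
        if loc_m is not None:
            body_location = indexed.mention_text(loc_m).lower()
            region = _entry_region(lex, loc_m.entry_id)
        else:
            implied = _entry_region(lex, inj.entry_id)
            if implied == "shoulder":
                body_location = "shoulder"
                region = "shoulder"
        findings.append(
            AnatomicFinding(
                injury_mention=inj,
                laterality=laterality,
                body_location=body_location,
                region=region,
                resolved=_is_resolved(indexed, inj),
                note_id=indexed.note.note_id,
                note_datetime=indexed.note.note_datetime,
            )
        )
    return findings


def _entry_region(lexicon, entry_id: str) -> str | None:
    if lexicon is None:
        return None
    try:
        return lexicon.get(entry_id).region
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# Temporal normalization

_UNIT_DAYS = {"day": 1, "week": 7, "month": 30, "year": 365}

_NUM_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
    "a couple of": 2, "couple of": 2, "a few": 3, "few": 3, "several": 3,
}

_WEEKDAYS = {name.lower(): i for i, name in enumerate(calendar.day_name)}
_MONTHS = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTHS.update({name.lower(): i for i, name in enumerate(calendar.month_abbr) if name})

_NUM_PAT = r"(\d+|a couple of|couple of|a few|few|several|an|a|one|two|three|four|five|six|seven|eight|nine|ten)"
_UNIT_PAT = r"(day|week|month|year)s?"

_DURATION_RE = re.compile(
    rf"(?:\b(?:for (?:the )?(?:last |past )?|over the (?:past|last) |lasting |lasted |x )|× ){_NUM_PAT} {_UNIT_PAT}\b",
    re.IGNORECASE,
)
_AGO_RE = re.compile(rf"\b{_NUM_PAT} {_UNIT_PAT} ago\b", re.IGNORECASE)
_SINCE_WEEKDAY_RE = re.compile(
    r"\bsince (?:last )?(monday|tuesday|wednesday|thursday|friday|saturday|sunday)\b",
    re.IGNORECASE,
)
_MONTH_NAMES = "|".join(sorted(_MONTHS, key=len, reverse=True))
_MONTH_DAY_RE = re.compile(
    rf"\b({_MONTH_NAMES})\.? (\d{{1,2}})(?:st|nd|rd|th)?(?:,? (\d{{4}}))?\b",
    re.IGNORECASE,
)
_SLASH_DATE_RE = re.compile(r"\b(\d{1,2})/(\d{1,2})(?:/(\d{2,4}))?\b")
_TODAY_RE = re.compile(r"\btoday\b", re.IGNORECASE)
_YESTERDAY_RE = re.compile(r"\byesterday\b", re.IGNORECASE)


def _parse_num(text: str) -> int:
    text = text.lower().strip()
    if text.isdigit():
        return int(text)
    return _NUM_WORDS[text]


def _nearest_year(month: int, day: int, anchor: date) -> date:
    """Place a yearless month/day in the year bringing it nearest the anchor
    date; ties break toward the earlier year."""
    best = None
    for year in (anchor.year - 1, anchor.year, anchor.year + 1):
        try:
            cand = date(year, month, day)
        except ValueError:
            continue
        dist = abs((cand - anchor).days)
        if best is None or dist < best[0]:  # strict: ties keep earlier year
            best = (dist, cand)
    if best is None:
        raise ValueError(f"impossible calendar date {month}/{day}")
    return best[1]


def normalize_temporal(expression: str, note_date: date) -> tuple[date | None, int | None]:
    """Normalize one temporal expression to (onset_date, duration_days).

    Conventions: week = 7 days, month = 30 days, year = 365 days; a duration
    of N days implies onset at note_date - N; "since <weekday>" resolves to
    the most recent such weekday strictly before the note date; a month/day
    without a year is placed in the year nearest the note creation date
    (ties toward the earlier year).  Unparseable input yields (None, None).
    """
    if isinstance(note_date, datetime):
        note_date = note_date.date()
    expr = expression.strip()

    m = _AGO_RE.search(expr)
    if m:
        days = _parse_num(m.group(1)) * _UNIT_DAYS[m.group(2).lower()]
        return (note_date - timedelta(days=days), None)

    m = _DURATION_RE.search(expr)
    if m:
        days = _parse_num(m.group(1)) * _UNIT_DAYS[m.group(2).lower()]
        return (note_date - timedelta(days=days), days)

    m = _SINCE_WEEKDAY_RE.search(expr)
    if m:
        target = _WEEKDAYS[m.group(1).lower()]
        delta = (note_date.weekday() - target - 1) % 7 + 1
        return (note_date - timedelta(days=delta), None)

    m = _MONTH_DAY_RE.search(expr)
    if m:
        month = _MONTHS[m.group(1).lower().rstrip(".")]
        day = int(m.group(2))
        try:
            if m.group(3):
                return (date(int(m.group(3)), month, day), None)
            return (_nearest_year(month, day, note_date), None)
        except ValueError:
            return (None, None)

    m = _SLASH_DATE_RE.search(expr)
    if m:
        month, day = int(m.group(1)), int(m.group(2))
        try:
            if m.group(3):
                year = int(m.group(3))
                if year < 100:
                    year += 2000
                return (date(year, month, day), None)
            return (_nearest_year(month, day, note_date), None)
        except ValueError:
            return (None, None)

    if _YESTERDAY_RE.search(expr):
        return (note_date - timedelta(days=1), None)
    if _TODAY_RE.search(expr):
        return (note_date, None)
    return (None, None)


#: Onset anchored to the vaccination itself rather than to the note date.
_VAX_WORDS = r"(?:vaccination|vaccinations|vaccine|immunization|immunizations|injection|shot)"
_AFTER_VAX_RE = re.compile(
    rf"\b{_NUM_PAT} {_UNIT_PAT} after (?:the |receiving |getting )?(?:\w+ )?{_VAX_WORDS}\b",
    re.IGNORECASE,
)
_DAY_OF_VAX_RE = re.compile(
    rf"\b(?:the day (?:\w+ ){{0,3}}?(?:got|received|had) |since (?:the |receiving |getting )?(?:\w+ )?){_VAX_WORDS}",
    re.IGNORECASE,
)

_TEMPORAL_SCAN_RES = (
    _AGO_RE,
    _DURATION_RE,
    _SINCE_WEEKDAY_RE,
    _MONTH_DAY_RE,
    _SLASH_DATE_RE,
    _YESTERDAY_RE,
    _TODAY_RE,
)


def extract_temporal(
    indexed: IndexedNote,
    index_date: date | None = None,
) -> list[TemporalFinding]:
    """Extract onset/duration findings for each eligible injury mention.

    Temporal expressions are searched in the mention's own sentence; onset
    day offsets are computed against ``index_date`` (the vaccination day)
    when given.  Expressions anchored to the vaccination itself ("2 days
    after the flu shot", "since immunizations") yield vaccination-relative
    offsets directly.  Mentions described with past-resolution cues are
    marked ``resolved``.
    """
    if isinstance(index_date, datetime):
        index_date = index_date.date()
    note_date = indexed.note.note_datetime.date()
    findings: list[TemporalFinding] = []
    for inj in _injury_mentions(indexed):
        sent = indexed.sentences[inj.sentence_index]
        text = indexed.note.text[sent.char_span[0] : sent.char_span[1]]
        resolved = _is_resolved(indexed, inj)
        emitted_spans: set[tuple[int, int]] = set()

        m = _AFTER_VAX_RE.search(text)
        if m:
            offset = _parse_num(m.group(1)) * _UNIT_DAYS[m.group(2).lower()]
            findings.append(
                TemporalFinding(
                    injury_mention=inj,
                    onset_date=index_date + timedelta(days=offset) if index_date else None,
                    onset_day_offset=offset,
                    duration_days=None,
                    resolved=resolved,
                    note_id=indexed.note.note_id,
                    note_datetime=indexed.note.note_datetime,
                )
            )
            emitted_spans.add(m.span())
        elif _DAY_OF_VAX_RE.search(text):
            findings.append(
                TemporalFinding(
                    injury_mention=inj,
                    onset_date=index_date,
                    onset_day_offset=0,
                    duration_days=None,
                    resolved=resolved,
                    note_id=indexed.note.note_id,
                    note_datetime=indexed.note.note_datetime,
                )
            )

        for pattern in _TEMPORAL_SCAN_RES:
            m = pattern.search(text)
            if not m or any(_overlaps(m.span(), s) for s in emitted_spans):
                continue
            onset, duration = normalize_temporal(m.group(0), note_date)
            if onset is None and duration is None:
                continue
            offset = (onset - index_date).days if (onset and index_date) else None
            findings.append(
                TemporalFinding(
                    injury_mention=inj,
                    onset_date=onset,
                    onset_day_offset=offset,
                    duration_days=duration,
                    resolved=resolved,
                    note_id=indexed.note.note_id,
                    note_datetime=indexed.note.note_datetime,
                )
            )
            emitted_spans.add(m.span())
            break  # one note-anchored expression per mention
    return findings


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# Causal extraction

_CAUSE_ONLY_CLASSES = CAUSE_CLASSES - {SemanticClass.CAUSE_UNKNOWN}


def _causal_queries(max_sentences: int, max_words: int) -> list[RelationQuery]:
    injury = ClassConstraint(frozenset(INJURY_CLASSES))
    trigger = ClassConstraint(frozenset({SemanticClass.CAUSAL_TRIGGER}))
    cause = ClassConstraint(frozenset(_CAUSE_ONLY_CLASSES))
    intra = RelationQuery(
        query_id="causal_intra",
        items=[injury, trigger, cause],
        ordered=True,
        max_sentence_span=1,
        max_intervening_words=max_words,
        require_same_section=True,
    )
    nested = RelationQuery(
        query_id="trigger_cause",
        items=[trigger, cause],
        ordered=True,
        max_sentence_span=1,
        max_intervening_words=3,
    )
    cross = RelationQuery(
        query_id="causal_cross",
        items=[injury, nested],
        ordered=True,
        max_sentence_span=max_sentences,
        max_intervening_words=max_words,
        require_same_section=True,
    )
    return [intra, cross]


def extract_causal(
    indexed: IndexedNote,
    lexicon=None,
    queries: list[RelationQuery] | None = None,
    strict_anatomy: bool = True,
    max_sentences: int = 4,
    max_words: int = 50,
) -> list[CausalFinding]:
    """Extract cause attributions for shoulder-injury mentions.

    Runs the causal relation query set: an intra-sentence pattern
    (injury ... trigger cause) and a cross-sentence pattern (injury ...
    nested[trigger cause]) over a window of ``max_sentences`` sentences and
    ``max_words`` intervening words.  With ``strict_anatomy`` (default on),
    only injury mentions that resolve to a shoulder-region body location may
    anchor a cause, which prevents attributing events to e.g. back pain.
    Non-negated unknown-cause statements ("insidious onset") near an anchor
    yield cause_type="unknown" without requiring a trigger.  Negated causes
    yield nothing.
    """
    if queries is None:
        queries = _causal_queries(max_sentences, max_words)

    anatomic = extract_anatomic(indexed, lexicon)
    shoulder_anchor_keys = {
        f.injury_mention.key()
        for f in anatomic
        if f.region == "shoulder"
    }

    def eligible(m: ConceptMention) -> bool:
        if m.negated or m.hypothetical:
            return False
        if m.semantic_class in INJURY_CLASSES and strict_anatomy:
            return m.key() in shoulder_anchor_keys
        return True

    best: dict[tuple, CausalFinding] = {}

    def consider(f: CausalFinding, anchor: ConceptMention, cause: ConceptMention) -> None:
        k = (anchor.key(), cause.key())
        prev = best.get(k)
        if prev is None or (prev.scope == "cross_sentence" and f.scope == "intra_sentence"):
            best[k] = f

    for query in queries:
        for match in search_relations(indexed, query, eligible=eligible):
            leaves = match.leaf_mentions()
            anchors = [m for m in leaves if m.semantic_class in INJURY_CLASSES]
            causes = [m for m in leaves if m.semantic_class in _CAUSE_ONLY_CLASSES]
            triggers = [
                m for m in leaves if m.semantic_class is SemanticClass.CAUSAL_TRIGGER
            ]
            if not anchors or not causes:
                continue
            anchor, cause = anchors[0], causes[0]
            vaccine_name = None
            if cause.semantic_class is SemanticClass.VACCINE and lexicon is not None:
                try:
                    vaccine_name = lexicon.get(cause.entry_id).product
                except KeyError:
                    pass
            consider(
                CausalFinding(
                    injury_mention=anchor,
                    cause_type=CAUSE_TYPE_BY_CLASS[cause.semantic_class],
                    cause_mention=cause,
                    trigger=triggers[0].entry_id if triggers else None,
                    scope=match.scope,
                    vaccine_name=vaccine_name,
                    note_id=indexed.note.note_id,
                    note_datetime=indexed.note.note_datetime,
                ),
                anchor,
                cause,
            )

    # Unknown-cause statements: no trigger required, just proximity.
    unknown_mentions = [
        m
        for m in indexed.mentions
        if m.semantic_class is SemanticClass.CAUSE_UNKNOWN
        and not m.negated
        and not m.hypothetical
    ]
    if unknown_mentions:
        anchors = [
            m
            for m in _injury_mentions(indexed)
            if not strict_anatomy or m.key() in shoulder_anchor_keys
        ]
        for unk in unknown_mentions:
            near = [
                a
                for a in anchors
                if abs(a.sentence_index - unk.sentence_index) < max_sentences
                and _word_distance(indexed, a, unk) <= max_words
            ]
            if not near:
                continue
            anchor = min(near, key=lambda a: _word_distance(indexed, a, unk))
            scope = (
                "intra_sentence"
                if anchor.sentence_index == unk.sentence_index
                else "cross_sentence"
            )
            consider(
                CausalFinding(
                    injury_mention=anchor,
                    cause_type="unknown",
                    cause_mention=unk,
                    trigger=None,
                    scope=scope,
                    vaccine_name=None,
                    note_id=indexed.note.note_id,
                    note_datetime=indexed.note.note_datetime,
                ),
                anchor,
                unk,
            )

    return sorted(
        best.values(),
        key=lambda f: (f.injury_mention.char_span, f.cause_mention.char_span),
    )
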