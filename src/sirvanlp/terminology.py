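"""Lexicons that drive concept matching.

A :class:`Lexicon` is a flat list of entries, each carrying a semantic class
(shoulder symptom, laterality, cause of a given type, causal trigger,
negation cue, ...), a canonical form, and surface-form variants.  Concept
matching against tokenized text is longest-match, left-to-right, and
case-insensitive unless an entry opts into exact token matching (used for
single-letter laterality abbreviations such as "L"/"R").

The shipped default lexicon is an editable reconstruction: shoulder-condition
vocabulary, the seven cause classes (vaccination, accident, work, other
medical condition, exercise, daily activity, unknown), 70+ causal trigger
terms, temporal cues, and NegEx-style context cues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence


class SemanticClass(str, Enum):
    """Closed enumeration of concept classes used throughout the pipeline."""

    SHOULDER_SYMPTOM = "shoulder_symptom"
    SHOULDER_DIAGNOSIS = "shoulder_diagnosis"
    BODY_LOCATION = "body_location"
    LATERALITY = "laterality"
    VACCINE = "vaccine"
    CAUSE_ACCIDENT = "cause_accident"
    CAUSE_WORK = "cause_work"
    CAUSE_MEDICAL_CONDITION = "cause_medical_condition"
    CAUSE_EXERCISE = "cause_exercise"
    CAUSE_DAILY_ACTIVITY = "cause_daily_activity"
    CAUSE_UNKNOWN = "cause_unknown"
    CAUSAL_TRIGGER = "causal_trigger"
    TEMPORAL_CUE = "temporal_cue"
    NEGATION_CUE = "negation_cue"
    UNCERTAINTY_CUE = "uncertainty_cue"
    HYPOTHETICAL_CUE = "hypothetical_cue"
    TERMINATION_CUE = "termination_cue"
    SECTION_HEADER = "section_header"


#: The non-vaccination cause classes plus ``VACCINE`` map one-to-one onto the
#: seven cause types used in case classification.
CAUSE_CLASSES = frozenset(
    {
        SemanticClass.VACCINE,
        SemanticClass.CAUSE_ACCIDENT,
        SemanticClass.CAUSE_WORK,
        SemanticClass.CAUSE_MEDICAL_CONDITION,
        SemanticClass.CAUSE_EXERCISE,
        SemanticClass.CAUSE_DAILY_ACTIVITY,
        SemanticClass.CAUSE_UNKNOWN,
    }
)

#: Cause type label for each cause-bearing semantic class.
CAUSE_TYPE_BY_CLASS = {
    SemanticClass.VACCINE: "vaccination",
    SemanticClass.CAUSE_ACCIDENT: "accident",
    SemanticClass.CAUSE_WORK: "work",
    SemanticClass.CAUSE_MEDICAL_CONDITION: "other_medical_condition",
    SemanticClass.CAUSE_EXERCISE: "exercise",
    SemanticClass.CAUSE_DAILY_ACTIVITY: "daily_activity",
    SemanticClass.CAUSE_UNKNOWN: "unknown",
}

INJURY_CLASSES = frozenset(
    {SemanticClass.SHOULDER_SYMPTOM, SemanticClass.SHOULDER_DIAGNOSIS}
)

CUE_CLASSES = frozenset(
    {
        SemanticClass.NEGATION_CUE,
        SemanticClass.UNCERTAINTY_CUE,
        SemanticClass.HYPOTHETICAL_CUE,
        SemanticClass.TERMINATION_CUE,
    }
)


class LexiconError(ValueError):
    """Raised when a lexicon file fails to parse or validate."""


@dataclass
class LexiconEntry:
    """One concept with its surface forms.

    ``match_policy`` is ``"case_insensitive"`` (default) or
    ``"exact_token_sequence"`` (case-sensitive; used for abbreviations like
    "L" that must not match the word "l").  ``direction`` applies to context
    cues only: ``"pre"`` cues scope forward, ``"post"`` cues scope backward.
    ``region`` applies to body locations ("shoulder" vs "other") and to
    injury entries with an implied location.  ``product`` names the vaccine
    product family for vaccine entries ("flu", "tdap", ...); None means a
    generic vaccine term.
    """

    entry_id: str
    semantic_class: SemanticClass
    canonical: str
    variants: list[str] = field(default_factory=list)
    match_policy: str = "case_insensitive"
    direction: str = "pre"
    region: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if not self.canonical:
            raise LexiconError(f"entry {self.entry_id}: empty canonical form")
        if any(not v for v in self.variants):
            raise LexiconError(f"entry {self.entry_id}: empty variant")
        if len(set(self.variants)) != len(self.variants):
            raise LexiconError(f"entry {self.entry_id}: duplicate variants")
        if self.match_policy not in ("case_insensitive", "exact_token_sequence"):
            raise LexiconError(
                f"entry {self.entry_id}: unknown match_policy {self.match_policy!r}"
            )

    @property
    def surfaces(self) -> list[str]:
        """Canonical form plus all variants."""
        out = [self.canonical]
        out.extend(v for v in self.variants if v != self.canonical)
        return out


@dataclass
class Lexicon:
    entries: list[LexiconEntry]
    version: str = "0"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LexiconError(f"duplicate entry ids: {dupes}")
        # No surface form may belong to two entries of the same class.
        seen: dict[tuple[SemanticClass, str], str] = {}
        for e in self.entries:
            for s in e.surfaces:
                key = (e.semantic_class, s.lower())
                if key in seen and seen[key] != e.entry_id:
                    raise LexiconError(
                        f"surface {s!r} of class {e.semantic_class.value} appears in "
                        f"both entries {seen[key]!r} and {e.entry_id!r}"
                    )
                seen[key] = e.entry_id

    def by_class(self, cls: SemanticClass) -> list[LexiconEntry]:
        return [e for e in self.entries if e.semantic_class is cls]

    def get(self, entry_id: str) -> LexiconEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def subset(self, classes: Iterable[SemanticClass]) -> "Lexicon":
        wanted = set(classes)
        return Lexicon(
            entries=[e for e in self.entries if e.semantic_class in wanted],
            version=self.version,
        )

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "id": e.entry_id,
                    "class": e.semantic_class.value,
                    "canonical": e.canonical,
                    "variants": e.variants,
                    "match_policy": e.match_policy,
                    "direction": e.direction,
                    "region": e.region,
                    "product": e.product,
                }
                for e in self.entries
            ],
        }
        return json.dumps(payload, indent=1)


def _entry_from_obj(obj: dict, where: str) -> LexiconEntry:
    try:
        cls = SemanticClass(obj["class"])
    except (KeyError, ValueError) as exc:
        raise LexiconError(f"{where}: bad semantic class in {obj!r}") from exc
    try:
        return LexiconEntry(
            entry_id=obj["id"],
            semantic_class=cls,
            canonical=obj["canonical"],
            variants=list(obj.get("variants", [])),
            match_policy=obj.get("match_policy", "case_insensitive"),
            direction=obj.get("direction", "pre"),
            region=obj.get("region"),
            product=obj.get("product"),
        )
    except KeyError as exc:
        raise LexiconError(f"{where}: missing field {exc}") from exc


def load_lexicon(path) -> Lexicon:
    """Load and validate a lexicon from a JSON file.

    The format is one object with a ``version`` string and an ``entries``
    list; each entry is ``{id, class, canonical, variants[], match_policy}``
    with optional ``direction``, ``region`` and ``product`` attributes.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LexiconError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    entries = [
        _entry_from_obj(obj, f"{path} entry {i}")
        for i, obj in enumerate(payload.get("entries", []))
    ]
    return Lexicon(entries=entries, version=str(payload.get("version", "0")))


def default_lexicon() -> Lexicon:
    """The shipped default lexicon (editable reconstruction, not a clinical gold standard)."""
    ref = resources.files("sirvanlp.data").joinpath("lexicon_default.json")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


# ---------------------------------------------------------------------------
# Variant expansion

_VOWELS = "aeiou"


def _plural(word: str) -> str:
    if word.endswith(("s", "x", "z", "ch", "sh")):
        return word + "es"
    if word.endswith("y") and len(word) > 1 and word[-2] not in _VOWELS:
        return word[:-1] + "ies"
    return word + "s"


def _verb_forms(word: str) -> list[str]:
    forms = []
    if word.endswith("e"):
        forms += [word[:-1] + "ed", word[:-1] + "ing"]
    else:
        forms += [word + "ed", word + "ing"]
    return forms


def _deletion_typos(word: str) -> list[str]:
    return [word[:i] + word[i + 1 :] for i in range(len(word))]


def expand_variants(
    entry: LexiconEntry,
    max_edit_distance: int = 0,
    known_misspellings: Sequence[str] | None = None,
) -> LexiconEntry:
    """Augment an entry's variants with rule-generated morphological forms.

    Plural/singular and -ed/-ing forms are added for single-word alphabetic
    surfaces.  With ``max_edit_distance=1``, single-character deletion typos
    are added, restricted to surfaces of length >= 4 so that short clinical
    shorthand ("flu", "s/p") is never mangled; if ``known_misspellings`` is
    given only typos present in that list are kept.
    """
    if max_edit_distance not in (0, 1):
        raise ValueError("max_edit_distance must be 0 or 1")
    new = set(entry.variants)
    for surface in entry.surfaces:
        if not surface.isalpha() or len(surface) < 4:
            continue
        new.add(_plural(surface))
        if surface.endswith("s") and len(surface) > 3:
            new.add(surface[:-1])
        new.update(_verb_forms(surface))
        if max_edit_distance == 1 and len(surface) >= 4:
            typos = _deletion_typos(surface)
            if known_misspellings is not None:
                allowed = {m.lower() for m in known_misspellings}
                typos = [t for t in typos if t.lower() in allowed]
            new.update(t for t in typos if len(t) >= 4)
    new.discard(entry.canonical)
    merged = list(entry.variants)
    merged.extend(sorted(new - set(entry.variants)))
    return LexiconEntry(
        entry_id=entry.entry_id,
        semantic_class=entry.semantic_class,
        canonical=entry.canonical,
        variants=merged,
        match_policy=entry.match_policy,
        direction=entry.direction,
        region=entry.region,
        product=entry.product,
    )


# ---------------------------------------------------------------------------
# Concept matching

class _Matcher:
    """Token-sequence matcher over a lexicon (longest match, left to right)."""

    def __init__(self, lexicon: Lexicon):
        self.table: dict[tuple[str, ...], list[tuple[LexiconEntry, bool]]] = {}
        self.max_len = 1
        for e in lexicon.entries:
            exact = e.match_policy == "exact_token_sequence"
            for s in e.surfaces:
                toks = tuple(_surface_tokens(s, lower=not exact))
                if not toks:
                    continue
                self.max_len = max(self.max_len, len(toks))
                self.table.setdefault(toks, []).append((e, exact))

    def lookup(self, toks: Sequence[str]) -> list[LexiconEntry]:
        hits = []
        for key in (tuple(t.lower() for t in toks), tuple(toks)):
            for e, exact in self.table.get(key, []):
                if exact and key != tuple(toks):
                    continue
                if not exact and key != tuple(t.lower() for t in toks):
                    continue
                hits.append(e)
        # De-duplicate while keeping order
        out, seen = [], set()
        for e in hits:
            if e.entry_id not in seen:
                seen.add(e.entry_id)
                out.append(e)
        return out


import re as _re

_SURFACE_TOKEN_RE = _re.compile(r"[A-Za-z0-9]+(?:[/\-'][A-Za-z0-9]+)*|\S")


def _surface_tokens(surface: str, lower: bool) -> list[str]:
    toks = _SURFACE_TOKEN_RE.findall(surface)
    return [t.lower() for t in toks] if lower else toks


def match_concepts(tokens, lexicon: Lexicon):
    """Match lexicon entries against a token sequence.

    ``tokens`` is a sequence of objects with ``surface`` and ``char_span``
    attributes (see :mod:`sirvanlp.note_indexing`).  Matching is greedy
    longest-match from left to right over the whole lexicon: at each
    position the longest matching surface wins, and shorter matches that
    start inside it are suppressed, so a multiword entry like "rotator cuff
    tear" shadows "rotator cuff".  Entries of different classes that match
    the same longest span are all returned.

    Returns a list of mention dicts ``{entry_id, semantic_class, char_span}``
    ordered by start offset; the caller attaches sentence indices and
    context flags.
    """
    matcher = lexicon._matcher if hasattr(lexicon, "_matcher") else _Matcher(lexicon)
    lexicon._matcher = matcher  # cache on the lexicon instance
    mentions = []
    n = len(tokens)
    i = 0
    while i < n:
        best_len = 0
        best_entries: list[LexiconEntry] = []
        upper = min(matcher.max_len, n - i)
        for length in range(upper, 0, -1):
            window = [t.surface for t in tokens[i : i + length]]
            hits = matcher.lookup(window)
            if hits:
                best_len = length
                best_entries = hits
                break
        if best_len:
            span = (tokens[i].char_span[0], tokens[i + best_len - 1].char_span[1])
            for e in best_entries:
                mentions.append(
                    {
                        "entry_id": e.entry_id,
                        "semantic_class": e.semantic_class,
                        "char_span": span,
                    }
                )
            i += best_len
        else:
            i += 1
    return mentions
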