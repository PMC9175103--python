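"""Turn raw clinical note text into an indexed document.

Indexing layers, in order: section detection (line-initial headers ending in
":" or all-caps lines), sentence segmentation (protecting clinical
abbreviations like "s/p" and decimal numbers), tokenization (preserving
intra-token "/" and "-" as in "s/p", "b/l", "x-ray"), lexicon concept
matching, and NegEx/ConText-style context scoping that flags mentions as
negated, uncertain, or hypothetical.

All character offsets are 0-based, half-open, into the original note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import datetime

from sirvanlp.terminology import (
    CUE_CLASSES,
    CAUSE_CLASSES,
    INJURY_CLASSES,
    Lexicon,
    SemanticClass,
    match_concepts,
)


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    note_datetime: datetime
    text: str


@dataclass(frozen=True)
class Section:
    label: str  # normalized header text, or "UNLABELED"
    char_span: tuple[int, int]


@dataclass(frozen=True)
class Sentence:
    index: int
    char_span: tuple[int, int]
    section_label: str


@dataclass(frozen=True)
class Token:
    char_span: tuple[int, int]
    sentence_index: int
    surface: str
    word_ordinal: int  # position among word tokens in the whole note; -1 for punctuation
    is_word: bool


@dataclass
class ConceptMention:
    entry_id: str
    semantic_class: SemanticClass
    char_span: tuple[int, int]
    sentence_index: int
    context_flags: set[str] = field(default_factory=set)

    @property
    def negated(self) -> bool:
        return "negated" in self.context_flags

    @property
    def uncertain(self) -> bool:
        return "uncertain" in self.context_flags

    @property
    def hypothetical(self) -> bool:
        return "hypothetical" in self.context_flags

    def key(self) -> tuple:
        return (self.entry_id, self.char_span)


@dataclass
class IndexedNote:
    note: ClinicalNote
    sections: list[Section]
    sentences: list[Sentence]
    tokens: list[Token]
    mentions: list[ConceptMention]

    def sentence_text(self, index: int) -> str:
        s = self.sentences[index]
        return self.note.text[s.char_span[0] : s.char_span[1]]

    def mention_text(self, m: ConceptMention) -> str:
        return self.note.text[m.char_span[0] : m.char_span[1]]

    def words_between(self, end: int, start: int) -> int:
        """Number of word tokens lying entirely within [end, start)."""
        if start < end:
            end, start = start, end
        return sum(
            1
            for t in self.tokens
            if t.is_word and t.char_span[0] >= end and t.char_span[1] <= start
        )


# ---------------------------------------------------------------------------
# Section detection

# Header = up to ~6 words of letters/digits/slashes at line start ending in ":"
_HEADER_COLON_RE = re.compile(
    r"^[ \t]{0,4}([A-Za-z][A-Za-z0-9 /&\-]{0,48}):", re.MULTILINE
)
_ALLCAPS_LINE_RE = re.compile(r"^[ \t]{0,4}([A-Z][A-Z /&\-]{2,48})[ \t]*$", re.MULTILINE)


def detect_sections(text: str, headers: Lexicon | None = None) -> list[Section]:
    """Split note text into sections that tile it.

    A section starts at each detected header (a line-initial phrase ending in
    ":" or an all-caps line) and runs to the next header or end of text;
    text before the first header is labeled "UNLABELED".  The optional header
    lexicon is used to normalize labels (the entry's canonical form wins over
    the raw surface).
    """
    if not text:
        return []
    starts: list[tuple[int, str]] = []
    for m in _HEADER_COLON_RE.finditer(text):
        starts.append((m.start(), m.group(1).strip().lower()))
    for m in _ALLCAPS_LINE_RE.finditer(text):
        label = m.group(1).strip().lower()
        if all(s != m.start() for s, _ in starts):
            starts.append((m.start(), label))
    starts.sort()

    label_map: dict[str, str] = {}
    if headers is not None:
        for e in headers.by_class(SemanticClass.SECTION_HEADER):
            for s in e.surfaces:
                label_map[s.lower()] = e.canonical.lower()

    sections: list[Section] = []
    if not starts or starts[0][0] > 0:
        end = starts[0][0] if starts else len(text)
        sections.append(Section("UNLABELED", (0, end)))
    for i, (pos, raw_label) in enumerate(starts):
        end = starts[i + 1][0] if i + 1 < len(starts) else len(text)
        sections.append(Section(label_map.get(raw_label, raw_label), (pos, end)))
    return sections


# ---------------------------------------------------------------------------
# Sentence segmentation

#: Dotted or slashed shorthand that must not end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "st", "vs", "approx", "hx", "fx", "rx", "tx",
        "pt", "appt", "dx", "sx", "etc", "e.g", "i.e", "no",
    }
)

_SENT_BREAK_RE = re.compile(r"[.!?]+[\"')\]]*(?=\s|$)|\n")
_BULLET_RE = re.compile(r"[-*•]\s")


def segment_sentences(
    section: Section,
    text: str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, int]]:
    """Split a section's text into sentence character spans.

    Splits at sentence-final punctuation and at newlines followed by a
    capitalized token or a bullet (clinical notes often lack final periods).
    A period preceded by a known abbreviation or sitting inside a decimal
    number does not split.  Returns half-open spans into the full note text,
    whitespace-trimmed.
    """
    start, end = section.char_span
    seg = text[start:end]
    breaks: list[int] = []
    for m in _SENT_BREAK_RE.finditer(seg):
        pos = m.start()
        if m.group(0) == "\n":
            nxt = seg[m.end() :].lstrip(" \t")
            if not (nxt[:1].isupper() or nxt[:1].isdigit() or _BULLET_RE.match(nxt)):
                continue
            breaks.append(m.end())
            continue
        # Decimal number guard: digit.digit
        if (
            pos > 0
            and seg[pos] == "."
            and seg[pos - 1].isdigit()
            and m.end() < len(seg)
            and seg[m.end() : m.end() + 1].isdigit()
        ):
            continue
        word = re.search(r"([A-Za-z][A-Za-z./]*)$", seg[:pos])
        if word and word.group(1).rstrip(".").lower() in abbreviations:
            continue
        breaks.append(m.end())
    spans: list[tuple[int, int]] = []
    prev = 0
    for b in breaks + [len(seg)]:
        chunk = seg[prev:b]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + prev + lstrip, start + b - rstrip))
        prev = b
    return spans


# ---------------------------------------------------------------------------
# Tokenization

#: Words keep internal "/", "-" and "'" (clinical shorthand: s/p, b/l, x-ray);
#: decimal numbers stay whole; everything else is single-character punctuation.
_TOKEN_RE = re.compile(
    r"\d+\.\d+|[A-Za-z0-9]+(?:[/\-'][A-Za-z0-9]+)*|\S"
)

_WORD_RE = re.compile(r"[A-Za-z0-9]")


def tokenize(text: str, offset: int = 0, sentence_index: int = 0) -> list[Token]:
    """Tokenize sentence text into word and punctuation tokens.

    ``offset`` shifts character spans so they index into the full note text.
    Word ordinals are assigned later at the note level (set to -1 here).
    """
    toks: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        toks.append(
            Token(
                char_span=(offset + m.start(), offset + m.end()),
                sentence_index=sentence_index,
                surface=surface,
                word_ordinal=-1,
                is_word=bool(_WORD_RE.search(surface)),
            )
        )
    return toks


# ---------------------------------------------------------------------------
# Context (NegEx/ConText-style) scoping

#: Mention classes eligible for context flags (clinical findings and causes).
_FLAGGABLE = INJURY_CLASSES | CAUSE_CLASSES

DEFAULT_SCOPE_WINDOW = 5  # word tokens after (before, for post-cues) the cue


def apply_context(
    indexed: IndexedNote,
    cue_lexicon: Lexicon | None = None,
    scope_window: int = DEFAULT_SCOPE_WINDOW,
) -> IndexedNote:
    """Flag mentions as negated/uncertain/hypothetical via cue scoping.

    A pre-cue ("denies", "no", "without", "if") opens a forward scope within
    its own sentence that closes at a termination cue ("but", "however"), at
    the sentence end, or after ``scope_window`` word tokens; a post-cue
    ("ruled out") scopes backward the same way.  Scopes never cross sentence
    boundaries.  Idempotent: flags are recomputed from cue geometry, so
    applying twice equals applying once.
    """
    flag_by_class = {
        SemanticClass.NEGATION_CUE: "negated",
        SemanticClass.UNCERTAINTY_CUE: "uncertain",
        SemanticClass.HYPOTHETICAL_CUE: "hypothetical",
    }
    cues = [m for m in indexed.mentions if m.semantic_class in flag_by_class]
    terminations = [
        m
        for m in indexed.mentions
        if m.semantic_class is SemanticClass.TERMINATION_CUE
    ]
    directions: dict[str, str] = {}
    if cue_lexicon is not None:
        for e in cue_lexicon.entries:
            if e.semantic_class in CUE_CLASSES:
                directions[e.entry_id] = e.direction

    targets = [m for m in indexed.mentions if m.semantic_class in _FLAGGABLE]
    for cue in cues:
        flag = flag_by_class[cue.semantic_class]
        direction = directions.get(cue.entry_id, "pre")
        sent = cue.sentence_index
        if direction == "pre":
            lo, hi = cue.char_span[1], indexed.sentences[sent].char_span[1]
            for t in terminations:
                if t.sentence_index == sent and t.char_span[0] >= lo:
                    hi = min(hi, t.char_span[0])
            for m in targets:
                if m.sentence_index != sent:
                    continue
                if not (lo <= m.char_span[0] < hi):
                    continue
                if indexed.words_between(lo, m.char_span[0]) > scope_window:
                    continue
                m.context_flags.add(flag)
        else:
            hi, lo = cue.char_span[0], indexed.sentences[sent].char_span[0]
            for t in terminations:
                if t.sentence_index == sent and t.char_span[1] <= hi:
                    lo = max(lo, t.char_span[1])
            for m in targets:
                if m.sentence_index != sent:
                    continue
                if not (lo <= m.char_span[0] and m.char_span[1] <= hi):
                    continue
                if indexed.words_between(m.char_span[1], hi) > scope_window:
                    continue
                m.context_flags.add(flag)
    return indexed


# ---------------------------------------------------------------------------
# Full indexing

class NoteInputError(ValueError):
    pass


def index_note(note: ClinicalNote, lexicon: Lexicon) -> IndexedNote:
    """Index a note: sections -> sentences -> tokens -> concepts -> context."""
    if not isinstance(note.text, str):
        raise NoteInputError(f"note {note.note_id}: text is not decodable string")
    sections = detect_sections(note.text, lexicon)
    sentences: list[Sentence] = []
    tokens: list[Token] = []
    for sec in sections:
        for span in segment_sentences(sec, note.text):
            idx = len(sentences)
            sentences.append(Sentence(index=idx, char_span=span, section_label=sec.label))
            tokens.extend(
                tokenize(note.text[span[0] : span[1]], offset=span[0], sentence_index=idx)
            )
    # Assign note-level word ordinals.
    ordinal = 0
    numbered: list[Token] = []
    for t in tokens:
        if t.is_word:
            numbered.append(replace(t, word_ordinal=ordinal))
            ordinal += 1
        else:
            numbered.append(t)
    tokens = numbered

    mentions: list[ConceptMention] = []
    # Match per sentence so no mention crosses a sentence boundary.
    for s in sentences:
        sent_tokens = [t for t in tokens if t.sentence_index == s.index]
        for raw in match_concepts(sent_tokens, lexicon):
            mentions.append(
                ConceptMention(
                    entry_id=raw["entry_id"],
                    semantic_class=raw["semantic_class"],
                    char_span=raw["char_span"],
                    sentence_index=s.index,
                )
            )
    indexed = IndexedNote(
        note=note, sections=sections, sentences=sentences, tokens=tokens,
        mentions=mentions,
    )
    indexed._lexicon = lexicon  # for downstream region/product lookups
    return apply_context(indexed, lexicon)


# ---------------------------------------------------------------------------
# JSON-lines I/O

def read_notes_jsonl(path) -> list[ClinicalNote]:
    """Read notes from JSON-lines: {note_id, patient_id, note_datetime, text}."""
    import json

    notes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                notes.append(
                    ClinicalNote(
                        note_id=str(obj["note_id"]),
                        patient_id=str(obj["patient_id"]),
                        note_datetime=datetime.fromisoformat(obj["note_datetime"]),
                        text=obj["text"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise NoteInputError(f"{path}:{lineno}: {exc}") from exc
    return notes


def dump_index(indexed: IndexedNote) -> dict:
    """Serializable audit view of an indexed note (for --dump-index)."""
    return {
        "note_id": indexed.note.note_id,
        "sections": [
            {"label": s.label, "span": list(s.char_span)} for s in indexed.sections
        ],
        "sentences": [
            {"index": s.index, "span": list(s.char_span), "section": s.section_label}
            for s in indexed.sentences
        ],
        "mentions": [
            {
                "entry_id": m.entry_id,
                "class": m.semantic_class.value,
                "span": list(m.char_span),
                "sentence": m.sentence_index,
                "flags": sorted(m.context_flags),
            }
            for m in indexed.mentions
        ],
    }
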