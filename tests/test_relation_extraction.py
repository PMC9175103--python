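"""Relation search engine, its brute-force oracle, and the three extractors."""

import random
from datetime import date, datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirvanlp.relation_extraction import (
    ClassConstraint,
    QueryError,
    RelationQuery,
    default_queries,
    extract_anatomic,
    extract_causal,
    extract_temporal,
    normalize_temporal,
    search_relations,
    search_relations_bruteforce,
)
from sirvanlp.terminology import SemanticClass

INJ = frozenset({SemanticClass.SHOULDER_SYMPTOM, SemanticClass.SHOULDER_DIAGNOSIS})
TRG = frozenset({SemanticClass.CAUSAL_TRIGGER})
CAUSE = frozenset(
    {
        SemanticClass.VACCINE,
        SemanticClass.CAUSE_ACCIDENT,
        SemanticClass.CAUSE_DAILY_ACTIVITY,
        SemanticClass.CAUSE_EXERCISE,
    }
)

CROSS_NOTE = (
    "Patient requesting an appointment for evaluation for left arm pain. "
    "States experiencing pain × 1 month s/p flu vaccine."
)


def _nested_query(span=4, words=50):
    return RelationQuery(
        query_id="q",
        items=[
            ClassConstraint(INJ),
            RelationQuery(
                query_id="tc",
                items=[ClassConstraint(TRG), ClassConstraint(CAUSE)],
                ordered=True,
                max_sentence_span=1,
                max_intervening_words=3,
            ),
        ],
        ordered=True,
        max_sentence_span=span,
        max_intervening_words=words,
    )


class TestSearchRelations:
    def test_cross_sentence_nested_match(self, make_note):
        idx = make_note(CROSS_NOTE)
        matches = search_relations(idx, _nested_query())
        assert matches
        cross = [m for m in matches if m.scope == "cross_sentence"]
        assert cross
        leaves = {
            (m.semantic_class.value, idx.mention_text(m).lower())
            for m in cross[0].leaf_mentions()
        }
        assert ("causal_trigger", "s/p") in leaves
        assert ("vaccine", "flu vaccine") in leaves

    def test_sentence_window_restriction(self, make_note):
        idx = make_note(CROSS_NOTE)
        matches = search_relations(idx, _nested_query(span=1))
        assert matches
        assert all(m.scope == "intra_sentence" for m in matches)
        assert all(m.sentence_window == (1, 1) for m in matches)

    def test_negated_mentions_never_ground(self, make_note):
        idx = make_note("Left shoulder pain. No injury after the fall reported.")
        q = RelationQuery(
            query_id="q",
            items=[ClassConstraint(INJ), ClassConstraint(CAUSE)],
            ordered=True,
            max_sentence_span=4,
        )
        for m in search_relations(idx, q):
            assert all(not leaf.negated for leaf in m.leaf_mentions())

    def test_unordered_collapses_symmetric_pair(self, make_note):
        idx = make_note("pain after exercise")
        q = RelationQuery(
            query_id="q",
            items=[ClassConstraint(INJ), ClassConstraint(CAUSE)],
            ordered=False,
            max_sentence_span=1,
        )
        matches = search_relations(idx, q)
        assert len(matches) == 1

    def test_depth_limit_rejected(self):
        q = _nested_query()
        deep = RelationQuery("d3", items=[q], max_sentence_span=1)
        deeper = RelationQuery("d4", items=[deep], max_sentence_span=1)
        with pytest.raises(QueryError, match="depth"):
            deeper.validate()

    def test_zero_mention_note_empty(self, make_note):
        idx = make_note("Nothing relevant here at all.")
        assert search_relations(idx, _nested_query()) == []
        assert search_relations_bruteforce(idx, _nested_query()) == []

    def test_default_query_file_loads(self):
        queries = default_queries()
        assert {q.query_id for q in queries} == {"causal_intra", "causal_cross"}


# ---------------------------------------------------------------------------
# Oracle equivalence on randomized notes

_VOCAB = [
    "pain", "soreness", "bursitis", "shoulder", "arm", "left", "right",
    "due to", "after", "s/p", "flu vaccine", "vaccination", "fell",
    "lifting", "exercise", "no", "denies", "but", "visit", "states",
    "patient", "reports", "mild", "the", "and", "today", "improving",
]


def _random_note_text(rng):
    n_sent = rng.randint(1, 5)
    sents = []
    for _ in range(n_sent):
        words = [rng.choice(_VOCAB) for _ in range(rng.randint(2, 8))]
        sents.append(" ".join(words).capitalize() + ".")
    return " ".join(sents)


def _random_query(rng):
    pools = [INJ, TRG, CAUSE, frozenset({SemanticClass.LATERALITY})]
    n_items = rng.randint(2, 3)
    items = [ClassConstraint(rng.choice(pools)) for _ in range(n_items)]
    if rng.random() < 0.4:
        items[-1] = RelationQuery(
            query_id="nested",
            items=[ClassConstraint(rng.choice(pools)), ClassConstraint(rng.choice(pools))],
            ordered=rng.random() < 0.7,
            max_sentence_span=1,
            max_intervening_words=rng.randint(0, 5),
        )
    return RelationQuery(
        query_id="rand",
        items=items,
        ordered=rng.random() < 0.7,
        max_sentence_span=rng.randint(1, 4),
        max_intervening_words=rng.randint(0, 50),
        require_same_section=rng.random() < 0.5,
    )


def _match_keys(matches):
    return sorted(m.key() for m in matches)


class TestOracleEquivalence:
    def test_engine_equals_bruteforce_on_randomized_notes(self, make_note):
        rng = random.Random(20170324)
        n_with_matches = 0
        for i in range(550):
            idx = make_note(_random_note_text(rng), note_id=f"r{i}")
            if len(idx.mentions) > 50:
                continue
            query = _random_query(rng)
            fast = search_relations(idx, query)
            slow = search_relations_bruteforce(idx, query)
            assert _match_keys(fast) == _match_keys(slow), (
                f"divergence on note {i}: {idx.note.text!r} query={query}"
            )
            n_with_matches += bool(fast)
        assert n_with_matches > 50  # the comparison must be non-vacuous

    def test_bruteforce_refuses_oversized_notes(self, make_note):
        idx = make_note(" ".join(["pain"] * 60))
        with pytest.raises(QueryError, match="brute-force"):
            search_relations_bruteforce(idx, _nested_query())

    def test_window_monotonicity(self, make_note):
        rng = random.Random(7)
        for i in range(60):
            idx = make_note(_random_note_text(rng), note_id=f"m{i}")
            base = _random_query(rng)
            small = search_relations(idx, base)
            bigger = RelationQuery(
                query_id=base.query_id,
                items=base.items,
                ordered=base.ordered,
                max_sentence_span=base.max_sentence_span + 2,
                max_intervening_words=base.max_intervening_words + 20,
                require_same_section=base.require_same_section,
            )
            large = search_relations(idx, bigger)
            assert set(_match_keys(small)) <= set(_match_keys(large))


# ---------------------------------------------------------------------------
# Anatomic extraction

class TestAnatomic:
    def test_left_arm_pain(self, make_note, lexicon):
        idx = make_note("Patient has persistent pain in his left arm.")
        (f,) = extract_anatomic(idx, lexicon)
        assert (f.laterality, f.body_location) == ("left", "arm")
        assert f.region == "shoulder"

    def test_missing_laterality_unknown(self, make_note, lexicon):
        idx = make_note("shoulder pain")
        (f,) = extract_anatomic(idx, lexicon)
        assert f.laterality == "unknown"
        assert f.body_location == "shoulder"

    def test_bilateral_abbreviation(self, make_note, lexicon):
        idx = make_note("She has chronic pain—neck, low back, B/L shoulders.")
        (f,) = extract_anatomic(idx, lexicon)
        assert f.laterality == "bilateral"

    def test_negated_mention_yields_no_finding(self, make_note, lexicon):
        idx = make_note("Denies any shoulder pain.")
        assert extract_anatomic(idx, lexicon) == []

    def test_tie_prefers_preceding_laterality(self, make_note, lexicon):
        idx = make_note("left pain right")  # equidistant: prefer the preceding one
        (f,) = extract_anatomic(idx, lexicon)
        assert f.laterality == "left"

    def test_diagnosis_implies_shoulder_region(self, make_note, lexicon):
        idx = make_note("Likely subdeltoid bursitis.")
        (f,) = extract_anatomic(idx, lexicon)
        assert f.region == "shoulder"
        assert f.body_location == "shoulder"


# ---------------------------------------------------------------------------
# Temporal normalization and extraction

class TestNormalizeTemporal:
    @pytest.mark.parametrize(
        "expr,note_date,onset,duration",
        [
            ("since last Thursday", date(2017, 3, 15), date(2017, 3, 9), None),
            ("for 2 months", date(2017, 6, 1), date(2017, 4, 2), 60),
            ("today", date(2017, 6, 1), date(2017, 6, 1), None),
            ("yesterday", date(2017, 6, 1), date(2017, 5, 31), None),
            ("3 weeks ago", date(2017, 6, 1), date(2017, 5, 11), None),
            ("over the past 2 weeks", date(2017, 6, 1), date(2017, 5, 18), 14),
            ("for a year", date(2017, 6, 1), date(2016, 6, 1), 365),
            ("× 1 month", date(2017, 3, 20), date(2017, 2, 18), 30),
            ("lasting a few days", date(2017, 3, 20), date(2017, 3, 17), 3),
            ("on 3/12", date(2017, 3, 20), date(2017, 3, 12), None),
            ("on March 12, 2016", date(2017, 3, 20), date(2016, 3, 12), None),
            ("since December 30", date(2017, 1, 5), date(2016, 12, 30), None),
            ("gibberish expression", date(2017, 1, 5), None, None),
        ],
    )
    def test_conventions(self, expr, note_date, onset, duration):
        assert normalize_temporal(expr, note_date) == (onset, duration)

    def test_yearless_tie_prefers_earlier_year(self):
        # July 2 is equidistant (182/183 days) only in non-leap arithmetic;
        # construct an exact tie: anchor midway between two candidates.
        onset, _ = normalize_temporal("on 1/1", date(2017, 7, 2))
        assert onset == date(2017, 1, 1)

    @given(
        st.dates(min_value=date(2015, 1, 1), max_value=date(2019, 12, 31)),
        st.integers(min_value=1, max_value=24),
        st.sampled_from(["day", "week", "month"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_duration_purity_and_consistency(self, note_date, n, unit):
        expr = f"for {n} {unit}s"
        a = normalize_temporal(expr, note_date)
        b = normalize_temporal(expr, note_date)
        assert a == b
        onset, duration = a
        assert duration == n * {"day": 1, "week": 7, "month": 30}[unit]
        assert onset == note_date - timedelta(days=duration)


class TestExtractTemporal:
    def test_duration_with_onset_backdated(self, make_note):
        idx = make_note(
            "Reports having R shoulder pain for last 2 months.",
            note_dt=datetime(2017, 6, 1, 9, 0),
        )
        (f,) = extract_temporal(idx, index_date=date(2017, 4, 1))
        assert f.duration_days == 60
        assert f.onset_date == date(2017, 4, 2)
        assert f.onset_day_offset == 1

    def test_resolved_symptom_flagged(self, make_note):
        idx = make_note(
            "States in past pain would travel to left shoulder causing numbness "
            "to left arm and lasting a few days but today denies any numbness."
        )
        findings = extract_temporal(idx, index_date=date(2017, 3, 1))
        assert findings
        assert any(f.resolved for f in findings)

    def test_no_expression_no_finding(self, make_note):
        idx = make_note("shoulder pain")
        assert extract_temporal(idx, index_date=date(2017, 3, 1)) == []

    def test_vaccination_anchored_onset(self, make_note):
        idx = make_note(
            "Left shoulder pain that started 2 days after the flu shot.",
            note_dt=datetime(2017, 5, 1, 9, 0),
        )
        findings = extract_temporal(idx, index_date=date(2017, 4, 1))
        assert any(f.onset_day_offset == 2 for f in findings)


# ---------------------------------------------------------------------------
# Causal extraction

class TestExtractCausal:
    def test_cross_sentence_vaccination_cause(self, make_note, lexicon):
        idx = make_note(CROSS_NOTE)
        findings = extract_causal(idx, lexicon)
        vax = [f for f in findings if f.cause_type == "vaccination"]
        assert len(vax) == 1
        assert vax[0].scope == "cross_sentence"
        assert vax[0].vaccine_name == "flu"

    def test_intra_sentence_daily_activity(self, make_note, lexicon):
        idx = make_note(
            "...who complains of left shoulder pain that started 3 weeks ago "
            "after vacuuming."
        )
        findings = extract_causal(idx, lexicon)
        assert [(f.cause_type, f.scope) for f in findings] == [
            ("daily_activity", "intra_sentence")
        ]

    def test_negated_cause_yields_nothing(self, make_note, lexicon):
        for text in ("Denies any injury.", "No injury or trauma."):
            idx = make_note(text)
            assert extract_causal(idx, lexicon) == []

    def test_non_shoulder_anchor_blocked_by_strict_anatomy(self, make_note, lexicon):
        idx = make_note(
            "She has chronic pain—neck, low back, B/L shoulders. She has "
            "fibromyalgia and also fell a few weeks ago which worsened her "
            "back pain."
        )
        assert extract_causal(idx, lexicon, strict_anatomy=True) == []

    def test_strict_anatomy_toggle(self, make_note, lexicon):
        idx = make_note("Her back pain started after a fall.")
        assert extract_causal(idx, lexicon, strict_anatomy=True) == []
        relaxed = extract_causal(idx, lexicon, strict_anatomy=False)
        assert any(f.cause_type == "accident" for f in relaxed)

    def test_vaccination_iff_vaccine_mention(self, make_note, lexicon):
        idx = make_note("Left shoulder pain due to flu vaccine after lifting.")
        for f in extract_causal(idx, lexicon):
            if f.cause_type == "vaccination":
                assert f.cause_mention.semantic_class is SemanticClass.VACCINE
            else:
                assert f.cause_mention.semantic_class is not SemanticClass.VACCINE

    def test_unknown_cause_statement(self, make_note, lexicon):
        idx = make_note("Left shoulder pain, insidious onset.")
        findings = extract_causal(idx, lexicon)
        assert [f.cause_type for f in findings] == ["unknown"]

    def test_hypothetical_mentions_never_anchor(self, make_note, lexicon):
        idx = make_note("Return if pain worsens after exercise.")
        assert extract_causal(idx, lexicon) == []
        assert extract_anatomic(idx, lexicon) == []
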