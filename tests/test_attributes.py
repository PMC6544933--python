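"""Attribute normalization methods and their contracts."""

from fractions import Fraction
from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from rxsig import TagInstance, validate_tag
from rxsig.attributes import (
    VALID_NUMERIC_VALUES,
    BaselinePredictor,
    ClassifierPredictor,
    FreqNormalizer,
    LiteralPredictor,
    SpanContext,
    TimingNormalizer,
    build_context,
    edit_distance,
    map_numeric,
    snap_valid,
)


def _ctx(text: str, left=(), right=()) -> SpanContext:
    from rxsig.numbers import find_number_expressions
    from rxsig.tagger import tokenize

    return SpanContext(
        text=text, tokens=tuple(t.surface for t in tokenize(text)),
        left=tuple(left), right=tuple(right),
        num_count=len(find_number_expressions(text)))


# ---------------------------------------------------------------------------
# Edit distance against an exhaustive recursive oracle

@lru_cache(maxsize=None)
def _oracle_distance(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _oracle_distance(a[1:], b) + 1,
        _oracle_distance(a, b[1:]) + 1,
        _oracle_distance(a[1:], b[1:]) + (a[0] != b[0]),
    )


def _all_strings(alphabet: str, max_len: int):
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        out.extend(frontier)
    return out


def test_edit_distance_examples():
    assert edit_distance("a", "a") == 0
    assert edit_distance("kitten", "sitting") == 3
    assert edit_distance("", "abc") == 3
    assert edit_distance("abc", "") == 3
    assert edit_distance("", "") == 0


def test_edit_distance_matches_oracle_exhaustive_short():
    strings = _all_strings("abelt", 3)  # all 156 strings of length <= 3
    for a in strings:
        for b in strings:
            assert edit_distance(a, b) == _oracle_distance(a, b)


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet="abelt", max_size=6), st.text(alphabet="abelt", max_size=6))
def test_edit_distance_matches_oracle_length_six(a, b):
    assert edit_distance(a, b) == _oracle_distance(a, b)


# ---------------------------------------------------------------------------
# Snap to the valid numeric set

@pytest.mark.parametrize("value, expected", [
    (1, 1), (12, 12), (13, 12), (14, 15), (13.5, 12), (22, 15), (23, 30),
    (50, 45), (53, 60), (100, 60), (0, 1), (0.2, 1),
])
def test_snap_valid(value, expected):
    assert snap_valid(value) == expected


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0, max_value=200, allow_nan=False))
def test_snap_is_nearest_member(v):
    s = snap_valid(v)
    assert s in VALID_NUMERIC_VALUES
    assert all(abs(s - Fraction(str(v))) <= abs(w - Fraction(str(v)))
               for w in VALID_NUMERIC_VALUES)


# ---------------------------------------------------------------------------
# Baseline / literal / levenshtein predictors

def test_baseline_majority():
    p = BaselinePredictor().fit(["day"] * 5 + ["hour"] * 2)
    assert p.predict(_ctx("anything")) == "day"


def test_baseline_single_value():
    assert BaselinePredictor().fit(["mg"]).predict(_ctx("x")) == "mg"


def test_baseline_requires_values():
    with pytest.raises(ValueError):
        BaselinePredictor().fit([None, None])


ALLOWED_UNITS = ("minute", "hour", "day", "week", "month", "other")


def test_literal_table_lookup():
    p = LiteralPredictor(("tablet", "capsule")).fit(
        ["tabs", "tabs", "tabs"], ["tablet", "tablet", "tablet"])
    assert p.predict(_ctx("tabs")) == "tablet"
    assert p.predict(_ctx("Tabs ")) == "tablet"  # case/space folded


def test_literal_fallback_exact_allowed_value():
    p = LiteralPredictor(ALLOWED_UNITS).fit(["days"], ["day"])
    assert p.predict(_ctx("week")) == "week"  # unseen but an allowed value


def test_literal_double_miss_returns_majority():
    p = LiteralPredictor(ALLOWED_UNITS).fit(["days", "days", "hrs"],
                                            ["day", "day", "hour"])
    assert p.predict(_ctx("zzz")) == "day"


def test_levenshtein_same_as_literal_on_seen_spans():
    spans = ["days", "hrs", "weeks"]
    values = ["day", "hour", "week"]
    lit = LiteralPredictor(ALLOWED_UNITS).fit(spans, values)
    lev = LiteralPredictor(ALLOWED_UNITS, levenshtein=True).fit(spans, values)
    for s in spans:
        assert lev.predict(_ctx(s)) == lit.predict(_ctx(s))


def test_levenshtein_resolves_misspelling():
    p = LiteralPredictor(("tablet", "capsule"), levenshtein=True).fit(
        ["tablet"], ["tablet"])
    assert p.predict(_ctx("tablts")) == "tablet"


def test_levenshtein_tie_breaks_lexicographically():
    # "dayz" is distance 1 from "day" and "days" is not allowed; construct an
    # equidistant case: "har" is distance 2 from both "hour" and "day"... use
    # explicit equal-frequency training and an equidistant query.
    p = LiteralPredictor(("aa", "bb"), levenshtein=True).fit(
        ["aa", "bb"], ["aa", "bb"])
    # "ab" is distance 1 from both; equal frequency -> lexicographic
    assert p.predict(_ctx("ab")) == "aa"


# ---------------------------------------------------------------------------
# Classifier predictor

def test_classifier_separable_by_word():
    contexts = [_ctx("every 4 hours"), _ctx("every 6 hours"),
                _ctx("3 times a day"), _ctx("2 times a day")]
    values = ["hour", "hour", "day", "day"]
    clf = ClassifierPredictor(seed=0).fit(contexts, values)
    for c, v in zip(contexts, values):
        assert clf.predict(c) == v


def test_classifier_single_class_degenerates_to_constant():
    clf = ClassifierPredictor(seed=0).fit([_ctx("a"), _ctx("b")], ["x", "x"])
    assert clf.predict(_ctx("unseen")) == "x"


def test_classifier_boolean_refill_separable():
    contexts = [_ctx("no refills"), _ctx("refill ok")]
    clf = ClassifierPredictor(seed=0).fit(contexts, ["false", "true"])
    assert clf.predict(contexts[0]) == "false"
    assert clf.predict(contexts[1]) == "true"


# ---------------------------------------------------------------------------
# FREQ normalization

@pytest.fixture(scope="module")
def freq_normalizer():
    rows = [
        ("2 times a day", {"times_per": 2, "every": 1, "unit": "day"}),
        ("3 times per day", {"times_per": 3, "every": 1, "unit": "day"}),
        ("2-3 times per day", {"times_per": 2, "to_times_per": 3, "every": 1,
                               "unit": "day"}),
        ("4 times daily", {"times_per": 4, "every": 1, "unit": "day"}),
        ("every 4 hours", {"times_per": 1, "every": 4, "unit": "hour"}),
        ("every 6 hours", {"times_per": 1, "every": 6, "unit": "hour"}),
        ("every 4-6 hours", {"times_per": 1, "every": 4, "to_every": 6,
                             "unit": "hour"}),
        ("every 2 days", {"times_per": 1, "every": 2, "unit": "day"}),
        ("every 3 days", {"times_per": 1, "every": 3, "unit": "day"}),
        ("once daily", {"times_per": 1, "every": 1, "unit": "day"}),
        ("twice a day", {"times_per": 2, "every": 1, "unit": "day"}),
        ("every 1 week", {"times_per": 1, "every": 1, "unit": "week"}),
        ("2 times per week", {"times_per": 2, "every": 1, "unit": "week"}),
    ] * 3  # enough repeats for stable classifier fits
    contexts = [_ctx(t) for t, _ in rows]
    return FreqNormalizer(seed=0).fit(contexts, [a for _, a in rows])


def test_freq_baseline_defaults(freq_normalizer):
    out = freq_normalizer.normalize(_ctx("whatever"), "baseline")
    assert out["times_per"] == 1 and out["every"] == 1
    assert out["to_times_per"] is None and out["to_every"] is None
    assert out["unit"] == "day"  # majority unit in training


def test_freq_hybrid_count_range(freq_normalizer):
    out = freq_normalizer.normalize(_ctx("2-3 times per day"), "hybrid")
    assert out == {"unit": "day", "times_per": 2, "to_times_per": 3,
                   "every": 1, "to_every": None}


def test_freq_hybrid_interval_range(freq_normalizer):
    out = freq_normalizer.normalize(_ctx("every 4-6 hours"), "hybrid")
    assert out["every"] == 4 and out["to_every"] == 6
    assert out["times_per"] == 1 and out["unit"] == "hour"


def test_freq_interval_vs_count_distinct(freq_normalizer):
    interval = freq_normalizer.normalize(_ctx("every 3 days"), "hybrid")
    count = freq_normalizer.normalize(_ctx("3 times per day"), "hybrid")
    assert interval["every"] == 3 and interval["times_per"] == 1
    assert count["times_per"] == 3 and count["every"] == 1
    assert interval != count


def test_freq_idiom_without_digits(freq_normalizer):
    out = freq_normalizer.normalize(_ctx("twice a day"), "hybrid")
    assert out["times_per"] == 2 and out["every"] == 1


def test_freq_classifier_snaps_to_valid_set(freq_normalizer):
    out = freq_normalizer.normalize(_ctx("every 4 hours"), "classifier")
    for name in ("times_per", "to_times_per", "every", "to_every"):
        assert out[name] is None or out[name] in VALID_NUMERIC_VALUES


# ---------------------------------------------------------------------------
# TIMING normalization

@pytest.fixture(scope="module")
def timing_normalizer():
    rows = [
        ("before meals", {"direction": "before", "event": "meals"}),
        ("after meals", {"direction": "after", "event": "meals"}),
        ("at bedtime", {"event": "bedtime"}),
        ("in the morning", {"event": "morning"}),
        ("1 hour after meals", {"offset": 1, "offset_unit": "hour",
                                "direction": "after", "event": "meals"}),
        ("30 minutes before breakfast", {"offset": 30,
                                         "offset_unit": "minute",
                                         "direction": "before",
                                         "event": "breakfast"}),
        ("before breakfast", {"direction": "before", "event": "breakfast"}),
        ("after dinner", {"direction": "after", "event": "dinner"}),
    ] * 3
    contexts = [_ctx(t) for t, _ in rows]
    return TimingNormalizer(seed=0).fit(contexts, [a for _, a in rows])


def test_timing_hybrid_offset_phrase(timing_normalizer):
    out = timing_normalizer.normalize(_ctx("1 hour after meals"), "hybrid")
    assert out["offset"] == 1 and out["offset_unit"] == "hour"
    assert out["direction"] == "after" and out["event"] == "meals"


def test_timing_hybrid_bare_event(timing_normalizer):
    out = timing_normalizer.normalize(_ctx("before meals"), "hybrid")
    assert out["direction"] == "before" and out["event"] == "meals"
    assert out["offset"] is None


def test_timing_bedtime_direction_null(timing_normalizer):
    out = timing_normalizer.normalize(_ctx("at bedtime"), "hybrid")
    assert out["event"] == "bedtime"
    assert out["direction"] in (None, "other")


# ---------------------------------------------------------------------------
# Numeric mapping

@pytest.mark.parametrize("span, mode, expected", [
    ("3", "normalized", {"amount": 3, "to_amount": None}),
    ("three", "unnormalized", {"amount": "three", "to_amount": None}),
    ("2-3", "normalized", {"num": 2, "to_num": 3}),
    ("1.5", "normalized", {"amount": 1.5, "to_amount": None}),
])
def test_map_numeric(span, mode, expected):
    names = tuple(expected.keys())
    assert map_numeric(span, mode, names) == expected


def test_map_numeric_no_number_yields_null():
    out = map_numeric("some", "normalized")
    assert out == {"amount": None, "to_amount": None}


def test_map_numeric_word_span_uses_retokenizer():
    # the gold span "three" must normalize to 3 (after canonicalization)
    ctx = build_context("take three tablets", 5, 10)
    assert ctx.text == "3"
    assert map_numeric(ctx.text, "normalized") == {"amount": 3,
                                                   "to_amount": None}


# ---------------------------------------------------------------------------
# Type safety: every predicted attribute map validates against the schema

def test_predicted_attributes_validate(registry, attribute_bundle,
                                       corpus_split):
    _, test_docs = corpus_split
    checked = 0
    for doc in test_docs[:80]:
        for t in doc.tags:
            for methods in ({"choice_method": "baseline",
                             "freq_method": "baseline"},
                            {"choice_method": "levenshtein",
                             "freq_method": "hybrid"},
                            {"choice_method": "classifier",
                             "freq_method": "classifier"}):
                attrs = attribute_bundle.predict_tag(doc.text, t, **methods)
                probe = TagInstance(t.label, t.start, t.end, attrs)
                assert validate_tag(probe, len(doc.text), registry) == []
                checked += 1
    assert checked > 100
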