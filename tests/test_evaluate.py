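"""Span scoring, pairwise agreement, attribute accuracy, corpus splits."""

import random

import pytest

from rxsig import (
    SigDocument,
    TagInstance,
    attribute_accuracy,
    pairwise_agreement,
    score_spans,
    split_corpus,
)


def _doc(doc_id, text, spans):
    return SigDocument(doc_id, text,
                       [TagInstance(lbl, a, b) for lbl, a, b in spans])


def test_perfect_agreement_scores_one(corpus):
    ref = corpus[:50]
    report = score_spans(ref, ref)
    assert report.overall.f_measure == 1.0
    for counts in report.per_label.values():
        assert counts.f_measure == 1.0


def test_empty_hypothesis_convention():
    ref = [_doc("d", "take 2 tablets", [("TAKE", 5, 6)])]
    hyp = [_doc("d", "take 2 tablets", [])]
    overall = score_spans(ref, hyp).overall
    assert overall.precision == 1.0
    assert overall.recall == 0.0
    assert overall.f_measure == 0.0


def test_half_right_hypothesis():
    ref = [_doc("d", "take 2 tablets now", [("TAKE", 5, 6),
                                            ("DOSEFORM", 7, 14)])]
    hyp = [_doc("d", "take 2 tablets now", [("TAKE", 5, 6),
                                            ("FREQ", 15, 18)])]
    overall = score_spans(ref, hyp).overall
    assert overall.precision == 0.5
    assert overall.recall == 0.5
    assert overall.f_measure == 0.5


def test_doc_id_mismatch_raises():
    with pytest.raises(ValueError):
        score_spans([_doc("a", "x", [])], [_doc("b", "x", [])])


def test_micro_consistency(corpus, trained_tagger):
    from rxsig import tag

    ref = corpus[800:900]
    hyp = [SigDocument(d.doc_id, d.text, tag(trained_tagger, d.text, 0.0))
           for d in ref]
    report = score_spans(ref, hyp)
    overall = report.overall
    assert overall.tp + overall.fn == sum(len(d.tags) for d in ref)
    assert overall.tp + overall.fp == sum(len(d.tags) for d in hyp)


def test_pairwise_agreement_symmetry_random():
    rng = random.Random(5)
    docs_a, docs_b = [], []
    for i in range(30):
        text = "x" * 40
        spans_a = [("TAKE", s, s + 2) for s in rng.sample(range(0, 38), 3)]
        spans_b = [("TAKE", s, s + 2) for s in rng.sample(range(0, 38), 3)]
        docs_a.append(_doc(f"d{i}", text, spans_a))
        docs_b.append(_doc(f"d{i}", text, spans_b))
    ab = pairwise_agreement(docs_a, docs_b)
    ba = pairwise_agreement(docs_b, docs_a)
    assert ab.overall.f_measure == pytest.approx(ba.overall.f_measure)
    assert ab.overall.precision == pytest.approx(ba.overall.recall)


def test_disjoint_annotations_score_zero():
    a = [_doc("d", "take two tablets", [("TAKE", 5, 8)])]
    b = [_doc("d", "take two tablets", [("DOSEFORM", 9, 16)])]
    assert pairwise_agreement(a, b).overall.f_measure == 0.0


# ---------------------------------------------------------------------------
# Attribute accuracy

def test_attribute_accuracy_all_correct():
    gold = [SigDocument("d", "take 2 tablets", [
        TagInstance("TAKE", 5, 6, {"amount": 2})])]
    pred = {"d": [TagInstance("TAKE", 5, 6, {"amount": 2})]}
    report = attribute_accuracy(gold, pred)
    assert report.accuracy("TAKE", "amount") == 1.0


def test_attribute_accuracy_majority_arithmetic():
    gold, pred = [], {}
    for i in range(10):
        unit = "day" if i < 7 else "hour"
        gold.append(SigDocument(f"d{i}", "unit span", [
            TagInstance("DURATION_UNIT", 0, 4, {"unit": unit})]))
        pred[f"d{i}"] = [TagInstance("DURATION_UNIT", 0, 4, {"unit": "day"})]
    report = attribute_accuracy(gold, pred)
    assert report.accuracy("DURATION_UNIT", "unit") == pytest.approx(0.7)


def test_attribute_accuracy_excludes_null_gold():
    gold = [SigDocument("d", "twice a day", [
        TagInstance("FREQ", 0, 11, {"times_per": 2, "to_every": None})])]
    pred = {"d": [TagInstance("FREQ", 0, 11, {"times_per": 2,
                                              "to_every": 5})]}
    report = attribute_accuracy(gold, pred)
    assert report.accuracy("FREQ", "times_per") == 1.0
    assert report.accuracy("FREQ", "to_every") is None  # all-null excluded


def test_attribute_accuracy_rejects_unknown_span():
    gold = [SigDocument("d", "take 2", [TagInstance("TAKE", 5, 6)])]
    pred = {"d": [TagInstance("TAKE", 0, 4, {"amount": 1})]}
    with pytest.raises(ValueError):
        attribute_accuracy(gold, pred)


# ---------------------------------------------------------------------------
# Corpus splitting

def test_split_sizes():
    docs = [_doc(f"d{i}", "x", []) for i in range(10)]
    train, test = split_corpus(docs, 0.8, seed=1)
    assert len(train) == 8 and len(test) == 2


def test_split_deterministic_and_exhaustive():
    docs = [_doc(f"d{i}", "x", []) for i in range(37)]
    a = split_corpus(docs, 0.8, seed=9)
    b = split_corpus(docs, 0.8, seed=9)
    assert [d.doc_id for d in a[0]] == [d.doc_id for d in b[0]]
    ids = {d.doc_id for d in a[0]} | {d.doc_id for d in a[1]}
    assert ids == {d.doc_id for d in docs}
    assert not ({d.doc_id for d in a[0]} & {d.doc_id for d in a[1]})


def test_split_rounding_on_full_corpus_size():
    docs = [_doc(f"d{i}", "x", []) for i in range(1746)]
    train, test = split_corpus(docs, 0.8, seed=0)
    assert len(train) == 1397 and len(test) == 349


def test_split_rejects_empty_and_bad_ratio():
    with pytest.raises(ValueError):
        split_corpus([], 0.8, seed=0)
    with pytest.raises(ValueError):
        split_corpus([_doc("d", "x", [])], 1.5, seed=0)
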