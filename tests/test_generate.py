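"""Synthetic corpus generator: determinism, validity, frequency profile."""

import random

import pytest

from rxsig import (
    GeneratorConfig,
    NoiseConfig,
    generate_corpus,
    validate_document,
)
from rxsig.generate import (
    DEFAULT_TAG_WEIGHTS,
    TEMPLATES,
    fit_template_weights,
    realize_template,
)
from rxsig.io import doc_to_dict
from rxsig.schema import LABELS


def test_same_seed_identical_corpora():
    a = generate_corpus(GeneratorConfig(n_documents=5, seed=17))
    b = generate_corpus(GeneratorConfig(n_documents=5, seed=17))
    assert [doc_to_dict(d) for d in a.documents] == [
        doc_to_dict(d) for d in b.documents]
    assert a.records == b.records


def test_different_seed_differs():
    a = generate_corpus(GeneratorConfig(n_documents=20, seed=1))
    b = generate_corpus(GeneratorConfig(n_documents=20, seed=2))
    assert [d.text for d in a.documents] != [d.text for d in b.documents]


def test_every_document_validates(registry, corpus):
    for doc in corpus:
        report = validate_document(doc, registry)
        assert report.ok, (doc.text, report.violations)


def test_gold_spans_cover_slot_surfaces(corpus):
    for doc in corpus[:200]:
        for tag in doc.tags:
            surface = doc.text[tag.start:tag.end]
            assert surface == surface.strip() and surface


def test_template_coverage_of_all_labels():
    covered = set()
    for tpl in TEMPLATES:
        covered.update(tpl.label_counts())
    assert covered == set(LABELS)


def test_frequency_profile_fidelity():
    from scipy.stats import chisquare

    docs, _, _ = generate_corpus(GeneratorConfig(n_documents=2000, seed=17))
    counts = {l: 0 for l in LABELS}
    for d in docs:
        for t in d.tags:
            counts[t.label] += 1
    total = sum(counts.values())
    target_total = sum(DEFAULT_TAG_WEIGHTS.values())
    observed = [counts[l] for l in LABELS]
    expected = [DEFAULT_TAG_WEIGHTS[l] / target_total * total for l in LABELS]
    # chi-square goodness of fit across the whole profile
    _stat, p = chisquare(observed, expected)
    assert p > 0.001
    # the ±20% band is meaningful where expected counts are large enough
    # for sampling noise to sit well inside it
    for label in LABELS:
        exp = DEFAULT_TAG_WEIGHTS[label] / target_total
        if exp * total >= 100:
            assert counts[label] / total == pytest.approx(exp, rel=0.2), label
    # FREQ and TIMING dominate every other non-INSTRUCTION label
    non_instr = {l: c for l, c in counts.items() if l != "INSTRUCTION"}
    top_two = sorted(non_instr, key=non_instr.get, reverse=True)[:2]
    assert set(top_two) == {"FREQ", "TIMING"}


def test_template_weights_match_targets_in_expectation():
    weights = fit_template_weights(DEFAULT_TAG_WEIGHTS)
    expected = {l: 0.0 for l in LABELS}
    for tpl, p in zip(TEMPLATES, weights):
        for l, c in tpl.label_counts().items():
            expected[l] += p * c
    total = sum(expected.values())
    target_total = sum(DEFAULT_TAG_WEIGHTS.values())
    for label in LABELS:
        assert expected[label] / total == pytest.approx(
            DEFAULT_TAG_WEIGHTS[label] / target_total, rel=0.1), label


def test_realize_template_gold_attributes_precede_word_rendering():
    # a slot rendered as a number word still carries the numeric gold value
    rng = random.Random(3)
    tpl = next(t for t in TEMPLATES
               if t.parts[:2] == ("take ", "TAKE"))
    noise = NoiseConfig(number_word_prob=1.0, misspelling_prob=0.0)
    seen_word = False
    for _ in range(40):
        doc, _updates = realize_template(tpl, rng, noise)
        take = next(t for t in doc.tags if t.label == "TAKE")
        surface = doc.text[take.start:take.end]
        if surface.isalpha() or " " in surface:
            seen_word = True
            from rxsig.numbers import parse_number

            assert parse_number(surface) is not None
            assert float(parse_number(surface)) == float(take.get("amount"))
    assert seen_word


def test_zero_noise_means_digits_only_and_no_misspellings(registry):
    config = GeneratorConfig(
        n_documents=150, seed=5,
        noise=NoiseConfig(misspelling_prob=0.0, abbreviation_prob=0.0,
                          number_word_prob=0.0))
    docs, _, _ = generate_corpus(config)
    for doc in docs:
        for tag in doc.tags:
            if tag.label in ("TAKE", "DISPENSE", "STRENGTH", "DOSEAMOUNT",
                             "DURATION"):
                surface = doc.text[tag.start:tag.end]
                assert not any(c.isalpha() for c in surface), surface


def test_prn_template_emits_prn_and_indication(corpus):
    joint = [d for d in corpus
             if d.tags_with_label("PRN") and d.tags_with_label("INDICATION")]
    assert joint
    for doc in joint[:20]:
        prn = doc.tags_with_label("PRN")[0]
        assert doc.text[prn.start:prn.end] in ("as needed", "prn")


def test_zero_discrepancy_rate_produces_no_findings(corpus_bundle):
    from rxsig import compare_record

    docs, records, perturbations = corpus_bundle
    assert perturbations == []
    for rec, doc in zip(records[:300], docs[:300]):
        assert compare_record(rec, doc).findings == []


def test_records_paired_with_documents(corpus_bundle):
    docs, records, _ = corpus_bundle
    assert len(docs) == len(records)
    for rec, doc in zip(records, docs):
        assert rec.directions == doc.text
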