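"""Shared fixtures: schema registry, synthetic corpora, trained models.

The expensive artifacts (1000-document corpus, trained tagger, fitted
attribute bundle) are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import pytest

from rxsig import (
    AttributeModelBundle,
    GeneratorConfig,
    SequenceTagger,
    TaggerConfig,
    generate_corpus,
    load_schema,
    split_corpus,
    train,
)


@pytest.fixture(scope="session")
def registry():
    return load_schema()


@pytest.fixture(scope="session")
def corpus_bundle():
    """1000 synthetic sigs at seed 17 with default noise, no discrepancies."""
    return generate_corpus(GeneratorConfig(n_documents=1000, seed=17))


@pytest.fixture(scope="session")
def corpus(corpus_bundle):
    return corpus_bundle.documents


@pytest.fixture(scope="session")
def corpus_split(corpus):
    return split_corpus(corpus, 0.8, seed=17)


@pytest.fixture(scope="session")
def trained_tagger(corpus_split) -> SequenceTagger:
    train_docs, _ = corpus_split
    return train(train_docs, TaggerConfig(epochs=12, seed=0))


@pytest.fixture(scope="session")
def attribute_bundle(registry, corpus_split) -> AttributeModelBundle:
    train_docs, _ = corpus_split
    return AttributeModelBundle(registry=registry, seed=0).fit(train_docs)
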