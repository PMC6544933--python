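# rxsig

Structured extraction and checking of free-text prescription directions
("sigs") — strings like *"take 2 tablets by mouth three times a day as
needed for pain"*. Pharmacy systems store such directions alongside
pharmacist-entered structured fields, but the text itself is opaque to
software. `rxsig` turns it into structured, normalized regimen data and
cross-checks the two representations.

The package is aimed at clinical NLP practitioners and pharmacy
informatics teams who need to

- **annotate** sigs with a 19-label concept schema (DISPENSE, MEDICATION,
  TAKE, STRENGTH, DOSEAMOUNT, DOSEFORM, DURATION, FREQ, TIMING, PRN,
  INDICATION, ROUTE, REFILL, SUB_STATUS, INSTRUCTION, and their unit
  labels), each label carrying typed attributes (numeric, choice,
  boolean, free text) that hold the normalized meaning of the span;
- **tag automatically** with a trainable linear-chain sequence model
  (BIO encoding, Viterbi decoding) whose decode-time bias trades
  precision against recall (+3 ≈ high precision, −3 ≈ high recall);
- **normalize attributes** with the method family that fits each
  attribute type: majority baseline, literal span memorization,
  edit-distance fallback for misspellings, maximum-entropy classifiers
  over bag-of-words/bigram features, and hybrid frequency/timing
  normalizers that classify the categorical attributes and read the
  numbers off a canonicalized span;
- **score** span/label precision, recall and F (also used as the
  pairwise inter-annotator agreement measure) and per-attribute accuracy
  on gold spans;
- **export** normalized regimens as FHIR-Dosage-shaped JSON
  (frequency/frequencyMax/period/periodMax/periodUnit, asNeeded, route,
  timing, …);
- **detect discrepancies** between the sig text and the structured
  record fields (Take, Frequency, Route, Duration, Dispense Quantity,
  PRN, Form).

## The core model

A sig is annotated with *tags*: a label, a character span, and an
attribute map. Frequency semantics distinguish counts from intervals:
"2-3 times per day" is `times_per = 2, to_times_per = 3, every = 1,
unit = day`, while "every 4-6 hours" is `every = 4, to_every = 6,
times_per = 1, unit = hour` — the distinction FHIR expresses as
frequency/frequencyMax versus period/periodMax.

Before attribute normalization, a numeric retokenizer canonicalizes
number expressions ("three" → 3, "one and a half" → 1.5, "2 1/2" → 2.5)
while keeping a bidirectional character-offset map so annotation spans
survive the rewrite.

Span tagging uses token features (character prefixes/suffixes up to
length 3, capitalization and digit flags, the current surface, and
surfaces up to three tokens away) feeding an averaged structured
perceptron with Viterbi decoding. Attribute classifiers are multinomial
logistic (maximum-entropy) models.

Because real sig corpora are rarely shareable, the package includes a
seeded synthetic generator that emits template-based sigs with gold
annotations, paired structured records, configurable per-label tag
frequencies, number-word/abbreviation/misspelling noise, and a logged
fraction of deliberately contradictory records for evaluating
discrepancy detection.

## Worked example

```python
from rxsig import (AttributeModelBundle, GeneratorConfig, SigDocument,
                   TaggerConfig, generate_corpus, load_schema, split_corpus,
                   score_spans, tag, to_fhir_dosage, train)

docs, records, _ = generate_corpus(GeneratorConfig(n_documents=1000, seed=17))
train_docs, test_docs = split_corpus(docs, 0.8, seed=17)
model = train(train_docs, TaggerConfig(epochs=12, seed=0))
bundle = AttributeModelBundle(registry=load_schema(), seed=0).fit(train_docs)

text = "take 2 tablets by mouth three times a day as needed for pain"
spans = tag(model, text, 0.0)
for t in spans:
    t.attributes = bundle.predict_tag(text, t)
    print(t.label, text[t.start:t.end], t.attributes)
```

prints

```
TAKE       2                  {'amount': 2, 'to_amount': None}
DOSEFORM   tablets            {'form': 'tablet'}
ROUTE      by mouth           {'route': 'oral', 'side': None}
FREQ       three times a day  {'unit': 'day', 'times_per': 3, 'to_times_per': None,
                               'every': 1, 'to_every': None}
PRN        as needed          {}
INDICATION pain               {}
```

i.e. two tablets per administration, by mouth, three times per day, as
needed, for pain. The FHIR view of the same document,
`to_fhir_dosage(SigDocument("demo", text, spans)).to_dict()`, is

```json
{"doseQuantity": 2, "doseUnit": "tablet", "frequency": 3, "period": 1,
 "periodUnit": "day", "asNeeded": true, "asNeededReason": "pain",
 "route": "oral"}
```

Scoring the tagger on the held-out synthetic test split:

```python
hyp = [SigDocument(d.doc_id, d.text, tag(model, d.text, 0.0)) for d in test_docs]
o = score_spans(test_docs, hyp).overall
print(f"P={o.precision:.3f} R={o.recall:.3f} F={o.f_measure:.3f}")
# P=0.999 R=0.999 F=0.999
```

(Synthetic, template-generated language is far easier than real sigs;
see `docs/methods.md` for what these numbers do and do not show.)

The same pipeline is available from the shell:

```bash
rxsig generate --n 1000 --seed 17 --out corpus.jsonl --records records.csv
rxsig train --in corpus.jsonl --out model.json --seed 0
rxsig tag --model model.json --in corpus.jsonl --out tagged.jsonl --bias 0
rxsig normalize --train corpus.jsonl --in tagged.jsonl --out normalized.jsonl
rxsig eval --ref corpus.jsonl --hyp tagged.jsonl --report report.json
rxsig check --records records.csv --annotations normalized.jsonl --out findings.json
rxsig export-fhir --in normalized.jsonl --out dosages.jsonl
```

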