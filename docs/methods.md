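# Methods

This note documents the models and procedures implemented in `rxsig`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## Annotation model

A sig document is a text plus standoff tags. A tag is a label (one of
19 regimen concept categories), a character span (0-based, half-open,
Unicode code points), and an attribute map. Attributes are typed:

- **numeric** — non-negative rationals, stored losslessly (so "one and a
  half" normalizes to exactly 1.5). Paired `X`/`to_X` attributes express
  ranges ("2-3 tablets" → `amount=2, to_amount=3`).
- **choice** — values from fixed lists. Time units share one list
  (minute, hour, day, week, month, other). The lists for dose forms,
  routes, and the three measurement-unit labels are deployment
  conventions rather than linguistic facts, so they ship as curated
  defaults that a schema config file can replace wholesale.
- **boolean** — refill and substitution permissions.
- **free text** — medication names and catch-all instruction notes.

Every attribute is nullable; null means "not stated in the text".
Unstated is distinct from any stated value, and scoring excludes
gold-null attributes from accuracy denominators.

The frequency model separates **counts** from **intervals**: `times_per`
(with `to_times_per`) counts administrations per unit; `every` (with
`to_every`) spaces administrations by a number of units. "Three times
per day" and "every three days" therefore receive different attribute
maps even though both mention 3 and days. This two-sided structure maps
one-to-one onto FHIR's frequency/frequencyMax and period/periodMax.

Two labels may in principle cover the same characters (a token serving
as both DOSEAMOUNT and STRENGTH); the validator treats same-label
overlap as a warning, not an error, since the schema itself does not
forbid it.

## Numeric retokenizer

Number expressions are detected left-to-right with longest-match
priority: digit literals and decimals, literal fractions ("1/2", mixed
"2 1/2"), additive/multiplicative English number words up to the
hundreds ("twenty one", "one hundred and five"), the words half and
quarter, and the "X and a half" idiom. Digit ranges ("2-3") yield two
separate spans — the hyphen belongs to neither number, and downstream
range rules want the endpoints individually.

Canonical rendering is base-10 with no trailing zeros and at most three
decimal places. Canonicalization is idempotent, and a segment-based
offset map relates original and rewritten positions (bijective outside
replaced segments, monotone and clamped inside them), so a span mapped
through the rewrite and back always contains the original span.

Ordinal words ("every third day") are detected with their numeric value
— interval frequencies need the 3 — but are *not* rewritten, since "every
3 day" is not a faithful rendering of the phrase. Fraction glyphs (½)
are not handled.

## Span tagger

Tokenization splits on whitespace and separates every punctuation
character (so "2-3" → `2`, `-`, `3` and "p.o." → `p`, `.`, `o`, `.`),
keeping decimal literals whole. Abbreviation identity is left to the
feature set rather than the tokenizer.

Per-token features: character prefixes and suffixes of lengths 1–3;
capitalization flags for the current and previous token; a
contains-digit flag; the current surface form; and the surface forms at
relative offsets ±1, ±2, ±3 with boundary placeholders.

Spans are encoded per token with BIO over the 19 labels. Gold spans not
aligned to token boundaries are snapped outward to whole tokens with a
logged warning. The sequence model is an averaged structured perceptron
— a discriminatively trained linear-chain model with emission weights
over the features above plus label-transition weights — decoded with
Viterbi. Training runs 12 epochs over seeded-shuffled documents and is
fully deterministic given corpus order and seed; unseen features at
decode time are ignored. The label inventory is {O} ∪ {B-L, I-L} for
every label present in training data.

### Precision/recall bias

A signed decode-time bias trades precision against recall, with the
convention that +3 is a strongly precision-biased run and −3 a strongly
recall-biased one. Two earlier formulations were implemented and
rejected because they fail under exact-span scoring: subtracting the
penalty from every non-O emission fragments multi-token spans (hurting
precision at positive bias and recall at negative bias), and penalizing
span-opening transitions merges adjacent spans at positive bias. The
shipped mechanism edits the unbiased Viterbi path at span granularity:

- **positive bias** prunes every decoded span whose score margin over an
  all-O replacement is below `scale × bias`. Weakest spans drop first;
  surviving spans are untouched. In the limit no tags remain.
- **negative bias** additionally opens a single-token span at every O
  position whose cheapest flip to a span-opening label costs at most
  `scale × |bias|`. Decoded spans are untouched, so exact-span recall
  can only rise. In the limit every token is tagged.

Both directions are monotone in the bias, so the predicted tag count is
non-increasing across the grid {−3, 0, +3}.

Perceptron scores have arbitrary magnitude, so a fixed scale would make
the conventional ±3 settings meaningless for some models and extreme
for others. The scale is therefore calibrated at the end of training to
one third of the median per-token decision margin (top score minus
runner-up) on the training data: ±3 then shifts decisions by one full
typical margin. The calibrated value is stored in the model file and
can be overridden via `TaggerConfig.bias_scale`.

## Attribute normalization

- **Baseline** — the most common training value; for FREQ, the majority
  unit with the defaults `times_per = 1, every = 1` and null ranges.
- **Literal match** — memorize span→value mappings (case-folded,
  whitespace-collapsed) and return the most common match; on a miss,
  accept an exact match against the allowed-value list. The paper-style
  method is partial on a double miss; this implementation falls back to
  the training majority so the method is total.
- **Edit-distance fallback** — like literal match, but a miss selects
  the allowed value with the smallest Levenshtein distance to the span
  (computed by edlib), with ties broken by higher training frequency and
  then lexicographically. This is the intended remedy for single-edit
  misspellings ("tablts").
- **Classifier** — multinomial logistic regression (lbfgs, C = 1.0,
  ≤200 iterations, fixed seed) over bag-of-words and bigram features of
  the span plus up to three flanking tokens per side; frequency/timing
  spans add the count of number expressions. Single-class training data
  degenerates to a constant predictor. A reserved class stands for null.

FREQ's **hybrid** method uses two classifiers — one for the unit, one
deciding interval-versus-count — and maps numbers from the retokenized
span left-to-right: a count phrase fills `times_per` (and
`to_times_per`) with `every = 1`, an interval phrase fills `every` (and
`to_every`) with `times_per = 1`. The left-to-right assignment is a
design choice; sig frequency phrases put the count/interval number
first. Spans without digits resolve through an idiom lexicon
(once/twice/thrice, daily, qd/bid/tid/qid, "every other day"), 1 if no
idiom applies. Training labels for the interval/count classifier derive
from gold attributes (`every ≠ 1` or a non-null `to_every`, else an
"every"-idiom surface check). The **classifier** variant adds one
classifier per numeric attribute whose output is snapped to the valid
set {1…12, 15, 30, 45, 60} (nearest member, ties to the smaller).

TIMING is analogous: classifiers for direction, event and offset_unit
(with a null class — "at bedtime" legitimately has no direction);
hybrid mode reads `offset`/`to_offset` as the first/second numbers in
the span.

Numeric-only labels (DISPENSE, DOSEAMOUNT, STRENGTH, TAKE, DURATION)
use direct mapping: *unnormalized* stores the verbatim surface,
*normalized* reads canonical decimals off the retokenized span with
ranges filling the value pair; a normalized span without a number yields
null with a warning.

## Scoring

Span scoring uses exact (start, end, label) matching, greedily one-to-one
within a document, micro-averaged overall. Exact matching is stricter
than overlap-based alternatives and reproducible; the criterion type is
extensible. When a hypothesis asserts nothing, precision is reported as
1.0 (no false assertions) with recall 0 — so a never-predicted label
shows the characteristic P = 1.000 / R = 0.000 / F = 0.000 row.
Pairwise inter-annotator agreement is the same F-measure with one
annotator as reference; overall F is symmetric under swapping the
annotators because precision and recall exchange. Attributes are
excluded from agreement; attribute accuracy is computed only on gold
spans, so span errors never compound with attribute errors.

Corpus splitting shuffles deterministically by seed with
`|train| = round(ratio · N)`.

## Synthetic corpus generator

The generator emulates short prescription-direction strings: ~40
templates composed of literal text and slots (take-amount, dose form,
frequency, route, timing, duration, PRN+indication, medication,
strength, dispense, refill, substitution, instruction clauses). Every
label occurs in at least one template, including the rare ones.

Gold attributes are fixed before surface rendering, so a slot rendered
as "three" still carries the gold value 3. Noise knobs control
number-word probability (0.3), clinical-abbreviation probability (0.3:
TID, b.i.d., p.o., prn), and single-character misspellings of
choice-attribute surfaces (0.05, never applied to numbers) — the exact
failure mode the edit-distance fallback targets.

Per-label tag frequencies follow a configurable relative-weight profile
whose default mirrors a realistic annotated-sig corpus (instruction
clauses dominate; frequency and timing expressions are the most common
regimen concepts; strength and dispense tags are rare). Template
sampling probabilities are fit to the profile by non-negative least
squares over the templates' label-count vectors, which reproduces the
profile within a few percent in expectation.

Each document is paired with a structured record whose fields are
filled from the gold attributes (frequency as a code such as TID or
Q6H when one fits, otherwise a canonical phrase). With
`discrepancy_rate > 0`, that fraction of records has one comparable
non-empty field perturbed to a semantically different value, and the
perturbation is logged as ground truth. `generate_corpus` returns
(documents, records, perturbations).

What the generator does **not** model: real drug-name distributions
(medication surfaces come from a short generic-name list), free-form
grammar and typos outside the slot inventory, multi-regimen sigs
("then taper…"), dates, and annotator disagreement. Consequently the
near-ceiling tagger F (≈0.999) and attribute accuracies (0.95–1.0) on
synthetic splits demonstrate pipeline correctness — that the models can
recover what the templates encode, with the expected method ordering
(classifier ≥ baseline, edit-distance fallback > literal on misspelled
surfaces) — not expected performance on real prescription text, where
span F in the 0.7–0.9 range per label is typical.

## Discrepancy detection

Field comparisons are exact after normalization: numeric fields compare
as canonical decimals (prescription quantities are discrete — no
tolerance); unit and form surfaces fold through alias tables
(tab/tabs/Tablet(s) → tablet); route codes fold the common shorthands
(PO, SL, PR…); the structured Frequency field is parsed through the
idiom lexicon and the deterministic frequency-phrase rules into an
attribute map before comparison. Values present on only one side yield
`missing_in_text` / `missing_in_structured` findings, distinct from
`mismatch`; every finding cites the contributing tag spans. On
synthetic pairs the mismatch-flagged record set equals the generator's
perturbation log exactly at the default noise levels.

## Problem sizes and determinism

The test suite and the acceptance script use 1000-document corpora with
an 80/20 split (profile-fidelity checks use 2000), sizes at which every
label has trainable support and all fits complete in seconds. All
randomness — generation, splitting, perceptron shuffling, classifier
initialization — flows from explicit integer seeds, and every model
artifact serializes to JSON text.
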