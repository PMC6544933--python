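"""Attribute normalization: from tagged spans to normalized values.

Four families of methods, chosen per attribute type:

* **baseline** — always predict the most common training value.
* **literal** — memorize span→value mappings from training; on a miss,
  accept an exact match against the allowed-value list; on a double miss,
  fall back to the training majority (so the method is total).
* **levenshtein** — like literal, but the fallback picks the allowed
  value with the smallest edit distance to the span instead of requiring
  an exact match.
* **classifier** — a multinomial maximum-entropy (logistic-regression)
  model over bag-of-words and bigram features of the span (plus up to
  three flanking tokens per side, and the count of number expressions
  for frequency/timing spans).

FREQ and TIMING get composite normalizers: a *hybrid* mode that uses
classifiers for the categorical attributes and reads the numeric
attributes directly off the retokenized span (first number, second
number for ranges), and a *classifier* mode that additionally predicts
each numeric attribute with a classifier whose output is snapped to the
valid-value set {1..12, 15, 30, 45, 60}.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import edlib
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .lexicon import COUNT_WORDS
from .numbers import canonicalize, find_number_expressions
from .tagger import tokenize

__all__ = [
    "VALID_NUMERIC_VALUES",
    "snap_valid",
    "edit_distance",
    "SpanContext",
    "build_context",
    "BaselinePredictor",
    "LiteralPredictor",
    "ClassifierPredictor",
    "FreqNormalizer",
    "TimingNormalizer",
    "map_numeric",
    "normalize_document",
    "AttributeModelBundle",
]

logger = logging.getLogger(__name__)

#: Valid snapped values for classifier-predicted numeric attributes.
VALID_NUMERIC_VALUES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 15, 30, 45, 60)

Numeric = Union[int, float, Fraction]


def snap_valid(value: Numeric) -> int:
    """Snap to the nearest valid numeric value (ties go to the smaller)."""
    value = Fraction(str(value)) if isinstance(value, float) else Fraction(value)
    best = min(VALID_NUMERIC_VALUES, key=lambda w: (abs(Fraction(w) - value), w))
    return best


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class SpanContext:
    """A tagged span, retokenized, with its immediate context.

    ``text`` is the normalized (canonical-number) span text; ``tokens``
    are its tokens; ``left``/``right`` hold up to three flanking tokens
    per side; ``num_count`` is the number of number expressions inside
    the span.
    """

    text: str
    tokens: tuple[str, ...]
    left: tuple[str, ...] = ()
    right: tuple[str, ...] = ()
    num_count: int = 0

    @property
    def numbers(self):
        return find_number_expressions(self.text)


def build_context(doc_text: str, start: int, end: int) -> SpanContext:
    """Build a SpanContext for span [start, end) of a sig.

    The whole sig is canonicalized first so that span text and context
    tokens carry canonical numbers; the span is mapped through the
    offset map.
    """
    norm = canonicalize(doc_text)
    n_start, n_end = norm.offset_map.span_to_normalized(start, end)
    span_text = norm.text[n_start:n_end]
    all_tokens = tokenize(norm.text)
    inside = [t.surface for t in all_tokens if t.start >= n_start and t.end <= n_end]
    left = [t.surface for t in all_tokens if t.end <= n_start][-3:]
    right = [t.surface for t in all_tokens if t.start >= n_end][:3]
    return SpanContext(
        text=span_text,
        tokens=tuple(inside),
        left=tuple(left),
        right=tuple(right),
        num_count=len(find_number_expressions(span_text)),
    )


def _norm_key(text: str) -> str:
    return " ".join(text.lower().split())


def _most_common(counter: Counter) -> str:
    """Highest count, ties broken lexicographically."""
    return min(counter, key=lambda v: (-counter[v], v))


class BaselinePredictor:
    """Predict the most common training value, always."""

    def __init__(self) -> None:
        self.value: Optional[str] = None
        self.counts: Counter = Counter()

    def fit(self, values: Sequence[Optional[str]]) -> "BaselinePredictor":
        self.counts = Counter(v for v in values if v is not None)
        if not self.counts:
            raise ValueError("no non-null training values")
        self.value = _most_common(self.counts)
        return self

    def predict(self, context: SpanContext) -> str:
        if self.value is None:
            raise ValueError("predictor not fitted")
        return self.value


class LiteralPredictor:
    """Span-table lookup with exact-match or edit-distance fallback.

    With ``levenshtein=False`` the fallback accepts only exact matches
    against the allowed-value list; with ``levenshtein=True`` it picks
    the allowed value minimizing edit distance to the span (ties broken
    by higher training frequency, then lexicographically).  A double
    miss returns the training-majority value.
    """

    def __init__(self, allowed_values: Sequence[str],
                 levenshtein: bool = False) -> None:
        self.allowed_values = tuple(allowed_values)
        self.levenshtein = levenshtein
        self.table: dict[str, Counter] = {}
        self.counts: Counter = Counter()
        self.majority: Optional[str] = None

    def fit(self, spans: Sequence[str],
            values: Sequence[Optional[str]]) -> "LiteralPredictor":
        for span, value in zip(spans, values):
            if value is None:
                continue
            self.table.setdefault(_norm_key(span), Counter())[value] += 1
            self.counts[value] += 1
        if not self.counts:
            raise ValueError("no non-null training values")
        self.majority = _most_common(self.counts)
        return self

    def predict(self, context: Union[SpanContext, str]) -> str:
        span = context.text if isinstance(context, SpanContext) else context
        key = _norm_key(span)
        hit = self.table.get(key)
        if hit:
            return _most_common(hit)
        if self.levenshtein:
            return min(
                self.allowed_values,
                key=lambda v: (edit_distance(key, v), -self.counts[v], v))
        if key in self.allowed_values:
            return key
        return self.majority  # type: ignore[return-value]


def _context_features(context: SpanContext,
                      with_num_count: bool = False) -> dict[str, float]:
    feats: dict[str, float] = {}
    toks = [t.lower() for t in context.tokens]
    for t in toks:
        feats[f"bow={t}"] = 1.0
    for a, b in zip(toks, toks[1:]):
        feats[f"bg={a}_{b}"] = 1.0
    for t in context.left:
        feats[f"lctx={t.lower()}"] = 1.0
    for t in context.right:
        feats[f"rctx={t.lower()}"] = 1.0
    if with_num_count:
        feats["num_count"] = float(context.num_count)
    return feats


class ClassifierPredictor:
    """Maximum-entropy classifier over bag-of-words/bigram span features."""

    def __init__(self, with_num_count: bool = False, seed: int = 0,
                 C: float = 1.0, max_iter: int = 200) -> None:
        self.with_num_count = with_num_count
        self.seed = seed
        self.C = C
        self.max_iter = max_iter
        self.model: Optional[LogisticRegression] = None
        self.vectorizer: Optional[DictVectorizer] = None
        self.constant: Optional[str] = None

    def fit(self, contexts: Sequence[SpanContext],
            values: Sequence[Optional[str]]) -> "ClassifierPredictor":
        pairs = [(c, v) for c, v in zip(contexts, values) if v is not None]
        if not pairs:
            raise ValueError("no non-null training values")
        classes = {v for _, v in pairs}
        if len(classes) < 2:
            # degenerate single-class training: constant predictor
            self.constant = next(iter(classes))
            return self
        X_dicts = [_context_features(c, self.with_num_count) for c, _ in pairs]
        y = [v for _, v in pairs]
        self.vectorizer = DictVectorizer(sparse=True)
        X = self.vectorizer.fit_transform(X_dicts)
        self.model = LogisticRegression(
            C=self.C, max_iter=self.max_iter, solver="lbfgs",
            random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model.fit(X, y)
        return self

    def predict(self, context: SpanContext) -> str:
        if self.constant is not None:
            return self.constant
        if self.model is None or self.vectorizer is None:
            raise ValueError("predictor not fitted")
        X = self.vectorizer.transform(
            [_context_features(context, self.with_num_count)])
        return str(self.model.predict(X)[0])


_NULL = "∅"  # class token standing for a null attribute value


def _to_number(value) -> Optional[Numeric]:
    if value is None:
        return None
    if isinstance(value, (int, float, Fraction)):
        return value
    frac = Fraction(str(value))
    return int(frac) if frac.denominator == 1 else float(frac)


def _span_numbers(context: SpanContext) -> list[Numeric]:
    out = []
    for sp in context.numbers:
        v = sp.value
        out.append(int(v) if v.denominator == 1 else float(v))
    return out


class FreqNormalizer:
    """Normalize FREQ spans to the five-attribute frequency map.

    A count phrase ("2-3 times per day") fills ``times_per`` (and
    ``to_times_per`` for ranges) with ``every = 1``; an interval phrase
    ("every 4-6 hours") fills ``every``/``to_every`` with ``times_per = 1``.
    In *hybrid* mode two classifiers decide the unit and the
    interval-vs-count question and the numbers are read left-to-right
    from the retokenized span; spans with no number expression resolve
    through the idiom lexicon (once/twice/..., defaulting to 1).
    *Classifier* mode adds per-numeric-attribute classifiers snapped to
    the valid-value set.  *Baseline* mode predicts the majority unit with
    the default numbers ``times_per = 1, every = 1``.
    """

    NUMERIC_ATTRS = ("times_per", "to_times_per", "every", "to_every")

    def __init__(self, seed: int = 0) -> None:
        self.seed = seed
        self.unit_clf = ClassifierPredictor(with_num_count=True, seed=seed)
        self.type_clf = ClassifierPredictor(with_num_count=True, seed=seed)
        self.numeric_clfs: dict[str, ClassifierPredictor] = {}
        self.unit_baseline: Optional[str] = None

    @staticmethod
    def _phrase_type(attrs: dict, context: SpanContext) -> str:
        """Derive the interval/count training label from gold attributes."""
        every = _to_number(attrs.get("every"))
        if (every is not None and every != 1) or attrs.get("to_every") is not None:
            return "interval"
        tp = _to_number(attrs.get("times_per"))
        words = {t.lower() for t in context.tokens}
        if tp in (None, 1) and ("every" in words or "q" in words):
            return "interval"
        return "count"

    def fit(self, contexts: Sequence[SpanContext],
            gold_attrs: Sequence[dict]) -> "FreqNormalizer":
        units = [a.get("unit") for a in gold_attrs]
        self.unit_clf.fit(contexts, units)
        unit_counts = Counter(u for u in units if u is not None)
        self.unit_baseline = _most_common(unit_counts) if unit_counts else "day"
        types = [self._phrase_type(a, c) for a, c in zip(gold_attrs, contexts)]
        self.type_clf.fit(contexts, types)
        for attr in self.NUMERIC_ATTRS:
            clf = ClassifierPredictor(with_num_count=True, seed=self.seed)
            values = [
                _NULL if a.get(attr) is None else str(_to_number(a.get(attr)))
                for a in gold_attrs
            ]
            clf.fit(contexts, values)
            self.numeric_clfs[attr] = clf
        return self

    def _implied_count(self, context: SpanContext) -> Numeric:
        for t in context.tokens:
            if t.lower() in COUNT_WORDS:
                return COUNT_WORDS[t.lower()]
        return 1

    def normalize(self, context: SpanContext, method: str = "hybrid") -> dict:
        if method == "baseline":
            return {"times_per": 1, "to_times_per": None, "every": 1,
                    "to_every": None, "unit": self.unit_baseline}
        if method not in ("hybrid", "classifier"):
            raise ValueError(f"unknown method {method!r}")
        unit = self.unit_clf.predict(context)
        ptype = self.type_clf.predict(context)
        attrs: dict = {"unit": unit}
        if method == "classifier":
            for name in self.NUMERIC_ATTRS:
                raw = self.numeric_clfs[name].predict(context)
                attrs[name] = None if raw == _NULL else snap_valid(
                    Fraction(raw))
            # keep the count/interval defaults coherent
            if attrs.get("times_per") is None:
                attrs["times_per"] = 1
            if attrs.get("every") is None:
                attrs["every"] = 1
            return attrs
        nums = _span_numbers(context)
        n1 = nums[0] if nums else self._implied_count(context)
        n2 = nums[1] if len(nums) > 1 else None
        if ptype == "interval":
            attrs.update(times_per=1, to_times_per=None, every=n1, to_every=n2)
        else:
            attrs.update(times_per=n1, to_times_per=n2, every=1, to_every=None)
        return attrs


class TimingNormalizer:
    """Normalize TIMING spans (direction, event, offset, offset_unit).

    Classifiers predict ``direction``, ``event`` and ``offset_unit`` (a
    null class covers unstated values); in *hybrid* mode ``offset`` and
    ``to_offset`` are the first and second numbers of the retokenized
    span (null when absent), while *classifier* mode predicts them too,
    snapped to the valid-value set.
    """

    CHOICE_ATTRS = ("direction", "event", "offset_unit")
    NUMERIC_ATTRS = ("offset", "to_offset")

    def __init__(self, seed: int = 0) -> None:
        self.seed = seed
        self.choice_clfs: dict[str, ClassifierPredictor] = {}
        self.numeric_clfs: dict[str, ClassifierPredictor] = {}
        self.baselines: dict[str, Optional[str]] = {}

    def fit(self, contexts: Sequence[SpanContext],
            gold_attrs: Sequence[dict]) -> "TimingNormalizer":
        for attr in self.CHOICE_ATTRS:
            values = [a.get(attr) if a.get(attr) is not None else _NULL
                      for a in gold_attrs]
            clf = ClassifierPredictor(with_num_count=True, seed=self.seed)
            clf.fit(contexts, values)
            self.choice_clfs[attr] = clf
            counts = Counter(v for v in values)
            self.baselines[attr] = _most_common(counts)
        for attr in self.NUMERIC_ATTRS:
            values = [
                _NULL if a.get(attr) is None else str(_to_number(a.get(attr)))
                for a in gold_attrs
            ]
            clf = ClassifierPredictor(with_num_count=True, seed=self.seed)
            clf.fit(contexts, values)
            self.numeric_clfs[attr] = clf
            counts = Counter(values)
            self.baselines[attr] = _most_common(counts)
        return self

    def normalize(self, context: SpanContext, method: str = "hybrid") -> dict:
        def _denull(v):
            return None if v == _NULL else v

        if method == "baseline":
            attrs = {a: _denull(self.baselines.get(a)) for a in self.CHOICE_ATTRS}
            for a in self.NUMERIC_ATTRS:
                raw = _denull(self.baselines.get(a))
                attrs[a] = None if raw is None else _to_number(raw)
            return attrs
        if method not in ("hybrid", "classifier"):
            raise ValueError(f"unknown method {method!r}")
        attrs = {a: _denull(self.choice_clfs[a].predict(context))
                 for a in self.CHOICE_ATTRS}
        if method == "classifier":
            for a in self.NUMERIC_ATTRS:
                raw = self.numeric_clfs[a].predict(context)
                attrs[a] = None if raw == _NULL else snap_valid(Fraction(raw))
        else:
            nums = _span_numbers(context)
            attrs["offset"] = nums[0] if nums else None
            attrs["to_offset"] = nums[1] if len(nums) > 1 else None
        return attrs


def map_numeric(span_text: str, mode: str = "normalized",
                names: tuple[str, str] = ("amount", "to_amount")) -> dict:
    """Map a numeric-attribute span ("three", "2-3") to attribute values.

    ``unnormalized`` stores the verbatim surface string; ``normalized``
    reads canonical decimals off the retokenized span, filling the
    (value, to_value) pair for ranges.  A normalized span with no number
    expression yields null with a logged warning.
    """
    lo_name, hi_name = names
    if mode == "unnormalized":
        return {lo_name: span_text, hi_name: None}
    if mode != "normalized":
        raise ValueError(f"unknown mode {mode!r}")
    nums = find_number_expressions(span_text)
    if not nums:
        logger.warning("no number expression in numeric span %r", span_text)
        return {lo_name: None, hi_name: None}
    values = [int(sp.value) if sp.value.denominator == 1 else float(sp.value)
              for sp in nums]
    return {lo_name: values[0],
            hi_name: values[1] if len(values) > 1 else None}


# ---------------------------------------------------------------------------
# Whole-document normalization

#: numeric tags → their attribute-name pair
_NUMERIC_TAGS = {
    "DISPENSE": ("quantity", "to_quantity"),
    "DOSEAMOUNT": ("amount", "to_amount"),
    "STRENGTH": ("amount", "to_amount"),
    "TAKE": ("amount", "to_amount"),
    "DURATION": ("num", "to_num"),
}

#: choice tags → attribute name
_CHOICE_TAGS = {
    "DISPENSE_UNIT": "unit",
    "DOSEAMOUNT_UNIT": "unit",
    "STRENGTH_UNIT": "unit",
    "DURATION_UNIT": "unit",
    "DOSEFORM": "form",
    "ROUTE": "route",
}

_BOOLEAN_TAGS = {"REFILL": "refill", "SUB_STATUS": "subst"}


@dataclass
class AttributeModelBundle:
    """Trained attribute predictors for a whole schema, one per target.

    ``choice_method`` selects among baseline/literal/levenshtein/classifier
    for choice attributes; FREQ and TIMING use their composite normalizers.
    """

    registry: "object"
    seed: int = 0
    choice: dict[str, dict[str, object]] = field(default_factory=dict)
    booleans: dict[str, ClassifierPredictor] = field(default_factory=dict)
    boolean_baselines: dict[str, BaselinePredictor] = field(default_factory=dict)
    freq: Optional[FreqNormalizer] = None
    timing: Optional[TimingNormalizer] = None

    def fit(self, corpus: Sequence["object"]) -> "AttributeModelBundle":
        """Train every predictor from gold-annotated documents."""
        from .io import SigDocument  # local import to avoid a cycle

        by_label: dict[str, list[tuple[SpanContext, dict, str]]] = {}
        for doc in corpus:
            for t in doc.tags:
                ctx = build_context(doc.text, t.start, t.end)
                by_label.setdefault(t.label, []).append(
                    (ctx, t.attributes, doc.text[t.start:t.end]))

        for label, attr in _CHOICE_TAGS.items():
            rows = by_label.get(label, [])
            values = [r[1].get(attr) for r in rows]
            if not any(v is not None for v in values):
                continue
            spans = [r[0].text for r in rows]
            contexts = [r[0] for r in rows]
            allowed = self.registry[label].attribute(attr).allowed_values
            entry: dict[str, object] = {}
            entry["baseline"] = BaselinePredictor().fit(values)
            entry["literal"] = LiteralPredictor(allowed).fit(spans, values)
            entry["levenshtein"] = LiteralPredictor(
                allowed, levenshtein=True).fit(spans, values)
            entry["classifier"] = ClassifierPredictor(seed=self.seed).fit(
                contexts, values)
            self.choice[label] = entry

        for label, attr in _BOOLEAN_TAGS.items():
            rows = by_label.get(label, [])
            values = ["true" if r[1].get(attr) else "false"
                      for r in rows if r[1].get(attr) is not None]
            if not values:
                continue
            contexts = [r[0] for r in rows if r[1].get(attr) is not None]
            self.booleans[label] = ClassifierPredictor(seed=self.seed).fit(
                contexts, values)
            self.boolean_baselines[label] = BaselinePredictor().fit(values)

        freq_rows = by_label.get("FREQ", [])
        if freq_rows:
            self.freq = FreqNormalizer(seed=self.seed).fit(
                [r[0] for r in freq_rows], [r[1] for r in freq_rows])
        timing_rows = by_label.get("TIMING", [])
        if timing_rows:
            self.timing = TimingNormalizer(seed=self.seed).fit(
                [r[0] for r in timing_rows], [r[1] for r in timing_rows])
        return self

    def predict_tag(self, doc_text: str, tag, choice_method: str = "levenshtein",
                    freq_method: str = "hybrid",
                    numeric_mode: str = "normalized",
                    boolean_method: str = "classifier") -> dict:
        """Predicted attribute map for one tagged span."""
        label = tag.label
        span_text = doc_text[tag.start:tag.end]
        if label in _NUMERIC_TAGS:
            ctx = build_context(doc_text, tag.start, tag.end)
            return map_numeric(ctx.text, numeric_mode, _NUMERIC_TAGS[label])
        if label in _CHOICE_TAGS and label in self.choice:
            attr = _CHOICE_TAGS[label]
            ctx = build_context(doc_text, tag.start, tag.end)
            predictor = self.choice[label][choice_method]
            value = predictor.predict(ctx)  # type: ignore[union-attr]
            out = {attr: value}
            if label == "ROUTE":
                out["side"] = None
            return out
        if label in _BOOLEAN_TAGS:
            attr = _BOOLEAN_TAGS[label]
            ctx = build_context(doc_text, tag.start, tag.end)
            if boolean_method == "baseline" and label in self.boolean_baselines:
                return {attr: self.boolean_baselines[label].predict(ctx) == "true"}
            if label in self.booleans:
                return {attr: self.booleans[label].predict(ctx) == "true"}
            return {}
        if label == "FREQ" and self.freq is not None:
            ctx = build_context(doc_text, tag.start, tag.end)
            return self.freq.normalize(ctx, freq_method)
        if label == "TIMING" and self.timing is not None:
            ctx = build_context(doc_text, tag.start, tag.end)
            return self.timing.normalize(ctx, freq_method)
        if label == "MEDICATION":
            return {"name": span_text}
        if label == "INSTRUCTION":
            return {"note": span_text}
        return {}


def normalize_document(doc, bundle: AttributeModelBundle,
                       **methods) -> None:
    """Fill the attribute maps of every tag of ``doc`` in place."""
    for tag in doc.tags:
        tag.attributes = bundle.predict_tag(doc.text, tag, **methods)
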