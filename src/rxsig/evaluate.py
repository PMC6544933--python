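"""Scoring: span/label precision-recall-F, agreement, attribute accuracy.

Span scoring uses exact (start, end, label) matching with greedy
one-to-one pairing, micro-averaged across documents.  The same machinery
scores inter-annotator agreement: the F-measure between two annotators'
tag sets is symmetric under swapping the annotators, because precision
and recall simply exchange.  When a hypothesis set is empty, precision is
reported as 1.0 (no false positives were asserted) with recall 0.

Attribute accuracy is computed on gold spans only — predictions are made
for manually identified spans, so span errors cannot compound with
attribute errors — and gold-null values are excluded from denominators.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .io import SigDocument

__all__ = [
    "LabelCounts",
    "PRFReport",
    "AccuracyReport",
    "score_spans",
    "pairwise_agreement",
    "attribute_accuracy",
    "split_corpus",
]


@dataclass
class LabelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        # no hypothesis tags → nothing asserted falsely → P = 1.0
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class PRFReport:
    per_label: dict[str, LabelCounts] = field(default_factory=dict)

    @property
    def overall(self) -> LabelCounts:
        total = LabelCounts()
        for c in self.per_label.values():
            total.tp += c.tp
            total.fp += c.fp
            total.fn += c.fn
        return total

    def to_dict(self) -> dict:
        def row(c: LabelCounts) -> dict:
            return {"precision": c.precision, "recall": c.recall,
                    "f": c.f_measure, "tp": c.tp, "fp": c.fp, "fn": c.fn}
        out = {label: row(c) for label, c in sorted(self.per_label.items())}
        out["OVERALL"] = row(self.overall)
        return out


def score_spans(reference: Sequence[SigDocument],
                hypothesis: Sequence[SigDocument]) -> PRFReport:
    """Micro-averaged exact span+label P/R/F between two corpora.

    Both collections must cover the same doc_ids; matching is one-to-one
    within a document (duplicate identical spans match at most once).
    """
    ref_by_id = {d.doc_id: d for d in reference}
    hyp_by_id = {d.doc_id: d for d in hypothesis}
    if set(ref_by_id) != set(hyp_by_id):
        missing = set(ref_by_id) ^ set(hyp_by_id)
        raise ValueError(f"doc_id mismatch between collections: {sorted(missing)[:5]}")
    report = PRFReport()

    def counts(label: str) -> LabelCounts:
        return report.per_label.setdefault(label, LabelCounts())

    for doc_id, ref_doc in ref_by_id.items():
        hyp_doc = hyp_by_id[doc_id]
        ref_keys = [(t.start, t.end, t.label) for t in ref_doc.tags]
        hyp_keys = [(t.start, t.end, t.label) for t in hyp_doc.tags]
        unmatched = list(ref_keys)
        for key in hyp_keys:
            if key in unmatched:
                unmatched.remove(key)
                counts(key[2]).tp += 1
            else:
                counts(key[2]).fp += 1
        for key in unmatched:
            counts(key[2]).fn += 1
    return report


def pairwise_agreement(annotations_a: Sequence[SigDocument],
                       annotations_b: Sequence[SigDocument]) -> PRFReport:
    """Agreement between two annotators as span/label F-measure.

    Annotator A is treated as reference and B as hypothesis; the overall
    F is invariant under swapping the arguments.
    """
    return score_spans(annotations_a, annotations_b)


@dataclass
class AccuracyReport:
    # (label, attribute) → (correct, total)
    cells: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def accuracy(self, label: str, attribute: str) -> Optional[float]:
        cell = self.cells.get((label, attribute))
        if cell is None or cell[1] == 0:
            return None
        return cell[0] / cell[1]

    def to_dict(self) -> dict:
        return {
            f"{label}.{attr}": {"accuracy": c / t, "n": t}
            for (label, attr), (c, t) in sorted(self.cells.items()) if t
        }


def _values_equal(gold, pred) -> bool:
    def as_frac(v):
        try:
            if isinstance(v, bool):
                return None
            return Fraction(str(v))
        except (ValueError, ZeroDivisionError):
            return None

    g, p = as_frac(gold), as_frac(pred)
    if g is not None and p is not None:
        return g == p
    return gold == pred


def attribute_accuracy(gold: Sequence[SigDocument],
                       predicted: Mapping[str, Sequence]) -> AccuracyReport:
    """Per-(label, attribute) accuracy of predictions on gold spans.

    ``predicted`` maps doc_id to tags whose spans must all exist in the
    gold document (same start, end, label); a prediction on an unknown
    span is an error.  Gold-null values are excluded from denominators.
    """
    report = AccuracyReport()
    gold_by_id = {d.doc_id: d for d in gold}
    for doc_id, pred_tags in predicted.items():
        if doc_id not in gold_by_id:
            raise ValueError(f"predictions for unknown document {doc_id!r}")
        gold_doc = gold_by_id[doc_id]
        gold_index = {(t.start, t.end, t.label): t for t in gold_doc.tags}
        for pt in pred_tags:
            key = (pt.start, pt.end, pt.label)
            if key not in gold_index:
                raise ValueError(
                    f"prediction on span {key} absent from gold document {doc_id!r}")
            gt = gold_index[key]
            for attr, gold_value in gt.attributes.items():
                if gold_value is None:
                    continue
                correct, total = report.cells.get((pt.label, attr), (0, 0))
                ok = _values_equal(gold_value, pt.attributes.get(attr))
                report.cells[(pt.label, attr)] = (correct + int(ok), total + 1)
    return report


def split_corpus(corpus: Sequence[SigDocument], ratio: float,
                 seed: int) -> tuple[list[SigDocument], list[SigDocument]]:
    """Deterministic shuffled train/test split; |train| = round(ratio·N)."""
    if not corpus:
        raise ValueError("empty corpus")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    order = list(range(len(corpus)))
    random.Random(seed).shuffle(order)
    n_train = round(ratio * len(corpus))
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return ([corpus[i] for i in train_idx], [corpus[i] for i in test_idx])
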