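"""Span tagging: tokenization, features, and a linear-chain sequence model.

Sigs are tokenized on whitespace with punctuation split into separate
tokens (decimal literals like "1.5" stay whole).  Each token position is
described by a small feature set — character prefixes/suffixes up to
length 3, capitalization flags for the current and previous token, a
contains-digit flag, the current surface, and the surfaces of tokens up
to three positions away.  Spans are encoded per token with the BIO scheme
over the 19 schema labels.

The sequence model is a linear-chain model with per-position emission
weights over the features above plus label-transition weights, trained
with the averaged structured perceptron and decoded with Viterbi.
Training is deterministic given the corpus order and seed.  A signed
``bias`` applied at decode time penalizes span-opening transitions by
``scale * bias``, so each decoded span pays the penalty exactly once:
positive values trade recall for precision (large values suppress all
tags), negative values trade precision for recall (large negative values
tag every token).  The scale is calibrated from training-data decision
margins so the conventional settings ±3 move the operating point
visibly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io import SigDocument
from .schema import TagInstance

__all__ = [
    "Token",
    "tokenize",
    "extract_features",
    "encode_bio",
    "decode_bio",
    "TaggerConfig",
    "SequenceTagger",
    "train",
    "tag",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\d+\.\d+|\d+|[A-Za-z]+|[^\sA-Za-z\d]")

_BOUNDARY = "<S>"


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Whitespace/punctuation tokenizer with exact offsets.

    Punctuation characters (including hyphen and slash) become separate
    tokens, so range endpoints ("2-3") and abbreviation letters ("p.o.")
    are individually addressable; decimal literals are kept whole.
    """
    return [Token(m.group(0), m.start(), m.end())
            for m in _TOKEN_RE.finditer(text)]


def extract_features(tokens: Sequence[Token], i: int) -> list[str]:
    """Feature strings for position ``i`` (see module docstring)."""
    surface = tokens[i].surface
    feats = [f"w={surface}"]
    for n in (1, 2, 3):
        if len(surface) >= n:
            feats.append(f"pre{n}={surface[:n]}")
            feats.append(f"suf{n}={surface[-n:]}")
    if surface[:1].isupper():
        feats.append("cap")
    prev = tokens[i - 1].surface if i > 0 else _BOUNDARY
    if prev[:1].isupper():
        feats.append("prev_cap")
    if any(c.isdigit() for c in surface):
        feats.append("digit")
    for off in (-3, -2, -1, 1, 2, 3):
        j = i + off
        ctx = tokens[j].surface if 0 <= j < len(tokens) else _BOUNDARY
        feats.append(f"w[{off}]={ctx}")
    return feats


def encode_bio(tokens: Sequence[Token], tags: Sequence[TagInstance]) -> list[str]:
    """Token-level BIO labels for gold spans.

    Spans not aligned to token boundaries are snapped outward to the full
    covering tokens (with a logged warning).  When spans overlap, the
    earlier-starting tag wins the contested tokens.
    """
    labels = ["O"] * len(tokens)
    for t in sorted(tags, key=lambda t: (t.start, t.end)):
        covered = [k for k, tok in enumerate(tokens)
                   if tok.end > t.start and tok.start < t.end]
        if not covered:
            continue
        first, last = covered[0], covered[-1]
        if tokens[first].start < t.start or tokens[last].end > t.end:
            logger.warning(
                "span [%d,%d) of %s snapped outward to token boundaries "
                "[%d,%d)", t.start, t.end, t.label,
                tokens[first].start, tokens[last].end)
        if any(labels[k] != "O" for k in covered):
            continue  # keep the earlier tag on contested tokens
        labels[first] = f"B-{t.label}"
        for k in covered[1:]:
            labels[k] = f"I-{t.label}"
    return labels


def decode_bio(tokens: Sequence[Token], labels: Sequence[str]) -> list[TagInstance]:
    """Convert maximal B/I runs back to spans (orphan I- starts a run)."""
    tags: list[TagInstance] = []
    i = 0
    while i < len(labels):
        lab = labels[i]
        if lab == "O":
            i += 1
            continue
        name = lab[2:]
        j = i + 1
        while j < len(labels) and labels[j] == f"I-{name}":
            j += 1
        tags.append(TagInstance(name, tokens[i].start, tokens[j - 1].end))
        i = j
    return tags


@dataclass
class TaggerConfig:
    """Training configuration (all deterministic knobs).

    ``bias_scale`` converts the conventional decode-bias settings
    (±3 and friends) into the model's raw score scale.  ``None`` selects
    automatic calibration at the end of training: the scale is set to
    one third of the median per-token decision margin on the training
    data, so a bias of ±3 shifts every non-O emission by one full
    typical margin — enough to visibly trade precision against recall
    regardless of how large the learned weights happen to be.
    """

    epochs: int = 12
    seed: int = 0
    shuffle: bool = True
    bias_scale: Optional[float] = None  # None → calibrate from margins


class SequenceTagger:
    """Averaged-perceptron linear-chain tagger over BIO labels."""

    def __init__(self, config: Optional[TaggerConfig] = None):
        self.config = config or TaggerConfig()
        self.labels: list[str] = ["O"]
        self.weights: dict[str, np.ndarray] = {}
        self.transitions: np.ndarray = np.zeros((2, 1))
        self.bias_scale: float = 1.0

    # -- internals --------------------------------------------------------
    def _emissions(self, feats: list[list[str]]) -> np.ndarray:
        L = len(self.labels)
        E = np.zeros((len(feats), L))
        for t, fs in enumerate(feats):
            for f in fs:
                w = self.weights.get(f)
                if w is not None:  # unseen features are ignored
                    E[t] += w
        return E

    def _viterbi(self, E: np.ndarray) -> list[int]:
        T, L = E.shape
        if T == 0:
            return []
        trans = self.transitions  # (L+1, L); row L = sequence start
        delta = trans[L] + E[0]
        back = np.zeros((T, L), dtype=np.intp)
        for t in range(1, T):
            scores = delta[:, None] + trans[:L]
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(L)] + E[t]
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        return path[::-1]

    def _span_margin(self, E: np.ndarray, path: list[int], i: int,
                     j: int) -> float:
        """Score advantage of the decoded span over replacing it with O."""
        trans = self.transitions
        L = len(self.labels)
        margin = 0.0
        for t in range(i, j):
            margin += E[t, path[t]] - E[t, 0]
            prev = path[t - 1] if t > 0 else L
            prev_o = (0 if i <= t - 1 else prev) if t > 0 else L
            margin += trans[prev, path[t]] - trans[prev_o, 0]
        if j < len(path):
            prev = path[j - 1]
            margin += trans[prev, path[j]] - trans[0, path[j]]
        return margin

    def _flip_cost(self, E: np.ndarray, path: list[int], t: int,
                   k: int) -> float:
        """Score cost of flipping O position ``t`` to label ``k``."""
        trans = self.transitions
        L = len(self.labels)
        prev = path[t - 1] if t > 0 else L
        cost = E[t, 0] - E[t, k] + trans[prev, 0] - trans[prev, k]
        if t + 1 < len(path):
            cost += trans[0, path[t + 1]] - trans[k, path[t + 1]]
        return cost

    def _decode_indices(self, feats: list[list[str]], bias: float) -> list[int]:
        """Viterbi decode with the precision/recall bias applied.

        The bias edits the unbiased Viterbi path span by span, so the
        two directions never fragment or merge confident spans.
        Positive bias prunes whole decoded spans whose score margin over
        an all-O replacement is below ``bias_scale * bias`` — the
        weakest spans drop first, so precision rises and in the limit no
        tags remain.  Negative bias additionally opens a single-token
        span on every O position whose cheapest flip to a span-opening
        label costs at most ``bias_scale * |bias|`` — decoded spans are
        untouched, recall can only rise, and in the limit every token is
        tagged.  Zero bias is plain Viterbi.
        """
        E = self._emissions(feats)
        path = self._viterbi(E)
        if bias > 0:
            threshold = self.bias_scale * bias
            t = 0
            while t < len(path):
                if path[t] == 0:
                    t += 1
                    continue
                name = self.labels[path[t]][2:]
                j = t + 1
                while j < len(path) and self.labels[path[j]] == f"I-{name}":
                    j += 1
                if self._span_margin(E, path, t, j) < threshold:
                    for k in range(t, j):
                        path[k] = 0
                t = j
        elif bias < 0:
            threshold = self.bias_scale * (-bias)
            b_cols = [k for k, lab in enumerate(self.labels)
                      if lab.startswith("B-")]
            if b_cols:
                flips = []
                for t in range(len(path)):
                    if path[t] != 0:
                        continue
                    best = min(b_cols,
                               key=lambda k: (self._flip_cost(E, path, t, k), k))
                    if self._flip_cost(E, path, t, best) <= threshold:
                        flips.append((t, best))
                for t, k in flips:
                    path[t] = k
        return path

    # -- training ---------------------------------------------------------
    def fit(self, sequences: list[tuple[list[list[str]], list[str]]]) -> "SequenceTagger":
        """Train on (features, BIO labels) pairs with the averaged perceptron."""
        if not sequences:
            raise ValueError("empty training corpus")
        base_labels = set()
        for _, labs in sequences:
            base_labels.update(l[2:] for l in labs if l != "O")
        self.labels = ["O"] + sorted(
            f"{p}-{l}" for l in base_labels for p in ("B", "I"))
        index = {lab: k for k, lab in enumerate(self.labels)}
        L = len(self.labels)
        self.transitions = np.zeros((L + 1, L))
        self.weights = {}
        # averaging accumulators (lazy, timestamp-based)
        acc_w: dict[str, np.ndarray] = {}
        acc_t = np.zeros((L + 1, L))
        stamp_w: dict[str, int] = {}
        stamp_t = np.zeros((L + 1, L), dtype=np.int64)
        step = 0

        rng = np.random.default_rng(self.config.seed)
        order = np.arange(len(sequences))
        for _epoch in range(self.config.epochs):
            if self.config.shuffle:
                rng.shuffle(order)
            for si in order:
                feats, labs = sequences[si]
                if not feats:
                    continue
                gold = [index[l] for l in labs]
                pred = self._decode_indices(feats, 0.0)
                step += 1
                if pred == gold:
                    continue
                for t, fs in enumerate(feats):
                    if pred[t] == gold[t]:
                        continue
                    for f in fs:
                        w = self.weights.get(f)
                        if w is None:
                            w = self.weights[f] = np.zeros(L)
                            acc_w[f] = np.zeros(L)
                            stamp_w[f] = step
                        else:
                            acc_w[f] += (step - stamp_w[f]) * w
                            stamp_w[f] = step
                        w[gold[t]] += 1.0
                        w[pred[t]] -= 1.0
                for t in range(len(feats)):
                    pg = gold[t - 1] if t > 0 else L
                    pp = pred[t - 1] if t > 0 else L
                    if (pg, gold[t]) != (pp, pred[t]):
                        for (r, c, d) in ((pg, gold[t], 1.0), (pp, pred[t], -1.0)):
                            acc_t[r, c] += (step - stamp_t[r, c]) * self.transitions[r, c]
                            stamp_t[r, c] = step
                            self.transitions[r, c] += d
        # finalize averages
        for f, w in self.weights.items():
            acc_w[f] += (step + 1 - stamp_w[f]) * w
            self.weights[f] = acc_w[f] / max(step, 1)
        acc_t += (step + 1 - stamp_t) * self.transitions
        self.transitions = acc_t / max(step, 1)
        self._calibrate_bias_scale(sequences)
        return self

    def _calibrate_bias_scale(self, sequences) -> None:
        """Set the bias unit from the median per-token decision margin."""
        if self.config.bias_scale is not None:
            self.bias_scale = self.config.bias_scale
            return
        margins: list[float] = []
        for feats, _labs in sequences:
            if not feats:
                continue
            E = self._emissions(feats)
            if E.shape[1] < 2:
                continue
            part = np.partition(E, -2, axis=1)
            margins.extend((part[:, -1] - part[:, -2]).tolist())
        med = float(np.median(margins)) if margins else 1.0
        self.bias_scale = max(med, 1e-6) / 3.0

    # -- inference --------------------------------------------------------
    def decode(self, tokens: Sequence[Token], bias: float = 0.0) -> list[str]:
        if not tokens:
            return []
        feats = [extract_features(tokens, i) for i in range(len(tokens))]
        return [self.labels[k] for k in self._decode_indices(feats, bias)]

    def tag_text(self, text: str, bias: float = 0.0) -> list[TagInstance]:
        tokens = tokenize(text)
        return decode_bio(tokens, self.decode(tokens, bias))

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "rxsig-tagger",
            "version": 1,
            "labels": self.labels,
            "config": {
                "epochs": self.config.epochs,
                "seed": self.config.seed,
                "shuffle": self.config.shuffle,
                "bias_scale": self.config.bias_scale,
            },
            "bias_scale": self.bias_scale,
            "transitions": self.transitions.tolist(),
            "weights": {f: w.tolist() for f, w in self.weights.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SequenceTagger":
        cfg = TaggerConfig(**data.get("config", {}))
        model = cls(cfg)
        model.labels = list(data["labels"])
        model.bias_scale = float(data.get("bias_scale", 1.0))
        model.transitions = np.asarray(data["transitions"], dtype=float)
        model.weights = {f: np.asarray(w, dtype=float)
                         for f, w in data["weights"].items()}
        return model

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SequenceTagger":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def train(corpus: Iterable[SigDocument],
          config: Optional[TaggerConfig] = None) -> SequenceTagger:
    """Train a tagger from annotated documents."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty training corpus")
    sequences = []
    for doc in corpus:
        tokens = tokenize(doc.text)
        feats = [extract_features(tokens, i) for i in range(len(tokens))]
        labels = encode_bio(tokens, doc.tags)
        sequences.append((feats, labels))
    return SequenceTagger(config).fit(sequences)


def tag(model: SequenceTagger, text: str, bias: float = 0.0) -> list[TagInstance]:
    """Decode spans for one sig at the given precision/recall bias."""
    return model.tag_text(text, bias)
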