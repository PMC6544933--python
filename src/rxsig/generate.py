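"""Seeded synthetic sig corpus with gold annotations and paired records.

Real prescription-direction corpora are rarely shareable, so this module
fabricates one: short template-based sigs ("take 2 tablets by mouth twice
a day as needed for pain") with gold tags whose spans exactly cover the
realized slot surfaces, plus a structured prescription record per sig
whose fields agree with the gold attributes by construction.

Fidelity knobs mirror the phenomena that make real sigs hard:

* number expressions rendered as digits or words ("three"), including
  fractions ("one and a half") and ranges ("2-3");
* clinical abbreviations (TID, b.i.d., p.o., prn) swapped in for long
  surface forms with a configurable probability;
* single-character misspellings of choice-attribute surfaces (never of
  numbers), the exact failure mode the edit-distance fallback exists for;
* a configurable fraction of records whose structured fields contradict
  the sig, with the perturbations logged as ground truth for evaluating
  discrepancy detection.

Per-label tag frequencies follow a configurable relative-weight profile;
template sampling weights are fit to the profile by non-negative least
squares over the templates' label-count vectors.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field as dc_field
from fractions import Fraction
from typing import Callable, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy.optimize import nnls

from .io import PrescriptionRecord, SigDocument
from .lexicon import attrs_to_freq_code
from .numbers import render_decimal
from .schema import LABELS, TagInstance

__all__ = [
    "NoiseConfig",
    "GeneratorConfig",
    "Perturbation",
    "CorpusBundle",
    "DEFAULT_TAG_WEIGHTS",
    "generate_corpus",
    "realize_template",
    "SigTemplate",
]

#: Default relative per-label frequency weights (annotated-corpus profile).
DEFAULT_TAG_WEIGHTS: dict[str, float] = {
    "DISPENSE": 46, "DISPENSE_UNIT": 73, "DOSEAMOUNT": 221,
    "DOSEAMOUNT_UNIT": 202, "DOSEFORM": 533, "DURATION": 205,
    "DURATION_UNIT": 193, "FREQ": 1329, "INDICATION": 319,
    "INSTRUCTION": 4075, "MEDICATION": 145, "PRN": 232, "REFILL": 70,
    "ROUTE": 591, "STRENGTH": 33, "STRENGTH_UNIT": 34, "SUB_STATUS": 112,
    "TAKE": 774, "TIMING": 1359,
}


@dataclass(frozen=True)
class NoiseConfig:
    """Noise probabilities for surface realization."""

    misspelling_prob: float = 0.05
    abbreviation_prob: float = 0.3
    number_word_prob: float = 0.3


@dataclass
class GeneratorConfig:
    n_documents: int = 1000
    seed: int = 17
    tag_frequency_targets: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_TAG_WEIGHTS))
    noise: NoiseConfig = dc_field(default_factory=NoiseConfig)
    discrepancy_rate: float = 0.0


class Perturbation(NamedTuple):
    """One logged structured-field corruption."""

    record_id: str
    field: str
    original: str
    perturbed: str


class CorpusBundle(NamedTuple):
    documents: list[SigDocument]
    records: list[PrescriptionRecord]
    perturbations: list[Perturbation]


# ---------------------------------------------------------------------------
# Surface realization helpers

_NUM_WORDS = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven",
    12: "twelve",
}


def _fr(x: Union[int, float]) -> Fraction:
    return Fraction(str(x))


def _num_value(v: Fraction) -> Union[int, float]:
    return int(v) if v.denominator == 1 else float(v)


def _render_number(value: Fraction, rng: random.Random,
                   noise: NoiseConfig) -> str:
    if rng.random() < noise.number_word_prob:
        if value == Fraction(3, 2):
            return "one and a half"
        if value.denominator == 1 and int(value) in _NUM_WORDS:
            return _NUM_WORDS[int(value)]
    return render_decimal(value)


def _misspell(word: str, rng: random.Random) -> str:
    """One random character edit; only applied to alphabetic words."""
    if len(word) < 4 or not word.isalpha():
        return word
    op = rng.choice(("delete", "substitute", "insert"))
    i = rng.randrange(len(word))
    letter = rng.choice(string.ascii_lowercase)
    if op == "delete":
        return word[:i] + word[i + 1:]
    if op == "substitute":
        return word[:i] + letter + word[i + 1:]
    return word[:i] + letter + word[i:]


def _maybe_misspell(word: str, rng: random.Random, noise: NoiseConfig) -> str:
    if rng.random() < noise.misspelling_prob:
        return _misspell(word, rng)
    return word


# A realized piece: surface text plus an optional (label, attributes) tag
# covering exactly that surface.
Piece = tuple[str, Optional[tuple[str, dict]]]
SlotResult = tuple[list[Piece], dict[str, str]]
Slot = Callable[[random.Random, NoiseConfig], SlotResult]


def _slot_take(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    if rng.random() < 0.15:
        lo, hi = rng.choice(((1, 2), (2, 3), (3, 4)))
        surface = f"{lo}-{hi}"
        attrs = {"amount": lo, "to_amount": hi}
        rec = {"take": str(lo)}
    else:
        value = _fr(rng.choice((1, 1, 2, 2, 2, 3, 4, 1.5)))
        surface = _render_number(value, rng, noise)
        attrs = {"amount": _num_value(value), "to_amount": None}
        rec = {"take": render_decimal(value)}
    return [(surface, ("TAKE", attrs))], rec


_FORMS = {
    "tablet": ("tablet", "tablets", "tab", "tabs"),
    "capsule": ("capsule", "capsules", "caps"),
    "puff": ("puff", "puffs"),
    "drop": ("drop", "drops"),
    "spray": ("spray", "sprays"),
    "patch": ("patch",),
}


def _slot_form(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    form = rng.choice(tuple(_FORMS))
    surface = _maybe_misspell(rng.choice(_FORMS[form]), rng, noise)
    return ([(surface, ("DOSEFORM", {"form": form}))],
            {"form": form.capitalize()})


_FREQ_COUNT_UNITS = ("a day", "per day", "daily")


def _slot_freq(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    kind = rng.choices(("count", "count_range", "interval", "interval_range",
                        "idiom"), weights=(30, 10, 25, 10, 25))[0]
    if kind == "idiom" and rng.random() < noise.abbreviation_prob:
        surface, attrs = rng.choice((
            ("b.i.d.", {"times_per": 2, "every": 1, "unit": "day"}),
            ("t.i.d.", {"times_per": 3, "every": 1, "unit": "day"}),
            ("TID", {"times_per": 3, "every": 1, "unit": "day"}),
            ("BID", {"times_per": 2, "every": 1, "unit": "day"}),
            ("QID", {"times_per": 4, "every": 1, "unit": "day"}),
            ("q.d.", {"times_per": 1, "every": 1, "unit": "day"}),
        ))
    elif kind == "idiom":
        surface, attrs = rng.choice((
            ("once daily", {"times_per": 1, "every": 1, "unit": "day"}),
            ("twice a day", {"times_per": 2, "every": 1, "unit": "day"}),
            ("twice daily", {"times_per": 2, "every": 1, "unit": "day"}),
            ("every other day", {"times_per": 1, "every": 2, "unit": "day"}),
            ("once a day", {"times_per": 1, "every": 1, "unit": "day"}),
            ("every day", {"times_per": 1, "every": 1, "unit": "day"}),
        ))
    elif kind == "count":
        n = rng.choice((2, 3, 3, 4, 5))
        unit_surf = rng.choice(_FREQ_COUNT_UNITS)
        surface = f"{_render_number(_fr(n), rng, noise)} times {unit_surf}"
        if unit_surf == "daily":
            surface = f"{_render_number(_fr(n), rng, noise)} times daily"
        attrs = {"times_per": n, "every": 1, "unit": "day"}
    elif kind == "count_range":
        lo, hi = rng.choice(((2, 3), (3, 4), (1, 2)))
        surface = f"{lo}-{hi} times {rng.choice(('per day', 'a day'))}"
        attrs = {"times_per": lo, "to_times_per": hi, "every": 1,
                 "unit": "day"}
    elif kind == "interval":
        n, unit = rng.choice(((4, "hour"), (6, "hour"), (8, "hour"),
                              (12, "hour"), (2, "day"), (3, "day"),
                              (1, "week")))
        unit_surf = unit + "s" if n != 1 else unit
        surface = f"every {_render_number(_fr(n), rng, noise)} {unit_surf}"
        if n == 1:
            surface = f"every {unit}"
        attrs = {"times_per": 1, "every": n, "unit": unit}
    else:  # interval_range
        lo, hi, unit = rng.choice(((4, 6, "hour"), (6, 8, "hour"),
                                   (2, 3, "day")))
        surface = f"every {lo}-{hi} {unit}s"
        attrs = {"times_per": 1, "every": lo, "to_every": hi, "unit": unit}
    full = {"times_per": 1, "to_times_per": None, "every": 1,
            "to_every": None, "unit": "day"}
    full.update(attrs)
    code = attrs_to_freq_code(full)
    if code is None:
        # canonical digit phrase; always parseable by the idiom/rule parser
        if full["to_every"] is not None or (full["every"] not in (None, 1)):
            hi = f"-{full['to_every']}" if full["to_every"] is not None else ""
            code = f"every {full['every']}{hi} {full['unit']}s"
        else:
            hi = f"-{full['to_times_per']}" if full["to_times_per"] is not None else ""
            code = f"{full['times_per']}{hi} times per {full['unit']}"
    return [(surface, ("FREQ", full))], {"frequency": code}


_TIMINGS: tuple[tuple[str, dict], ...] = (
    ("before meals", {"direction": "before", "event": "meals"}),
    ("after meals", {"direction": "after", "event": "meals"}),
    ("with meals", {"direction": "other", "event": "meals"}),
    ("at bedtime", {"event": "bedtime"}),
    ("in the morning", {"event": "morning"}),
    ("in the evening", {"event": "evening"}),
    ("before breakfast", {"direction": "before", "event": "breakfast"}),
    ("after dinner", {"direction": "after", "event": "dinner"}),
    ("1 hour after meals", {"offset": 1, "offset_unit": "hour",
                            "direction": "after", "event": "meals"}),
    ("30 minutes before breakfast", {"offset": 30, "offset_unit": "minute",
                                     "direction": "before",
                                     "event": "breakfast"}),
    ("2 hours before the procedure", {"offset": 2, "offset_unit": "hour",
                                      "direction": "before",
                                      "event": "procedure"}),
)


def _slot_timing(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    surface, attrs = rng.choice(_TIMINGS)
    full = {"offset": None, "to_offset": None, "offset_unit": None,
            "direction": None, "event": None}
    full.update(attrs)
    return [(surface, ("TIMING", full))], {}


_ROUTES: tuple[tuple[str, str, Optional[str], str, bool], ...] = (
    # (surface, route, side, structured code, abbreviation?)
    ("by mouth", "oral", None, "PO", False),
    ("orally", "oral", None, "PO", False),
    ("p.o.", "oral", None, "PO", True),
    ("topically", "topical", None, "TOPICAL", False),
    ("under the tongue", "sublingual", None, "SL", False),
    ("in the left ear", "otic", "left", "OTIC", False),
    ("in the right eye", "ophthalmic", "right", "OPHTHALMIC", False),
    ("in each nostril", "nasal", "both", "NASAL", False),
    ("rectally", "rectal", None, "PR", False),
)


def _slot_route(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    abbrevs = [r for r in _ROUTES if r[4]]
    longs = [r for r in _ROUTES if not r[4]]
    pool = abbrevs if rng.random() < noise.abbreviation_prob else longs
    surface, route, side, code, _ = rng.choice(pool)
    return ([(surface, ("ROUTE", {"route": route, "side": side}))],
            {"route": code})


def _slot_duration(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    if rng.random() < 0.15:
        lo, hi, unit = rng.choice(((7, 10, "day"), (2, 3, "week")))
        num_piece = (f"{lo}-{hi}", ("DURATION", {"num": lo, "to_num": hi}))
        rec_num = str(lo)
    else:
        n, unit = rng.choice(((5, "day"), (7, "day"), (10, "day"),
                              (14, "day"), (30, "day"), (2, "week"),
                              (3, "week"), (1, "month")))
        num_piece = (_render_number(_fr(n), rng, noise),
                     ("DURATION", {"num": n, "to_num": None}))
        rec_num = str(n)
    unit_surface = _maybe_misspell(
        unit + "s" if rec_num != "1" else unit, rng, noise)
    return ([("for ", None), num_piece, (" ", None),
             (unit_surface, ("DURATION_UNIT", {"unit": unit}))],
            {"duration": rec_num, "duration_units": unit.capitalize() + "(s)"})


_REASONS = ("pain", "nausea", "anxiety", "insomnia", "cough", "headache",
            "fever", "itching", "wheezing")


def _slot_prn_ind(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    prn_surface = "prn" if rng.random() < noise.abbreviation_prob else "as needed"
    reason = rng.choice(_REASONS)
    return ([(prn_surface, ("PRN", {})), (" for ", None),
             (reason, ("INDICATION", {}))],
            {"prn": "1", "prn_reason": reason.capitalize()})


def _slot_prn(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    prn_surface = "prn" if rng.random() < noise.abbreviation_prob else "as needed"
    return [(prn_surface, ("PRN", {}))], {"prn": "1"}


def _slot_indication(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    reason = rng.choice(_REASONS)
    return ([("for ", None), (reason, ("INDICATION", {}))],
            {"prn_reason": reason.capitalize()})


_MEDICATIONS = ("ibuprofen", "amoxicillin", "lisinopril", "metformin",
                "atorvastatin", "omeprazole", "sertraline", "albuterol",
                "prednisone", "gabapentin")


def _slot_medication(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    name = rng.choice(_MEDICATIONS)
    return ([(name, ("MEDICATION", {"name": name}))],
            {"medication": name.upper()})


def _slot_strength(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    amount = rng.choice((25, 50, 100, 200, 250, 400, 500, 600, 800))
    return ([(str(amount), ("STRENGTH", {"amount": amount, "to_amount": None})),
             (" ", None),
             ("mg", ("STRENGTH_UNIT", {"unit": "mg"}))],
            {"strength": f"{amount}MG"})


def _slot_doseamount(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    amount = rng.choice((100, 200, 400, 500, 600, 800))
    unit = rng.choice(("mg", "mg", "mg", "mcg", "ml"))
    unit_surface = _maybe_misspell(unit, rng, noise)
    return ([(str(amount), ("DOSEAMOUNT", {"amount": amount, "to_amount": None})),
             (" ", None),
             (unit_surface, ("DOSEAMOUNT_UNIT", {"unit": unit}))],
            {"dose": str(amount), "dose_units": unit.upper()})


def _slot_dispense(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    qty = rng.choice((30, 60, 90, 120))
    form = rng.choice(("tablet", "capsule"))
    unit_surface = _maybe_misspell(form + "s", rng, noise)
    return ([("dispense ", None),
             (str(qty), ("DISPENSE", {"quantity": qty, "to_quantity": None})),
             (" ", None),
             (unit_surface, ("DISPENSE_UNIT", {"unit": form}))],
            {"dispense_quantity": str(qty),
             "dispense_quantity_units": form.capitalize() + "(s)"})


def _slot_dispense_unit(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    form = rng.choice(("tablet", "capsule"))
    unit_surface = _maybe_misspell(form + "s", rng, noise)
    return ([("dispense as ", None),
             (unit_surface, ("DISPENSE_UNIT", {"unit": form}))],
            {"dispense_quantity_units": form.capitalize() + "(s)"})


def _slot_refill(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    surface, value = rng.choice((("no refills", False), ("no refill", False),
                                 ("refills allowed", True),
                                 ("may refill", True)))
    return [(surface, ("REFILL", {"refill": value}))], {}


def _slot_substatus(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    surface, value = rng.choice((("no substitutions", False),
                                 ("no substitution", False),
                                 ("substitution permitted", True),
                                 ("may substitute", True)))
    return [(surface, ("SUB_STATUS", {"subst": value}))], {}


_INSTRUCTIONS = (
    "then stop", "do not crush", "take with a full glass of water",
    "call your physician if symptoms persist", "shake well before use",
    "finish all medication", "may cause drowsiness", "avoid alcohol",
    "store at room temperature", "use as directed",
    "discard after 30 days", "do not exceed the recommended dose",
)


def _slot_instruction(rng: random.Random, noise: NoiseConfig) -> SlotResult:
    note = rng.choice(_INSTRUCTIONS)
    return [(note, ("INSTRUCTION", {"note": note}))], {}


_SLOTS: dict[str, tuple[Slot, tuple[str, ...]]] = {
    # name → (realizer, labels it always emits)
    "TAKE": (_slot_take, ("TAKE",)),
    "FORM": (_slot_form, ("DOSEFORM",)),
    "FREQ": (_slot_freq, ("FREQ",)),
    "TIMING": (_slot_timing, ("TIMING",)),
    "ROUTE": (_slot_route, ("ROUTE",)),
    "DUR": (_slot_duration, ("DURATION", "DURATION_UNIT")),
    "PRNIND": (_slot_prn_ind, ("PRN", "INDICATION")),
    "PRN": (_slot_prn, ("PRN",)),
    "IND": (_slot_indication, ("INDICATION",)),
    "MED": (_slot_medication, ("MEDICATION",)),
    "STRENGTH": (_slot_strength, ("STRENGTH", "STRENGTH_UNIT")),
    "AMOUNT": (_slot_doseamount, ("DOSEAMOUNT", "DOSEAMOUNT_UNIT")),
    "DISP": (_slot_dispense, ("DISPENSE", "DISPENSE_UNIT")),
    "DISPU": (_slot_dispense_unit, ("DISPENSE_UNIT",)),
    "REFILL": (_slot_refill, ("REFILL",)),
    "SUBST": (_slot_substatus, ("SUB_STATUS",)),
    "INSTR": (_slot_instruction, ("INSTRUCTION",)),
}


@dataclass(frozen=True)
class SigTemplate:
    """A sequence of literal strings and slot names."""

    parts: tuple[str, ...]
    slots: tuple[str, ...]  # names within parts that are slots

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.slots:
            for label in _SLOTS[name][1]:
                counts[label] = counts.get(label, 0) + 1
        return counts


def _template(*parts: str) -> SigTemplate:
    slots = tuple(p for p in parts if p in _SLOTS)
    return SigTemplate(parts=tuple(parts), slots=slots)


#: The template inventory.  Every label occurs in at least one template;
#: instruction clauses appear both inline and as whole-sig templates.
TEMPLATES: tuple[SigTemplate, ...] = (
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ"),
    _template("take ", "TAKE", " ", "FORM", " ", "ROUTE", " ", "FREQ"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "PRNIND"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "DUR"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "TIMING"),
    _template("take ", "TAKE", " ", "FORM", " ", "ROUTE", " ", "FREQ", " ",
              "TIMING"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "TIMING", " ",
              "DUR", ", ", "INSTR"),
    _template("take ", "TAKE", " ", "ROUTE", " ", "FREQ"),
    _template("take ", "TAKE", " ", "FREQ", " ", "PRNIND"),
    _template("take ", "AMOUNT", " ", "ROUTE", " ", "FREQ"),
    _template("take ", "AMOUNT", " ", "FREQ"),
    _template("take ", "AMOUNT", " ", "FREQ", " ", "PRNIND"),
    _template("take ", "AMOUNT", " ", "FREQ", " ", "TIMING"),
    _template("MED", " ", "STRENGTH", ": take ", "TAKE", " ", "FORM", " ",
              "FREQ"),
    _template("take ", "TAKE", " ", "FORM", " of ", "MED", " ", "FREQ"),
    _template("use ", "MED", " ", "TIMING"),
    _template("use ", "MED", " ", "FREQ", " ", "PRNIND"),
    _template("take ", "TAKE", " ", "FORM", " ", "TIMING"),
    _template("apply ", "ROUTE", " ", "FREQ"),
    _template("apply ", "ROUTE", " ", "FREQ", " ", "TIMING"),
    _template("use ", "ROUTE", " ", "TIMING", " ", "PRNIND"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "IND"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "PRN"),
    _template("inhale ", "TAKE", " ", "FORM", " ", "FREQ", " ", "PRNIND"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", ", ", "DISP"),
    _template("DISP"),
    _template("DISPU"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", "; ", "REFILL"),
    _template("REFILL"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", "; ", "SUBST"),
    _template("SUBST"),
    _template("INSTR"),
    _template("INSTR", "; ", "INSTR"),
    _template("INSTR", "; ", "INSTR", "; ", "INSTR"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", ", ", "INSTR"),
    _template("take ", "TAKE", " ", "FORM", " ", "FREQ", " ", "DUR", ", ",
              "INSTR", "; ", "INSTR"),
    _template("use ", "TIMING", " ", "PRNIND", ", ", "INSTR"),
    _template("TIMING", ", take ", "TAKE", " ", "FORM"),
    _template("take ", "TAKE", " ", "FORM", " ", "TIMING", " and ",
              "TIMING"),
    _template("take ", "TAKE", " ", "FORM", " ", "ROUTE", " ", "FREQ", " ",
              "DUR", " ", "IND", ", ", "INSTR"),
)


def fit_template_weights(targets: dict[str, float],
                         templates: Sequence[SigTemplate] = TEMPLATES) -> np.ndarray:
    """Template sampling probabilities matching a per-label weight profile.

    Solves a non-negative least-squares problem over the templates'
    label-count vectors so that the expected per-label tag counts of a
    sampled corpus are proportional to ``targets``.
    """
    labels = [l for l in LABELS if targets.get(l, 0) > 0]
    total = sum(targets[l] for l in labels)
    b = np.array([targets[l] / total for l in labels])
    A = np.zeros((len(labels), len(templates)))
    for j, tpl in enumerate(templates):
        counts = tpl.label_counts()
        for i, lab in enumerate(labels):
            A[i, j] = counts.get(lab, 0)
    # scale so that the fitted p sums near 1; exact scale is irrelevant
    # because p is renormalized (relative proportions are preserved).
    mean_tags = float(A.sum(axis=0).mean())
    weights, _ = nnls(A, b * mean_tags / max(A.sum(axis=0).max(), 1))
    if weights.sum() <= 0:
        raise ValueError("template weights degenerate for given targets")
    return weights / weights.sum()


def realize_template(template: SigTemplate, rng: random.Random,
                     noise: Optional[NoiseConfig] = None,
                     doc_id: str = "sig-0") -> tuple[SigDocument, dict[str, str]]:
    """Realize one template into a document plus record-field updates.

    Gold attributes are fixed before surface rendering, so a slot whose
    number is rendered as "three" still carries the gold value 3.
    """
    noise = noise or NoiseConfig()
    pieces: list[Piece] = []
    record_updates: dict[str, str] = {}
    for part in template.parts:
        if part in _SLOTS:
            slot_pieces, updates = _SLOTS[part][0](rng, noise)
            pieces.extend(slot_pieces)
            record_updates.update(updates)
        else:
            pieces.append((part, None))
    text_parts: list[str] = []
    tags: list[TagInstance] = []
    pos = 0
    for surface, tag_info in pieces:
        text_parts.append(surface)
        if tag_info is not None:
            label, attrs = tag_info
            tags.append(TagInstance(label, pos, pos + len(surface),
                                    dict(attrs)))
        pos += len(surface)
    doc = SigDocument(doc_id=doc_id, text="".join(text_parts), tags=tags,
                      source="synthetic")
    return doc, record_updates


_PERTURBABLE = ("take", "frequency", "route", "duration",
                "dispense_quantity", "form", "prn_reason")

_ALT_FREQ = ("QD", "BID", "TID", "QID", "Q6H")
_ALT_ROUTE = ("PO", "TOPICAL", "SL", "PR", "OTIC")
_ALT_FORM = ("Tablet", "Capsule", "Puff", "Drop", "Spray")


def _perturb_record(rec: PrescriptionRecord, rng: random.Random
                    ) -> Optional[Perturbation]:
    """Corrupt one non-empty comparable structured field, if any."""
    candidates = [f for f in _PERTURBABLE if getattr(rec, f)]
    if not candidates:
        return None
    fld = rng.choice(candidates)
    original = getattr(rec, fld)
    if fld in ("take", "duration", "dispense_quantity"):
        bump = 3 if fld != "take" else 1
        new = render_decimal(Fraction(original) + bump)
    elif fld == "frequency":
        new = rng.choice([c for c in _ALT_FREQ if c != original] or ["Q8H"])
    elif fld == "route":
        new = rng.choice([c for c in _ALT_ROUTE if c != original])
    elif fld == "form":
        new = rng.choice([c for c in _ALT_FORM if c != original])
    else:  # prn_reason
        new = rng.choice([r.capitalize() for r in _REASONS
                          if r.capitalize() != original])
    setattr(rec, fld, new)
    return Perturbation(rec.id, fld, original, new)


def generate_corpus(config: Optional[GeneratorConfig] = None) -> CorpusBundle:
    """Generate a seeded synthetic corpus with paired structured records.

    Returns (documents, records, perturbations); the perturbation log is
    the ground truth for discrepancy-detection evaluation.  Deterministic
    given the config seed.
    """
    config = config or GeneratorConfig()
    if config.n_documents < 1:
        raise ValueError("n_documents must be >= 1")
    rng = random.Random(config.seed)
    weights = fit_template_weights(config.tag_frequency_targets)
    docs: list[SigDocument] = []
    records: list[PrescriptionRecord] = []
    perturbations: list[Perturbation] = []
    for i in range(config.n_documents):
        tpl = rng.choices(TEMPLATES, weights=weights)[0]
        doc_id = f"sig-{i + 1:05d}"
        doc, updates = realize_template(tpl, rng, config.noise, doc_id)
        rec = PrescriptionRecord(id=str(i + 1), directions=doc.text)
        for fld, value in updates.items():
            setattr(rec, fld, value)
        if rng.random() < config.discrepancy_rate:
            pert = _perturb_record(rec, rng)
            if pert is not None:
                perturbations.append(pert)
        docs.append(doc)
        records.append(rec)
    return CorpusBundle(docs, records, perturbations)
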