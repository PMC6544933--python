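"""Shared lexicons: frequency idioms, unit/route aliases, structured codes.

Sig language is dense with idioms and Latin abbreviations whose numeric
content is implicit ("twice daily", "b.i.d.", "TID").  The tables here map
those surfaces to canonical frequency attributes and back, and fold common
unit/route spelling variants onto schema values.  They are plain data and
can be extended by callers.
"""

from __future__ import annotations

import re
from fractions import Fraction
from typing import Optional

__all__ = [
    "FREQ_IDIOMS",
    "COUNT_WORDS",
    "UNIT_WORDS",
    "fold_unit",
    "fold_route",
    "fold_form",
    "freq_code_to_attrs",
    "attrs_to_freq_code",
    "parse_freq_phrase",
]

#: times_per values implied by count words when a FREQ span has no digits.
COUNT_WORDS = {"once": 1, "twice": 2, "thrice": 3}

#: Canonical attribute maps for whole-span frequency idioms.  Keys are
#: lowercase with punctuation stripped.
FREQ_IDIOMS: dict[str, dict] = {
    "qd": {"times_per": 1, "every": 1, "unit": "day"},
    "od": {"times_per": 1, "every": 1, "unit": "day"},
    "daily": {"times_per": 1, "every": 1, "unit": "day"},
    "once daily": {"times_per": 1, "every": 1, "unit": "day"},
    "once a day": {"times_per": 1, "every": 1, "unit": "day"},
    "every day": {"times_per": 1, "every": 1, "unit": "day"},
    "bid": {"times_per": 2, "every": 1, "unit": "day"},
    "twice daily": {"times_per": 2, "every": 1, "unit": "day"},
    "twice a day": {"times_per": 2, "every": 1, "unit": "day"},
    "tid": {"times_per": 3, "every": 1, "unit": "day"},
    "qid": {"times_per": 4, "every": 1, "unit": "day"},
    "qhs": {"times_per": 1, "every": 1, "unit": "day"},
    "every other day": {"times_per": 1, "every": 2, "unit": "day"},
    "qod": {"times_per": 1, "every": 2, "unit": "day"},
    "weekly": {"times_per": 1, "every": 1, "unit": "week"},
    "qwk": {"times_per": 1, "every": 1, "unit": "week"},
    "once weekly": {"times_per": 1, "every": 1, "unit": "week"},
    "monthly": {"times_per": 1, "every": 1, "unit": "month"},
    "hourly": {"times_per": 1, "every": 1, "unit": "hour"},
}

#: Surface → schema time-unit value.
UNIT_WORDS = {
    "minute": "minute", "minutes": "minute", "min": "minute",
    "hour": "hour", "hours": "hour", "hr": "hour", "hrs": "hour", "h": "hour",
    "day": "day", "days": "day", "d": "day",
    "week": "week", "weeks": "week", "wk": "week", "wks": "week",
    "month": "month", "months": "month", "mo": "month",
}

_UNIT_ALIASES = {
    "tablet": "tablet", "tablets": "tablet", "tab": "tablet", "tabs": "tablet",
    "tablet(s)": "tablet",
    "capsule": "capsule", "capsules": "capsule", "cap": "capsule",
    "caps": "capsule", "capsule(s)": "capsule",
    "mg": "mg", "milligram": "mg", "milligrams": "mg",
    "mcg": "mcg", "microgram": "mcg", "micrograms": "mcg", "ug": "mcg",
    "g": "g", "gram": "g", "grams": "g", "gm": "g",
    "ml": "ml", "milliliter": "ml", "milliliters": "ml", "cc": "ml",
    "unit": "unit", "units": "unit",
    "puff": "puff", "puffs": "puff",
    "drop": "drop", "drops": "drop", "gtt": "drop",
}

_ROUTE_ALIASES = {
    "po": "oral", "p.o.": "oral", "by mouth": "oral", "oral": "oral",
    "orally": "oral", "per os": "oral",
    "topical": "topical", "topically": "topical",
    "sq": "subcutaneous", "subq": "subcutaneous", "sc": "subcutaneous",
    "subcutaneous": "subcutaneous", "subcutaneously": "subcutaneous",
    "im": "intramuscular", "intramuscular": "intramuscular",
    "iv": "intravenous", "intravenous": "intravenous",
    "inhaled": "inhaled", "by inhalation": "inhaled", "inh": "inhaled",
    "pr": "rectal", "rectal": "rectal", "rectally": "rectal",
    "pv": "vaginal", "vaginal": "vaginal", "vaginally": "vaginal",
    "ophthalmic": "ophthalmic", "in the eye": "ophthalmic",
    "otic": "otic", "in the ear": "otic",
    "nasal": "nasal", "nasally": "nasal", "intranasal": "nasal",
    "transdermal": "transdermal",
    "sl": "sublingual", "sublingual": "sublingual",
    "under the tongue": "sublingual",
}

_FORM_ALIASES = {
    **{k: v for k, v in _UNIT_ALIASES.items() if v in ("tablet", "capsule", "puff", "drop", "ml")},
    "patch": "patch", "patches": "patch",
    "spray": "spray", "sprays": "spray",
    "suppository": "suppository", "suppositories": "suppository",
    "application": "application", "applications": "application",
}


def _key(surface: str) -> str:
    return re.sub(r"\s+", " ", surface.lower().replace(".", "").strip())


def fold_unit(surface: str) -> Optional[str]:
    """Map a unit surface ("tabs", "Tablet(s)") to its schema value."""
    return _UNIT_ALIASES.get(_key(surface))


def fold_route(surface: str) -> Optional[str]:
    return _ROUTE_ALIASES.get(_key(surface))


def fold_form(surface: str) -> Optional[str]:
    return _FORM_ALIASES.get(_key(surface))


def parse_freq_phrase(surface: str) -> Optional[dict]:
    """Deterministic rule-based parse of a frequency phrase or code.

    Handles whole-span idioms (TID, "twice a day"), count phrases
    ("3 times a day", "2-3 times per day") and interval phrases
    ("every 6 hours", "every 4-6 hours", "q4h", "every third day").
    Returns a full FREQ attribute map or None if unparseable.
    """
    from .numbers import find_number_expressions

    key = _key(surface)
    if key in FREQ_IDIOMS:
        m = dict(FREQ_IDIOMS[key])
        m.setdefault("to_times_per", None)
        m.setdefault("to_every", None)
        return m

    # qNh / qN codes: "q4h", "q 4-6 h"
    code = re.fullmatch(r"q\s*(\d+)(?:\s*-\s*(\d+))?\s*([a-z]+)?", key)
    if code:
        unit = UNIT_WORDS.get(code.group(3) or "h", "hour")
        return {"times_per": 1, "to_times_per": None,
                "every": int(code.group(1)),
                "to_every": int(code.group(2)) if code.group(2) else None,
                "unit": unit}

    words = re.findall(r"[a-z]+", key)
    unit = None
    for w in words:
        if w in UNIT_WORDS:
            unit = UNIT_WORDS[w]
            break
    nums = [sp.value for sp in find_number_expressions(surface)]
    interval = "every" in words or "q" in words
    if unit is None and not nums:
        return None
    unit = unit or "other"

    def _num(v):
        return int(v) if Fraction(v).denominator == 1 else float(v)

    n1 = _num(nums[0]) if nums else None
    n2 = _num(nums[1]) if len(nums) > 1 else None
    if n1 is None:
        for w in words:
            if w in COUNT_WORDS:
                n1 = COUNT_WORDS[w]
                break
        if n1 is None:
            n1 = 1
    if interval:
        return {"times_per": 1, "to_times_per": None,
                "every": n1, "to_every": n2, "unit": unit}
    return {"times_per": n1, "to_times_per": n2,
            "every": 1, "to_every": None, "unit": unit}


#: Structured-field frequency codes emitted for common regimens.
_CODE_TABLE = {
    (1, 1, "day"): "QD",
    (2, 1, "day"): "BID",
    (3, 1, "day"): "TID",
    (4, 1, "day"): "QID",
    (1, 2, "day"): "QOD",
    (1, 1, "week"): "QWK",
}


def attrs_to_freq_code(attrs: dict) -> Optional[str]:
    """Render a FREQ attribute map as a structured-field code, if one fits."""
    tp, ev = attrs.get("times_per"), attrs.get("every")
    unit = attrs.get("unit")
    if attrs.get("to_times_per") is not None or attrs.get("to_every") is not None:
        return None
    try:
        key = (int(tp), int(ev), unit)
    except (TypeError, ValueError):
        return None
    if key in _CODE_TABLE:
        return _CODE_TABLE[key]
    if tp == 1 and unit == "hour" and ev and int(ev) == ev:
        return f"Q{int(ev)}H"
    if tp == 1 and unit == "day" and ev and int(ev) == ev:
        return f"Q{int(ev)}D"
    return None


def freq_code_to_attrs(code: str) -> Optional[dict]:
    """Parse a structured-field frequency value (code or phrase)."""
    return parse_freq_phrase(code)
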