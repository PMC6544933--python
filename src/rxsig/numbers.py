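"""Numeric retokenizer: canonicalize English number expressions in sigs.

Prescription directions mix digit literals ("4", "1.5"), number words
("three", "twenty one"), fractions ("1/2", "one and a half") and digit
ranges ("2-3").  Before attribute normalization every number expression is
mapped to a canonical decimal rendering while an offset map records the
correspondence between original and rewritten character positions, so that
annotation spans survive the rewrite.

Range expressions like "2-3" deliberately yield two separate number spans
(for 2 and for 3): downstream attribute rules read range endpoints as a
(value, to_value) pair.  Ordinal words ("third") are detected — their value
is needed for interval frequencies like "every third day" — but are not
rewritten; they carry an ``ordinal`` marker instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

__all__ = [
    "NumberSpan",
    "NormalizedText",
    "find_number_expressions",
    "canonicalize",
    "render_decimal",
    "parse_number",
]

_UNITS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9,
}
_TEENS = {
    "ten": 10, "eleven": 11, "twelve": 12, "thirteen": 13, "fourteen": 14,
    "fifteen": 15, "sixteen": 16, "seventeen": 17, "eighteen": 18,
    "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50, "sixty": 60,
    "seventy": 70, "eighty": 80, "ninety": 90,
}
_FRACTION_WORDS = {"half": Fraction(1, 2), "quarter": Fraction(1, 4)}
_ORDINALS = {
    "first": 1, "second": 2, "third": 3, "fourth": 4, "fifth": 5,
    "sixth": 6, "seventh": 7, "eighth": 8, "ninth": 9, "tenth": 10,
    "eleventh": 11, "twelfth": 12,
}

_TOKEN_RE = re.compile(r"\d+\.\d+|\d+|[A-Za-z]+|[^\sA-Za-z\d]")


@dataclass(frozen=True)
class NumberSpan:
    """One detected number expression in the original text."""

    start: int
    end: int
    value: Fraction
    surface: str
    ordinal: bool = False


@dataclass
class OffsetMap:
    """Monotone correspondence between original and normalized positions.

    Built from the list of replaced segments; positions outside replaced
    segments map bijectively, positions inside map monotonically (clamped
    to the replacement's extent).
    """

    # (orig_start, orig_end, norm_start, norm_end) per replacement, sorted
    segments: list[tuple[int, int, int, int]] = field(default_factory=list)

    def _map(self, pos: int, forward: bool) -> int:
        a, b = (0, 2) if forward else (2, 0)
        shift = 0
        for seg in self.segments:
            src_start, src_end = seg[a], seg[a + 1]
            dst_start, dst_end = seg[b], seg[b + 1]
            if pos <= src_start:
                break
            if pos < src_end:
                return min(dst_start + (pos - src_start), dst_end)
            shift = dst_end - src_end
        return pos + shift

    def to_normalized(self, pos: int) -> int:
        return self._map(pos, forward=True)

    def to_original(self, pos: int) -> int:
        return self._map(pos, forward=False)

    def span_to_normalized(self, start: int, end: int) -> tuple[int, int]:
        return self.to_normalized(start), self.to_normalized(end)

    def span_to_original(self, start: int, end: int) -> tuple[int, int]:
        return self.to_original(start), self.to_original(end)


@dataclass
class NormalizedText:
    """Result of canonicalization: rewritten text plus the offset map."""

    text: str
    offset_map: OffsetMap
    numbers: list[NumberSpan]
    original: str = ""


def _tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _adjacent(tokens, i: int, j: int) -> bool:
    """True if tokens i..j are contiguous (no intervening characters)."""
    return all(tokens[k][2] == tokens[k + 1][1] for k in range(i, j))


def _parse_word_number(tokens, i: int) -> Optional[tuple[Fraction, int]]:
    """Parse an additive/multiplicative word number starting at token i.

    Grammar: [unit] "hundred" ["and"] [tens-part] | tens-part | teens | unit,
    where tens-part is tens [["-"] unit].  Returns (value, next_index).
    """
    n = len(tokens)
    word = tokens[i][0].lower()

    def tens_part(k):
        w = tokens[k][0].lower()
        if w in _TENS:
            val = Fraction(_TENS[w])
            k += 1
            # optional hyphen between tens and unit ("twenty-one")
            j = k
            if j < n and tokens[j][0] == "-" and _adjacent(tokens, j - 1, j):
                j += 1
                if j < n and tokens[j][0].lower() in _UNITS and _adjacent(tokens, j - 1, j):
                    return val + _UNITS[tokens[j][0].lower()], j + 1
            if k < n and tokens[k][0].lower() in _UNITS and _UNITS[tokens[k][0].lower()] > 0:
                return val + _UNITS[tokens[k][0].lower()], k + 1
            return val, k
        if w in _TEENS:
            return Fraction(_TEENS[w]), k + 1
        if w in _UNITS:
            return Fraction(_UNITS[w]), k + 1
        return None

    # hundreds: "one hundred (and) twenty one", "a hundred"
    if word in _UNITS or word == "a":
        mult = Fraction(_UNITS.get(word, 1))
        if i + 1 < n and tokens[i + 1][0].lower() == "hundred":
            val = mult * 100
            k = i + 2
            if k < n and tokens[k][0].lower() == "and":
                rest = tens_part(k + 1)
                if rest is not None:
                    return val + rest[0], rest[1]
            rest = tens_part(k) if k < n else None
            if rest is not None:
                return val + rest[0], rest[1]
            return val, k
        if word == "a":
            return None
    return tens_part(i)


def _parse_at(text: str, tokens, i: int) -> Optional[tuple[Fraction, int, bool]]:
    """Longest number expression starting at token i.

    Returns (value, next_token_index, ordinal_flag) or None.
    """
    n = len(tokens)
    tok, start, end = tokens[i]
    low = tok.lower()

    base: Optional[Fraction] = None
    j = i

    if re.fullmatch(r"\d+\.\d+", tok):
        base, j = Fraction(tok), i + 1
    elif tok.isdigit():
        base, j = Fraction(int(tok)), i + 1
        # "1/2" (contiguous) — a literal fraction
        if (j + 1 < n and tokens[j][0] == "/" and tokens[j + 1][0].isdigit()
                and _adjacent(tokens, i, j + 1) and int(tokens[j + 1][0]) != 0):
            base = base / int(tokens[j + 1][0])
            j += 2
        # mixed "2 1/2": integer then a separate contiguous fraction
        elif (j + 2 < n and tokens[j][0].isdigit() and tokens[j + 1][0] == "/"
              and tokens[j + 2][0].isdigit() and _adjacent(tokens, j, j + 2)
              and int(tokens[j + 2][0]) != 0):
            base = base + Fraction(int(tokens[j][0]), int(tokens[j + 2][0]))
            j += 3
    elif low in _ORDINALS:
        return Fraction(_ORDINALS[low]), i + 1, True
    elif low in _FRACTION_WORDS:
        base, j = _FRACTION_WORDS[low], i + 1
    else:
        parsed = _parse_word_number(tokens, i)
        if parsed is not None:
            base, j = parsed

    if base is None:
        return None

    # "... and a half" / "... and one quarter"
    if (j + 2 < n and tokens[j][0].lower() == "and"
            and tokens[j + 1][0].lower() in ("a", "one")
            and tokens[j + 2][0].lower() in _FRACTION_WORDS):
        base = base + _FRACTION_WORDS[tokens[j + 2][0].lower()]
        j += 3
    return base, j, False


def find_number_expressions(text: str) -> list[NumberSpan]:
    """Detect number expressions left-to-right, longest match first.

    Spans are non-overlapping.  Digit ranges ("2-3") appear as two spans
    because the hyphen is not part of either number.
    """
    tokens = _tokenize(text)
    spans: list[NumberSpan] = []
    i = 0
    while i < len(tokens):
        parsed = _parse_at(text, tokens, i)
        if parsed is None:
            i += 1
            continue
        value, j, ordinal = parsed
        start, end = tokens[i][1], tokens[j - 1][2]
        spans.append(NumberSpan(start, end, value, text[start:end], ordinal))
        i = j
    return spans


def render_decimal(value: Fraction) -> str:
    """Canonical base-10 rendering: integers bare, else ≤3 decimal places."""
    value = Fraction(value)
    if value.denominator == 1:
        return str(value.numerator)
    s = f"{float(value):.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def parse_number(text: str) -> Optional[Fraction]:
    """Parse a string that is exactly one number expression, else None."""
    spans = find_number_expressions(text)
    if len(spans) == 1 and spans[0].start == 0 and spans[0].end == len(text.rstrip()):
        return spans[0].value
    if len(spans) == 1 and spans[0].surface == text.strip():
        return spans[0].value
    return None


def canonicalize(text: str) -> NormalizedText:
    """Rewrite every non-ordinal number expression to its canonical decimal.

    All other characters are preserved byte-identically; the returned
    offset map relates original and rewritten positions.  Idempotent:
    canonical text is a fixed point.
    """
    spans = find_number_expressions(text)
    out: list[str] = []
    segments: list[tuple[int, int, int, int]] = []
    pos = 0
    new_pos = 0
    for sp in spans:
        if sp.ordinal:
            continue
        rendering = render_decimal(sp.value)
        out.append(text[pos:sp.start])
        new_pos += sp.start - pos
        out.append(rendering)
        segments.append((sp.start, sp.end, new_pos, new_pos + len(rendering)))
        new_pos += len(rendering)
        pos = sp.end
    out.append(text[pos:])
    return NormalizedText(
        text="".join(out),
        offset_map=OffsetMap(segments=segments),
        numbers=spans,
        original=text,
    )
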