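"""Compare normalized sig annotations against structured record fields.

A prescription record carries both pharmacist-entered structured fields
and the free-text directions; once the directions are annotated and
normalized, the two representations describe the same regimen twice and
can be cross-checked.  Each comparable field is matched against the
attribute(s) of its corresponding tag:

====================  =======================================
structured field      text-derived value
====================  =======================================
Take                  TAKE.amount
Frequency             FREQ attribute map (codes like TID are
                      expanded through the idiom lexicon)
Route                 ROUTE.route (surfaces alias-folded)
Duration (+units)     DURATION.num (+DURATION_UNIT.unit)
Dispense Quantity     DISPENSE.quantity
PRN                   presence of a PRN tag
PRN Reason            INDICATION span text
Form                  DOSEFORM.form (surfaces alias-folded)
====================  =======================================

Equal values produce no finding; unequal values a ``mismatch``; a value
present on only one side a ``missing_in_structured`` or
``missing_in_text`` finding.  Numeric comparison is exact after decimal
canonicalization — prescription quantities are discrete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .io import PrescriptionRecord, SigDocument
from .lexicon import UNIT_WORDS, fold_form, fold_route, freq_code_to_attrs
from .numbers import parse_number
from .schema import TagInstance

__all__ = ["Finding", "DiscrepancyReport", "compare_record"]

MISMATCH = "mismatch"
MISSING_IN_TEXT = "missing_in_text"
MISSING_IN_STRUCTURED = "missing_in_structured"


@dataclass(frozen=True)
class Finding:
    """One discrepancy between a structured field and the sig text."""

    field: str
    structured_value: str
    text_value: str
    severity: str  # mismatch | missing_in_text | missing_in_structured
    spans: tuple[tuple[int, int], ...] = ()

    def to_dict(self) -> dict:
        return {
            "field": self.field,
            "structured": self.structured_value,
            "text": self.text_value,
            "severity": self.severity,
            "spans": [list(s) for s in self.spans],
        }


@dataclass
class DiscrepancyReport:
    record_id: str
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def mismatches(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == MISMATCH]

    def to_dict(self) -> dict:
        return {"record_id": self.record_id,
                "findings": [f.to_dict() for f in self.findings]}


def _num_or_none(text: str) -> Optional[Fraction]:
    text = text.strip()
    if not text:
        return None
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError):
        return parse_number(text)


def _attr_num(value) -> Optional[Fraction]:
    if value is None:
        return None
    return Fraction(str(value))


def _spans(*tags: Optional[TagInstance]) -> tuple[tuple[int, int], ...]:
    return tuple(t.span() for t in tags if t is not None)


def _first(doc: SigDocument, label: str) -> Optional[TagInstance]:
    tags = doc.tags_with_label(label)
    return tags[0] if tags else None


def _truthy_flag(value: str) -> Optional[bool]:
    value = value.strip().lower()
    if not value:
        return None
    return value in ("1", "true", "yes", "y")


def compare_record(record: PrescriptionRecord,
                   doc: SigDocument) -> DiscrepancyReport:
    """Field-by-field comparison of a record with its annotated sig.

    ``doc`` must hold the record's directions text with normalized tag
    attributes; a text mismatch raises ValueError.
    """
    if record.directions != doc.text:
        raise ValueError(
            f"record {record.id!r}: directions do not match document text")
    report = DiscrepancyReport(record_id=record.id)

    def finding(fld: str, structured: str, text_value: str, severity: str,
                spans: tuple[tuple[int, int], ...] = ()) -> None:
        report.findings.append(
            Finding(fld, structured, text_value, severity, spans))

    def compare_numeric(fld: str, structured_raw: str, label: str,
                        attr: str) -> None:
        structured = _num_or_none(structured_raw)
        tag = _first(doc, label)
        text_num = _attr_num(tag.get(attr)) if tag is not None else None
        if structured is None and text_num is None:
            return
        if text_num is None:
            finding(fld, structured_raw, "", MISSING_IN_TEXT)
        elif structured is None:
            finding(fld, "", str(text_num), MISSING_IN_STRUCTURED,
                    _spans(tag))
        elif structured != text_num:
            finding(fld, structured_raw, str(_attr_num(tag.get(attr))),
                    MISMATCH, _spans(tag))

    # Take ↔ TAKE.amount; Dispense Quantity ↔ DISPENSE.quantity
    compare_numeric("Take", record.take, "TAKE", "amount")
    compare_numeric("Dispense Quantity", record.dispense_quantity,
                    "DISPENSE", "quantity")

    # Frequency ↔ FREQ attribute map, through the idiom lexicon
    freq_tag = _first(doc, "FREQ")
    structured_freq = (freq_code_to_attrs(record.frequency)
                       if record.frequency.strip() else None)
    if record.frequency.strip() and structured_freq is None:
        structured_freq = None  # unparseable code: treat as absent
    if structured_freq is not None or freq_tag is not None:
        if freq_tag is None:
            report.findings.append(Finding(
                "Frequency", record.frequency, "", MISSING_IN_TEXT))
        elif structured_freq is None:
            report.findings.append(Finding(
                "Frequency", record.frequency, doc.text[freq_tag.start:freq_tag.end],
                MISSING_IN_STRUCTURED, _spans(freq_tag)))
        else:
            keys = ("times_per", "to_times_per", "every", "to_every", "unit")

            def norm(v):
                if v is None or isinstance(v, str):
                    return v
                return Fraction(str(v))

            if any(norm(structured_freq.get(k)) != norm(freq_tag.get(k))
                   for k in keys):
                report.findings.append(Finding(
                    "Frequency", record.frequency,
                    doc.text[freq_tag.start:freq_tag.end], MISMATCH,
                    _spans(freq_tag)))

    # Route ↔ ROUTE.route with alias folding on both sides
    route_tag = _first(doc, "ROUTE")
    structured_route = (fold_route(record.route) or record.route.strip().lower()
                        if record.route.strip() else None)
    text_route = route_tag.get("route") if route_tag is not None else None
    if structured_route is not None or text_route is not None:
        if text_route is None:
            finding("Route", record.route, "", MISSING_IN_TEXT)
        elif structured_route is None:
            finding("Route", "", str(text_route), MISSING_IN_STRUCTURED,
                    _spans(route_tag))
        elif structured_route != text_route:
            finding("Route", record.route, str(text_route), MISMATCH,
                    _spans(route_tag))

    # Duration (+ units)
    compare_numeric("Duration", record.duration, "DURATION", "num")
    unit_tag = _first(doc, "DURATION_UNIT")
    structured_unit = record.duration_units.strip()
    folded_structured = (
        UNIT_WORDS.get(structured_unit.lower().rstrip("(s)").strip())
        or UNIT_WORDS.get(structured_unit.lower())
        or (structured_unit.lower() or None))
    text_unit = unit_tag.get("unit") if unit_tag is not None else None
    if folded_structured is not None or text_unit is not None:
        if text_unit is None:
            finding("Duration Units", record.duration_units, "",
                    MISSING_IN_TEXT)
        elif folded_structured is None:
            finding("Duration Units", "", str(text_unit),
                    MISSING_IN_STRUCTURED, _spans(unit_tag))
        elif folded_structured != text_unit:
            finding("Duration Units", record.duration_units, str(text_unit),
                    MISMATCH, _spans(unit_tag))

    # PRN flag ↔ PRN tag presence; PRN Reason ↔ INDICATION span text
    prn_flag = _truthy_flag(record.prn)
    prn_tag = _first(doc, "PRN")
    if prn_flag and prn_tag is None:
        finding("PRN", record.prn, "", MISSING_IN_TEXT)
    elif prn_flag is None and prn_tag is not None:
        finding("PRN", "", "as needed", MISSING_IN_STRUCTURED,
                _spans(prn_tag))
    elif prn_flag is False and prn_tag is not None:
        finding("PRN", record.prn, "as needed", MISMATCH, _spans(prn_tag))

    ind_tag = _first(doc, "INDICATION")
    structured_reason = record.prn_reason.strip().lower() or None
    text_reason = (doc.text[ind_tag.start:ind_tag.end].strip().lower()
                   if ind_tag is not None else None)
    if structured_reason is not None or text_reason is not None:
        if text_reason is None:
            finding("PRN Reason", record.prn_reason, "", MISSING_IN_TEXT)
        elif structured_reason is None:
            finding("PRN Reason", "", text_reason, MISSING_IN_STRUCTURED,
                    _spans(ind_tag))
        elif structured_reason != text_reason:
            finding("PRN Reason", record.prn_reason, text_reason, MISMATCH,
                    _spans(ind_tag))

    # Form ↔ DOSEFORM.form with alias folding
    form_tag = _first(doc, "DOSEFORM")
    structured_form = (fold_form(record.form) or record.form.strip().lower()
                       if record.form.strip() else None)
    text_form = form_tag.get("form") if form_tag is not None else None
    if structured_form is not None or text_form is not None:
        if text_form is None:
            finding("Form", record.form, "", MISSING_IN_TEXT)
        elif structured_form is None:
            finding("Form", "", str(text_form), MISSING_IN_STRUCTURED,
                    _spans(form_tag))
        elif structured_form != text_form:
            finding("Form", record.form, str(text_form), MISMATCH,
                    _spans(form_tag))

    return report
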