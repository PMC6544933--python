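"""Reading and writing sig documents, records, and export formats.

Formats handled here:

* **Standoff JSON** — one document as ``{"doc_id", "text", "source",
  "annotator_id", "tags": [{"label", "start", "end", "attributes"}]}``;
  null-valued attributes are omitted on write.  Corpora are JSON Lines,
  one document per line.
* **Record tables** — comma- or tab-delimited files whose header carries
  the structured prescription fields (ID, Medication, Route, Dose, ...,
  Directions); the delimiter is auto-detected from the header line.
* **Inline XML** — a human-inspectable view with tags rendered as inline
  elements; stripping the elements recovers the text exactly.
* **FHIR-Dosage-shaped JSON** — the regimen mapped onto the field layout
  of a FHIR Dosage (dose, frequency/period/periodUnit, route, asNeeded,
  timing), with strength/dispense data in an ``extensions`` block since
  they live outside Dosage in FHIR proper.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union
from xml.sax.saxutils import escape, quoteattr

from .numbers import render_decimal
from .schema import (
    ATTRIBUTE_ALIASES,
    SchemaRegistry,
    TagInstance,
    load_schema,
    validate_tag,
)

__all__ = [
    "SigDocument",
    "PrescriptionRecord",
    "FhirDosage",
    "ParseError",
    "ConflictError",
    "read_standoff",
    "write_standoff",
    "read_corpus",
    "write_corpus",
    "read_records",
    "write_records",
    "export_inline_xml",
    "to_fhir_dosage",
]


class ParseError(ValueError):
    """Malformed standoff file, unknown label, or out-of-range span."""


class ConflictError(ValueError):
    """Multiple tags map to the same FHIR field with conflicting values."""


@dataclass
class SigDocument:
    """A sig text with its standoff annotations and provenance."""

    doc_id: str
    text: str
    tags: list[TagInstance] = field(default_factory=list)
    source: str = "human"  # human | model | synthetic
    annotator_id: Optional[str] = None

    def tags_with_label(self, label: str) -> list[TagInstance]:
        return [t for t in self.tags if t.label == label]


# Table-style structured prescription fields.  All default to empty; the
# directions string is the only field the tagger consumes.
@dataclass
class PrescriptionRecord:
    id: str = ""
    medication: str = ""
    route: str = ""
    dose: str = ""
    dose_units: str = ""
    strength: str = ""
    take: str = ""
    form: str = ""
    frequency: str = ""
    prn: str = ""
    prn_reason: str = ""
    duration: str = ""
    duration_units: str = ""
    dispense_quantity: str = ""
    dispense_quantity_units: str = ""
    directions: str = ""


_RECORD_FIELDS = {
    "id": "id",
    "medication": "medication",
    "route": "route",
    "dose": "dose",
    "doseunits": "dose_units",
    "strength": "strength",
    "take": "take",
    "form": "form",
    "frequency": "frequency",
    "prn": "prn",
    "prnreason": "prn_reason",
    "duration": "duration",
    "durationunits": "duration_units",
    "dispensequantity": "dispense_quantity",
    "dispensequantityunits": "dispense_quantity_units",
    "directions": "directions",
}

_RECORD_HEADER = [
    "ID", "Medication", "Route", "Dose", "Dose Units", "Strength", "Take",
    "Form", "Frequency", "PRN", "PRN Reason", "Duration", "Duration Units",
    "Dispense Quantity", "Dispense Quantity Units", "Directions",
]


def _attr_value_to_json(value: Any) -> Any:
    if isinstance(value, Fraction):
        return int(value) if value.denominator == 1 else float(value)
    return value


def doc_to_dict(doc: SigDocument) -> dict[str, Any]:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "source": doc.source,
        "annotator_id": doc.annotator_id,
        "tags": [
            {
                "label": t.label,
                "start": t.start,
                "end": t.end,
                "attributes": {
                    k: _attr_value_to_json(v)
                    for k, v in t.attributes.items() if v is not None
                },
            }
            for t in doc.tags
        ],
    }


def doc_from_dict(data: dict[str, Any],
                  registry: Optional[SchemaRegistry] = None) -> SigDocument:
    registry = registry or load_schema()
    try:
        text = data["text"]
        tags = []
        for i, td in enumerate(data.get("tags", [])):
            attrs = {
                ATTRIBUTE_ALIASES.get(k, k): v
                for k, v in td.get("attributes", {}).items()
            }
            tags.append(TagInstance(td["label"], td["start"], td["end"], attrs))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed standoff document: {exc}") from exc
    doc = SigDocument(
        doc_id=str(data.get("doc_id", "")),
        text=text,
        tags=tags,
        source=data.get("source", "human"),
        annotator_id=data.get("annotator_id"),
    )
    for i, tag in enumerate(doc.tags):
        violations = validate_tag(tag, len(text), registry)
        if violations:
            raise ParseError(
                f"tag {i} ({tag.label} [{tag.start},{tag.end})) invalid: "
                + "; ".join(v.message for v in violations))
    return doc


def read_standoff(path: Union[str, Path],
                  registry: Optional[SchemaRegistry] = None) -> SigDocument:
    """Read one standoff JSON document, validating against the registry."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON in {path}: {exc}") from exc
    return doc_from_dict(data, registry)


def write_standoff(doc: SigDocument, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(doc_to_dict(doc), ensure_ascii=False, indent=1),
        encoding="utf-8")


def read_corpus(path: Union[str, Path],
                registry: Optional[SchemaRegistry] = None) -> list[SigDocument]:
    """Read a JSON Lines corpus (one standoff document per line)."""
    registry = registry or load_schema()
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(doc_from_dict(json.loads(line), registry))
    return docs


def write_corpus(docs: Iterable[SigDocument], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc_to_dict(doc), ensure_ascii=False) + "\n")


def _normalize_header(name: str) -> str:
    return re.sub(r"[\s_]+", "", name.strip().lower())


def read_records(path: Union[str, Path],
                 dialect: Optional[str] = None) -> list[PrescriptionRecord]:
    """Read a delimited prescription-record table.

    The delimiter is taken from ``dialect`` ("csv"/"tsv") or auto-detected
    from the header line.  Header names are matched case-insensitively with
    spaces/underscores ignored.  A table without a Directions column is
    rejected — there would be nothing to annotate.
    """
    raw = Path(path).read_text(encoding="utf-8")
    if dialect == "csv":
        delim = ","
    elif dialect == "tsv":
        delim = "\t"
    else:
        header_line = raw.splitlines()[0] if raw.splitlines() else ""
        delim = "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","
    reader = csv.reader(_stdio.StringIO(raw), delimiter=delim)
    rows = list(reader)
    if not rows:
        raise ParseError(f"empty record table: {path}")
    header = [_normalize_header(h) for h in rows[0]]
    mapping = [(_RECORD_FIELDS.get(h), idx) for idx, h in enumerate(header)]
    if not any(fld == "directions" for fld, _ in mapping):
        raise ParseError("record table has no Directions column")
    records = []
    for row in rows[1:]:
        if not any(cell.strip() for cell in row):
            continue
        rec = PrescriptionRecord()
        for fld, idx in mapping:
            if fld is not None and idx < len(row):
                setattr(rec, fld, row[idx].strip())
        records.append(rec)
    return records


def write_records(records: Sequence[PrescriptionRecord],
                  path: Union[str, Path], dialect: str = "csv") -> None:
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(_RECORD_HEADER)
        for rec in records:
            writer.writerow([
                rec.id, rec.medication, rec.route, rec.dose, rec.dose_units,
                rec.strength, rec.take, rec.form, rec.frequency, rec.prn,
                rec.prn_reason, rec.duration, rec.duration_units,
                rec.dispense_quantity, rec.dispense_quantity_units,
                rec.directions,
            ])


class ExportError(ValueError):
    """Crossing (partially overlapping) spans cannot be rendered inline."""


def export_inline_xml(doc: SigDocument) -> str:
    """Render annotations as inline elements inside the text.

    Tags must be non-overlapping or properly nested; crossing spans raise
    ExportError naming the offending pair.  Stripping the elements from
    the output recovers ``doc.text`` exactly (text content is XML-escaped
    on write, so unescaping is part of stripping).
    """
    tags = sorted(enumerate(doc.tags), key=lambda it: (it[1].start, -it[1].end))
    for (i, a) in tags:
        for (j, b) in tags:
            if i < j and a.start < b.start < a.end < b.end:
                raise ExportError(
                    f"crossing spans: tag {i} ({a.label} [{a.start},{a.end})) and "
                    f"tag {j} ({b.label} [{b.start},{b.end}))")

    events: list[tuple[int, int, int, str]] = []  # (pos, order, idx, kind)
    for idx, (i, t) in enumerate(tags):
        def _render(v: Any) -> str:
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float, Fraction)):
                return render_decimal(Fraction(str(v)) if isinstance(v, float) else Fraction(v))
            return str(v)

        attrs = "".join(
            f" {k}={quoteattr(_render(v))}"
            for k, v in t.attributes.items() if v is not None
        )
        events.append((t.start, 1, idx, f"<{t.label}{attrs}>"))
        events.append((t.end, 0, -idx, f"</{t.label}>"))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    out = []
    pos = 0
    for p, _, _, markup in events:
        out.append(escape(doc.text[pos:p]))
        out.append(markup)
        pos = p
    out.append(escape(doc.text[pos:]))
    return "".join(out)


@dataclass
class FhirDosage:
    """A Dosage-shaped view of one normalized regimen document."""

    dose_quantity: Optional[float] = None
    dose_range: Optional[dict] = None  # {"low": x, "high": y}
    dose_unit: Optional[str] = None
    duration: Optional[float] = None
    duration_max: Optional[float] = None
    duration_unit: Optional[str] = None
    frequency: Optional[float] = None
    frequency_max: Optional[float] = None
    period: Optional[float] = None
    period_max: Optional[float] = None
    period_unit: Optional[str] = None
    as_needed: Optional[bool] = None
    as_needed_reason: Optional[str] = None
    route: Optional[str] = None
    timing_when: Optional[str] = None
    timing_offset: Optional[float] = None
    timing_offset_unit: Optional[str] = None
    additional_instructions: Optional[str] = None
    medication_text: Optional[str] = None
    extensions: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        camel = {
            "dose_quantity": "doseQuantity", "dose_range": "doseRange",
            "dose_unit": "doseUnit", "duration": "duration",
            "duration_max": "durationMax", "duration_unit": "durationUnit",
            "frequency": "frequency", "frequency_max": "frequencyMax",
            "period": "period", "period_max": "periodMax",
            "period_unit": "periodUnit", "as_needed": "asNeeded",
            "as_needed_reason": "asNeededReason", "route": "route",
            "timing_when": "timingWhen", "timing_offset": "timingOffset",
            "timing_offset_unit": "timingOffsetUnit",
            "additional_instructions": "additionalInstructions",
            "medication_text": "medicationText",
        }
        for attr, key in camel.items():
            value = getattr(self, attr)
            if value is not None:
                out[key] = value
        if self.extensions:
            out["extensions"] = self.extensions
        return out


def _num(value: Any) -> Optional[float]:
    if value is None:
        return None
    f = float(value)
    return int(f) if f == int(f) else f


def _single(doc: SigDocument, label: str, keys: Sequence[str]) -> Optional[TagInstance]:
    """The unique tag with this label, tolerating exact duplicates."""
    tags = doc.tags_with_label(label)
    if not tags:
        return None
    first = tags[0]
    for other in tags[1:]:
        if any(other.get(k) != first.get(k) for k in keys):
            spans = ", ".join(f"[{t.start},{t.end})" for t in tags)
            raise ConflictError(
                f"conflicting {label} tags at spans {spans}")
    return first


def to_fhir_dosage(doc: SigDocument) -> FhirDosage:
    """Map a normalized document onto the FHIR Dosage field layout.

    Dose comes from TAKE (count of dose units, unit from DOSEFORM) or
    DOSEAMOUNT (mass of active ingredient, unit from DOSEAMOUNT_UNIT);
    FREQ populates frequency/period, with the Max variants present only
    when the source attributes carry a range; PRN and INDICATION become
    the as-needed flag and reason; TIMING becomes when/offset.  Strength
    and dispense tags, which have no Dosage home, go to ``extensions``.
    """
    dosage = FhirDosage()

    take = _single(doc, "TAKE", ("amount", "to_amount"))
    doseamount = _single(doc, "DOSEAMOUNT", ("amount", "to_amount"))
    dose_tag = take if take is not None else doseamount
    if dose_tag is not None:
        lo, hi = _num(dose_tag.get("amount")), _num(dose_tag.get("to_amount"))
        if hi is not None:
            dosage.dose_range = {"low": lo, "high": hi}
        else:
            dosage.dose_quantity = lo
        if take is not None:
            form = _single(doc, "DOSEFORM", ("form",))
            if form is not None:
                dosage.dose_unit = form.get("form")
        else:
            unit = _single(doc, "DOSEAMOUNT_UNIT", ("unit",))
            if unit is not None:
                dosage.dose_unit = unit.get("unit")

    dur = _single(doc, "DURATION", ("num", "to_num"))
    if dur is not None:
        dosage.duration = _num(dur.get("num"))
        dosage.duration_max = _num(dur.get("to_num"))
    dur_unit = _single(doc, "DURATION_UNIT", ("unit",))
    if dur_unit is not None:
        dosage.duration_unit = dur_unit.get("unit")

    freq = _single(doc, "FREQ", ("times_per", "to_times_per", "every",
                                 "to_every", "unit"))
    if freq is not None:
        dosage.frequency = _num(freq.get("times_per"))
        dosage.frequency_max = _num(freq.get("to_times_per"))
        dosage.period = _num(freq.get("every"))
        dosage.period_max = _num(freq.get("to_every"))
        dosage.period_unit = freq.get("unit")

    if doc.tags_with_label("PRN"):
        dosage.as_needed = True
    indications = doc.tags_with_label("INDICATION")
    if indications:
        dosage.as_needed_reason = "; ".join(
            doc.text[t.start:t.end] for t in indications)

    route = _single(doc, "ROUTE", ("route", "side"))
    if route is not None:
        dosage.route = route.get("route") or doc.text[route.start:route.end]

    timing = _single(doc, "TIMING", ("offset", "to_offset", "offset_unit",
                                     "direction", "event"))
    if timing is not None:
        event, direction = timing.get("event"), timing.get("direction")
        if event is not None:
            dosage.timing_when = (
                f"{direction} {event}" if direction in ("before", "after")
                else str(event))
        dosage.timing_offset = _num(timing.get("offset"))
        dosage.timing_offset_unit = timing.get("offset_unit")

    meds = doc.tags_with_label("MEDICATION")
    if meds:
        tag = meds[0]
        dosage.medication_text = tag.get("name") or doc.text[tag.start:tag.end]

    notes = doc.tags_with_label("INSTRUCTION")
    if notes:
        dosage.additional_instructions = "; ".join(
            t.get("note") or doc.text[t.start:t.end] for t in notes)

    ext: dict[str, Any] = {}
    strength = _single(doc, "STRENGTH", ("amount", "to_amount"))
    if strength is not None:
        ext["strength"] = _num(strength.get("amount"))
    strength_unit = _single(doc, "STRENGTH_UNIT", ("unit",))
    if strength_unit is not None:
        ext["strengthUnit"] = strength_unit.get("unit")
    dispense = _single(doc, "DISPENSE", ("quantity", "to_quantity"))
    if dispense is not None:
        ext["dispenseQuantity"] = _num(dispense.get("quantity"))
    dispense_unit = _single(doc, "DISPENSE_UNIT", ("unit",))
    if dispense_unit is not None:
        ext["dispenseUnit"] = dispense_unit.get("unit")
    refill = _single(doc, "REFILL", ("refill",))
    if refill is not None and refill.get("refill") is not None:
        ext["refillAllowed"] = bool(refill.get("refill"))
    subst = _single(doc, "SUB_STATUS", ("subst",))
    if subst is not None and subst.get("subst") is not None:
        ext["substitutionAllowed"] = bool(subst.get("subst"))
    dosage.extensions = ext
    return dosage
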