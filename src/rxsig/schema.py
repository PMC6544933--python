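"""Tag schema for prescription-direction ("sig") annotation.

The schema defines 19 concept labels covering the components of a
medication regimen (dose, frequency, route, duration, ...).  Each label
carries a set of typed attributes through which the meaning of a tagged
span is recorded in normalized form: numeric attributes hold non-negative
rationals, choice attributes draw from fixed value lists, boolean
attributes are flags, and free-text attributes hold arbitrary strings.
All attributes are nullable — a null value means "not stated in the text".

Character offsets throughout are 0-based, half-open, over Unicode code
points, the standard convention for standoff annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "AttributeSpec",
    "TagLabelSpec",
    "SchemaRegistry",
    "TagInstance",
    "Violation",
    "ValidationReport",
    "LABELS",
    "load_schema",
    "validate_tag",
    "validate_document",
]

NumericValue = Union[int, float, Fraction]
AttrValue = Union[NumericValue, str, bool, None]

#: The 19 concept labels, in canonical order.
LABELS = (
    "DISPENSE", "DISPENSE_UNIT", "MEDICATION", "TAKE", "STRENGTH",
    "STRENGTH_UNIT", "DOSEAMOUNT", "DOSEAMOUNT_UNIT", "DOSEFORM",
    "DURATION", "DURATION_UNIT", "FREQ", "TIMING", "PRN", "INDICATION",
    "ROUTE", "REFILL", "SUB_STATUS", "INSTRUCTION",
)

#: Time-unit list shared by DURATION_UNIT, FREQ.unit and TIMING.offset_unit.
TIME_UNITS = ("minute", "hour", "day", "week", "month", "other")

#: Read-time aliases for attribute names (abbreviated forms accepted on input).
ATTRIBUTE_ALIASES = {
    "amt": "amount",
    "to_amt": "to_amount",
}

# Curated default value lists for the attributes whose lists are
# deployment-configurable (they can be replaced wholesale via load_schema).
_DEFAULT_FORMS = (
    "tablet", "capsule", "puff", "drop", "patch", "spray",
    "suppository", "ml", "application", "other",
)
_DEFAULT_ROUTES = (
    "oral", "topical", "subcutaneous", "intramuscular", "intravenous",
    "inhaled", "rectal", "vaginal", "ophthalmic", "otic", "nasal",
    "transdermal", "sublingual", "other",
)
_DEFAULT_UNITS = (
    "tablet", "capsule", "mg", "mcg", "g", "ml", "unit", "puff",
    "drop", "other",
)


@dataclass(frozen=True)
class AttributeSpec:
    """Specification of a single attribute of a tag label."""

    name: str
    kind: str  # numeric | choice | free_text | boolean
    allowed_values: tuple[str, ...] = ()
    configurable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "choice", "free_text", "boolean"):
            raise ValueError(f"unknown attribute kind: {self.kind!r}")

    def check(self, value: AttrValue) -> Optional[str]:
        """Return a violation message for ``value``, or None if valid.

        Null (None) is always acceptable: every attribute is nullable.
        """
        if value is None:
            return None
        if self.kind == "numeric":
            if isinstance(value, bool) or not isinstance(value, (int, float, Rational)):
                return f"attribute {self.name!r} expects a number, got {value!r}"
            if value < 0:
                return f"attribute {self.name!r} must be non-negative, got {value!r}"
        elif self.kind == "choice":
            if value not in self.allowed_values:
                return (
                    f"attribute {self.name!r} value {value!r} not in allowed "
                    f"values {list(self.allowed_values)}"
                )
        elif self.kind == "boolean":
            if not isinstance(value, bool):
                return f"attribute {self.name!r} expects a boolean, got {value!r}"
        else:  # free_text
            if not isinstance(value, str):
                return f"attribute {self.name!r} expects a string, got {value!r}"
        return None


@dataclass(frozen=True)
class TagLabelSpec:
    """One of the 19 tag labels together with its attribute framework."""

    label: str
    attributes: tuple[AttributeSpec, ...]
    description: str = ""

    def attribute(self, name: str) -> Optional[AttributeSpec]:
        name = ATTRIBUTE_ALIASES.get(name, name)
        for spec in self.attributes:
            if spec.name == name:
                return spec
        return None

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)


@dataclass
class TagInstance:
    """A single annotation: a label applied to a character span.

    ``attributes`` maps attribute names to normalized values; keys whose
    value is None are equivalent to absent keys.
    """

    label: str
    start: int
    end: int
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def get(self, name: str, default: AttrValue = None) -> AttrValue:
        return self.attributes.get(name, default)


@dataclass(frozen=True)
class Violation:
    """A single constraint violation found while validating a tag."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.field}/{self.rule}] {self.message}"


@dataclass
class ValidationReport:
    """Aggregate validation result for a document."""

    violations: list[tuple[int, Violation]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def _time_unit_attr(name: str = "unit") -> AttributeSpec:
    return AttributeSpec(name, "choice", TIME_UNITS)


def _numeric_pair(base: str) -> tuple[AttributeSpec, AttributeSpec]:
    return (AttributeSpec(base, "numeric"), AttributeSpec(f"to_{base}", "numeric"))


def _default_specs() -> dict[str, TagLabelSpec]:
    specs = {
        "DISPENSE": TagLabelSpec(
            "DISPENSE", _numeric_pair("quantity"),
            "Quantity of medication to be issued by the pharmacist."),
        "DISPENSE_UNIT": TagLabelSpec(
            "DISPENSE_UNIT",
            (AttributeSpec("unit", "choice", _DEFAULT_UNITS, configurable=True),),
            "Unit of the dispensed quantity."),
        "MEDICATION": TagLabelSpec(
            "MEDICATION", (AttributeSpec("name", "free_text"),),
            "Text specifying a pharmaceutical product."),
        "TAKE": TagLabelSpec(
            "TAKE", _numeric_pair("amount"),
            "Quantity of medication per application, patient perspective."),
        "STRENGTH": TagLabelSpec(
            "STRENGTH", _numeric_pair("amount"),
            "Amount of active ingredient per physical quantity of medication."),
        "STRENGTH_UNIT": TagLabelSpec(
            "STRENGTH_UNIT",
            (AttributeSpec("unit", "choice", _DEFAULT_UNITS, configurable=True),),
            "Unit of the strength amount."),
        "DOSEAMOUNT": TagLabelSpec(
            "DOSEAMOUNT", _numeric_pair("amount"),
            "Amount of active ingredient per application of medication."),
        "DOSEAMOUNT_UNIT": TagLabelSpec(
            "DOSEAMOUNT_UNIT",
            (AttributeSpec("unit", "choice", _DEFAULT_UNITS, configurable=True),),
            "Unit of the dose amount."),
        "DOSEFORM": TagLabelSpec(
            "DOSEFORM",
            (AttributeSpec("form", "choice", _DEFAULT_FORMS, configurable=True),),
            "Physical form of the medication taken."),
        "DURATION": TagLabelSpec(
            "DURATION", _numeric_pair("num"),
            "Period of time a patient should continue using a medication."),
        "DURATION_UNIT": TagLabelSpec(
            "DURATION_UNIT", (_time_unit_attr(),),
            "Unit of the duration period."),
        "FREQ": TagLabelSpec(
            "FREQ",
            (*_numeric_pair("times_per"), *_numeric_pair("every"), _time_unit_attr()),
            "Frequency of use: N times per unit and/or every N units."),
        "TIMING": TagLabelSpec(
            "TIMING",
            (*_numeric_pair("offset"),
             _time_unit_attr("offset_unit"),
             AttributeSpec("direction", "choice", ("before", "after", "other")),
             AttributeSpec("event", "choice",
                           ("breakfast", "lunch", "dinner", "meals", "morning",
                            "noon", "afternoon", "evening", "bedtime",
                            "procedure", "treatment", "other"))),
            "Temporal alignment of doses with life events."),
        "PRN": TagLabelSpec(
            "PRN", (), "Medication to be taken only as needed."),
        "INDICATION": TagLabelSpec(
            "INDICATION", (), "Condition for which medication is taken."),
        "ROUTE": TagLabelSpec(
            "ROUTE",
            (AttributeSpec("route", "choice", _DEFAULT_ROUTES, configurable=True),
             AttributeSpec("side", "choice", ("left", "right", "both"))),
            "Manner or point of application to the body."),
        "REFILL": TagLabelSpec(
            "REFILL", (AttributeSpec("refill", "boolean"),),
            "Whether refills are allowed."),
        "SUB_STATUS": TagLabelSpec(
            "SUB_STATUS", (AttributeSpec("subst", "boolean"),),
            "Whether substitutions are allowed."),
        "INSTRUCTION": TagLabelSpec(
            "INSTRUCTION", (AttributeSpec("note", "free_text"),),
            "Patient actions not captured by another tag."),
    }
    return {label: specs[label] for label in LABELS}


@dataclass
class SchemaRegistry:
    """The full label inventory with per-label attribute specifications."""

    labels: dict[str, TagLabelSpec]
    version: str = "1.0"

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __getitem__(self, label: str) -> TagLabelSpec:
        return self.labels[label]

    def resolve_attribute(self, name: str) -> tuple[str, str]:
        """Resolve a bare attribute name to its unique (label, attribute) pair.

        Accepts the read-time aliases (amt → amount).  Raises KeyError if the
        name is unknown or ambiguous across labels in a way that cannot be
        resolved (names shared by several labels with identical specs resolve
        to the first label in canonical order).
        """
        name = ATTRIBUTE_ALIASES.get(name, name)
        hits = [(lbl, name) for lbl, spec in self.labels.items()
                if spec.attribute(name) is not None]
        if not hits:
            raise KeyError(f"unknown attribute name: {name!r}")
        return hits[0]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "labels": {
                lbl: {
                    "description": spec.description,
                    "attributes": [
                        {
                            "name": a.name,
                            "kind": a.kind,
                            "allowed_values": list(a.allowed_values),
                            "configurable": a.configurable,
                        }
                        for a in spec.attributes
                    ],
                }
                for lbl, spec in self.labels.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SchemaRegistry":
        labels = {}
        for lbl, entry in data["labels"].items():
            attrs = tuple(
                AttributeSpec(a["name"], a["kind"], tuple(a.get("allowed_values", ())),
                              a.get("configurable", False))
                for a in entry["attributes"]
            )
            labels[lbl] = TagLabelSpec(lbl, attrs, entry.get("description", ""))
        return cls(labels=labels, version=data.get("version", "1.0"))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SchemaRegistry":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


class SchemaConfigError(ValueError):
    """A value-list configuration named an unknown label or attribute."""


def load_schema(config: Optional[Union[Mapping[str, Mapping[str, Sequence[str]]], str, Path]] = None) -> SchemaRegistry:
    """Build the default 19-label registry, optionally merging value lists.

    Parameters
    ----------
    config
        Either a mapping ``{label: {attribute: [values...]}}`` replacing the
        allowed-value lists of *configurable* choice attributes, or a path to
        a YAML/JSON file holding such a mapping.

    Returns
    -------
    SchemaRegistry
        Deterministic: the same config always yields an identical registry.
    """
    specs = _default_specs()
    if config is None:
        return SchemaRegistry(labels=specs)
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
    for label, attrs in config.items():
        if label not in specs:
            raise SchemaConfigError(f"config names unknown label {label!r}")
        spec = specs[label]
        new_attrs = list(spec.attributes)
        for attr_name, values in attrs.items():
            aspec = spec.attribute(attr_name)
            if aspec is None:
                raise SchemaConfigError(
                    f"config names unknown attribute {label}.{attr_name}")
            if not aspec.configurable:
                raise SchemaConfigError(
                    f"attribute {label}.{attr_name} is not configurable")
            if not values:
                raise SchemaConfigError(
                    f"empty value list for {label}.{attr_name}")
            idx = new_attrs.index(aspec)
            new_attrs[idx] = AttributeSpec(
                aspec.name, aspec.kind, tuple(str(v) for v in values), True)
        specs[label] = TagLabelSpec(label, tuple(new_attrs), spec.description)
    return SchemaRegistry(labels=specs)


def validate_tag(tag: TagInstance, text_length: int,
                 registry: SchemaRegistry) -> list[Violation]:
    """Check one tag against span and attribute constraints.

    Returns a (possibly empty) list of violations; never raises for an
    invalid tag — validation results are data, not exceptions.
    """
    out: list[Violation] = []
    if tag.label not in registry:
        out.append(Violation("label", "known-label",
                             f"unknown label {tag.label!r}"))
        return out
    if not (0 <= tag.start < tag.end <= text_length):
        out.append(Violation(
            "span", "in-range",
            f"span [{tag.start},{tag.end}) invalid for text of length {text_length}"))
    spec = registry[tag.label]
    for key, value in tag.attributes.items():
        aspec = spec.attribute(key)
        if aspec is None:
            out.append(Violation(
                f"attributes.{key}", "known-attribute",
                f"label {tag.label} has no attribute {key!r}"))
            continue
        msg = aspec.check(value)
        if msg is not None:
            out.append(Violation(f"attributes.{key}", "value-type", msg))
    return out


def validate_document(doc: "SigDocument", registry: SchemaRegistry) -> ValidationReport:
    """Validate every tag of a document and collect overlap warnings.

    Overlapping spans with the same label are reported as warnings only —
    the schema permits a character to carry multiple labels.
    """
    report = ValidationReport()
    n = len(doc.text)
    for i, tag in enumerate(doc.tags):
        for v in validate_tag(tag, n, registry):
            report.violations.append((i, v))
    by_label: dict[str, list[tuple[int, TagInstance]]] = {}
    for i, tag in enumerate(doc.tags):
        by_label.setdefault(tag.label, []).append((i, tag))
    for label, tagged in by_label.items():
        tagged.sort(key=lambda it: (it[1].start, it[1].end))
        for (i, a), (j, b) in zip(tagged, tagged[1:]):
            if b.start < a.end:
                report.warnings.append(
                    f"overlapping {label} spans: tag {i} [{a.start},{a.end}) "
                    f"and tag {j} [{b.start},{b.end})")
    return report
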