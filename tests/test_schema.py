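"""Schema registry structure and tag validation."""

import pytest

from rxsig import LABELS, SigDocument, TagInstance, load_schema, validate_document, validate_tag
from rxsig.schema import SchemaConfigError, SchemaRegistry


def test_default_registry_has_19_labels(registry):
    assert len(registry.labels) == 19
    assert set(registry.labels) == set(LABELS)


def test_freq_has_exactly_five_attributes(registry):
    names = registry["FREQ"].attribute_names
    assert names == ("times_per", "to_times_per", "every", "to_every", "unit")


def test_span_only_labels_have_no_attributes(registry):
    assert registry["PRN"].attributes == ()
    assert registry["INDICATION"].attributes == ()


@pytest.mark.parametrize(
    "label, expected",
    [
        ("DISPENSE", ("quantity", "to_quantity")),
        ("TAKE", ("amount", "to_amount")),
        ("STRENGTH", ("amount", "to_amount")),
        ("DOSEAMOUNT", ("amount", "to_amount")),
        ("DURATION", ("num", "to_num")),
        ("DURATION_UNIT", ("unit",)),
        ("DOSEFORM", ("form",)),
        ("MEDICATION", ("name",)),
        ("ROUTE", ("route", "side")),
        ("TIMING", ("offset", "to_offset", "offset_unit", "direction", "event")),
        ("INSTRUCTION", ("note",)),
        ("REFILL", ("refill",)),
        ("SUB_STATUS", ("subst",)),
    ],
)
def test_attribute_layout(registry, label, expected):
    assert registry[label].attribute_names == expected


def test_time_unit_value_lists(registry):
    units = ("minute", "hour", "day", "week", "month", "other")
    assert registry["DURATION_UNIT"].attribute("unit").allowed_values == units
    assert registry["FREQ"].attribute("unit").allowed_values == units
    assert registry["TIMING"].attribute("offset_unit").allowed_values == units
    assert registry["TIMING"].attribute("direction").allowed_values == (
        "before", "after", "other")
    assert registry["ROUTE"].attribute("side").allowed_values == (
        "left", "right", "both")


def test_config_replaces_route_list():
    reg = load_schema({"ROUTE": {"route": ["oral", "topical", "other"]}})
    assert reg["ROUTE"].attribute("route").allowed_values == (
        "oral", "topical", "other")
    # non-configured attributes untouched
    assert reg["ROUTE"].attribute("side").allowed_values == (
        "left", "right", "both")


@pytest.mark.parametrize("config", [
    {"NOSUCH": {"x": ["a"]}},
    {"ROUTE": {"nosuch": ["a"]}},
    {"TIMING": {"direction": ["sideways"]}},  # not configurable
])
def test_bad_config_rejected(config):
    with pytest.raises(SchemaConfigError):
        load_schema(config)


def test_validate_tag_accepts_valid_freq(registry):
    tag = TagInstance("FREQ", 5, 22, {"unit": "day", "times_per": 2})
    assert validate_tag(tag, 30, registry) == []


def test_validate_tag_rejects_prn_attribute(registry):
    tag = TagInstance("PRN", 0, 9, {"reason": "pain"})
    violations = validate_tag(tag, 20, registry)
    assert len(violations) == 1
    assert "reason" in violations[0].field


def test_validate_tag_rejects_bad_choice_value(registry):
    tag = TagInstance("TIMING", 0, 6, {"direction": "during"})
    violations = validate_tag(tag, 10, registry)
    assert len(violations) == 1
    assert violations[0].field == "attributes.direction"


@pytest.mark.parametrize("start, end, length", [(-1, 3, 10), (3, 3, 10), (5, 12, 10)])
def test_validate_tag_rejects_bad_spans(registry, start, end, length):
    tag = TagInstance("TAKE", start, end)
    assert any(v.field == "span" for v in validate_tag(tag, length, registry))


def test_validate_tag_rejects_negative_numeric(registry):
    tag = TagInstance("TAKE", 0, 1, {"amount": -2})
    assert len(validate_tag(tag, 5, registry)) == 1


def test_validate_document_aggregates(registry):
    doc = SigDocument("d1", "take 2 tablets twice a day", tags=[
        TagInstance("REFILL", 0, 4, {"refill": "maybe"}),  # bad boolean
        TagInstance("FREQ", 15, 26, {"unit": "day", "times_per": 2}),
    ])
    report = validate_document(doc, registry)
    assert len(report.violations) == 1


def test_validate_document_empty_and_valid(registry):
    assert validate_document(SigDocument("d", "text"), registry).ok
    doc = SigDocument("d", "take 2 tablets",
                      tags=[TagInstance("TAKE", 5, 6, {"amount": 2})])
    assert validate_document(doc, registry).ok


def test_overlapping_same_label_spans_warn_not_error(registry):
    doc = SigDocument("d", "take 2 tablets", tags=[
        TagInstance("TAKE", 5, 6, {"amount": 2}),
        TagInstance("TAKE", 5, 14),
    ])
    report = validate_document(doc, registry)
    assert report.ok
    assert len(report.warnings) == 1


def test_registry_round_trip(tmp_path, registry):
    path = tmp_path / "schema.json"
    registry.save(path)
    assert SchemaRegistry.load(path) == registry


def test_every_reported_attribute_name_resolves(registry):
    # every attribute name used in per-attribute accuracy reporting,
    # including the short aliases, resolves to exactly one (label, attr)
    names = ["form", "route", "side", "unit", "every", "to_every",
             "times_per", "to_times_per", "direction", "event", "offset",
             "to_offset", "offset_unit", "amt", "amount", "to_amt",
             "to_amount", "num", "to_num", "quantity", "to_quantity",
             "refill", "subst"]
    for name in names:
        label, attr = registry.resolve_attribute(name)
        assert registry[label].attribute(attr) is not None
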