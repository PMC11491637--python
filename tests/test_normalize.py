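"""Address parsing, standardization rules, and rule-set validation."""

import pytest
from hypothesis import given, strategies as st

import commaddr as ca
from commaddr.errors import RuleSetError
from commaddr.normalize import Geocodability, validate_ruleset


@pytest.mark.parametrize(
    "street,zip_,cls",
    [
        ("po box 1234", "85999", Geocodability.PO_BOX),
        ("P.O. Box 99", "85999", Geocodability.PO_BOX),
        ("POB 7", "85999", Geocodability.PO_BOX),
        ("", "", Geocodability.BLANK),
        ("   ", "85999", Geocodability.BLANK),
        ("MESQUITE FLATS RD", "85999", Geocodability.NUMBERLESS),
        ("742 evergreen ter apt 3", "85999", Geocodability.GEOCODABLE),
        ("42 BOX ELDER RD", "85999", Geocodability.GEOCODABLE),  # BOX mid-name is not a PO box
    ],
)
def test_parse_geocodability(street, zip_, cls):
    assert ca.parse_address(street, zip_).geocodability is cls


def test_parse_structure():
    p = ca.parse_address("742 evergreen ter apt 3", "85999")
    assert p.street_number == 742
    assert p.street_name == "EVERGREEN TER"
    assert p.unit == "APT 3"
    assert p.zip == "85999"


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("85999", "85999"),
        ("85999-1234", "85999"),
        ("859991234", "85999"),
        ("8599", None),
        ("", None),
        ("TUCSON", None),
    ],
)
def test_zip_normalization(raw, expected):
    assert ca.parse_address("1 MAIN ST", raw).zip == expected


def test_parse_never_raises_on_junk():
    for junk in ["###", "?????", "12", "-", "#4", "ñ"]:
        ca.parse_address(junk, junk)  # degrade, never raise


def test_standardize_rule_application():
    rules = ca.RuleSet(rules=(ca.Rule(r"\bSTREEET\b", "ST"),))
    p = ca.parse_address("12 MAIN STREEET", "85999")
    assert ca.standardize(p, rules).street_name == "MAIN ST"


def test_standardize_historical_alias():
    rules = ca.RuleSet(rules=(ca.Rule(r"\bOLD AGENCY RD\b", "AGENCY LOOP"),))
    p = ca.parse_address("123 OLD AGENCY RD", "86544")
    assert ca.standardize(p, rules).street_name == "AGENCY LOOP"


def test_standardize_abbreviation_table_applied_last():
    p = ca.parse_address("5 NORTH MESQUITE FLATS ROAD", "86544")
    assert ca.standardize(p).street_name == "N MESQUITE FLATS RD"


def test_standardize_preserves_number_and_zip(small_reference):
    rules = small_reference.rule_set
    for raw in ["17 STAGE ONE RTE", "203 Mesquite Flats Road", "55 ELM GROVE PARK LN"]:
        p = ca.parse_address(raw, "86544")
        s = ca.standardize(p, rules)
        assert s.street_number == p.street_number
        assert s.zip == p.zip


@given(st.sampled_from([
    "12 MAIN STREET", "55 NORTH ELM GROVE ROAD", "7 STAGE ONE RTE",
    "100 MESQUITE FLATS RD", "1 OAK KNOLL DRIVE APT 2", "742 EVERGREEN TERRACE",
]))
def test_standardize_idempotent(small_reference, raw):
    p = ca.parse_address(raw, "86544")
    once = ca.standardize(p, small_reference.rule_set)
    twice = ca.standardize(once, small_reference.rule_set)
    assert once == twice


def test_non_terminating_rule_rejected_at_load():
    with pytest.raises(RuleSetError, match="reintroduces"):
        ca.RuleSet(rules=(ca.Rule(r"\bST\b", "ST ST"),))


def test_bad_pattern_rejected_at_load():
    with pytest.raises(RuleSetError, match="compile"):
        ca.RuleSet(rules=(ca.Rule(r"(", "X"),))


def test_ruleset_json_round_trip(tmp_path, small_reference):
    path = tmp_path / "rules.json"
    small_reference.rule_set.to_json(path)
    loaded = ca.RuleSet.from_json(path)
    assert loaded.rules == small_reference.rule_set.rules


class TestValidateRuleset:
    county = ["MESA VERDE DR", "MAPLE HILL DR", "OAK GROVE LN"]

    def test_rule_hitting_county_street_flagged(self):
        rules = ca.RuleSet(rules=(ca.Rule(r"\bMESA VERDE\b", "MESA GRANDE"),))
        report = validate_ruleset(rules, self.county, {"86544"})
        assert [(f.pattern, f.matched_street) for f in report.rule_flags] == [
            (r"\bMESA VERDE\b", "MESA VERDE DR")
        ]

    def test_empty_ruleset_empty_report(self):
        report = validate_ruleset(ca.RuleSet(), self.county, {"86544"})
        assert report.clean

    def test_rule_matching_only_community_street_not_flagged(self):
        """Exhaustive scan: a rule touching only the community street name
        produces no flags against the county inventory."""
        rules = ca.RuleSet(rules=(ca.Rule(r"\bSAGUARO WASH\b", "SAGUARO BASIN"),))
        report = validate_ruleset(rules, self.county, {"86544"})
        assert not report.rule_flags

    def test_rewrite_with_noncommunity_zip_queued_for_review(self):
        rules = ca.RuleSet(rules=(ca.Rule(r"\bOLD AGENCY RD\b", "AGENCY LOOP"),))
        inside = ca.parse_address("1 OLD AGENCY RD", "86544")
        outside = ca.parse_address("2 OLD AGENCY RD", "85701")
        report = validate_ruleset(rules, self.county, {"86544"}, [inside, outside])
        assert [a.zip for a in report.review_addresses] == ["85701"]


def test_geocodability_partition_is_conserved(noisy_extract):
    """Removed blank/PO-box/numberless records are exactly the complement
    of the geocoder input."""
    classes = [
        ca.parse_address(r.raw_street, r.raw_zip).geocodability for r in noisy_extract.records
    ]
    total = len(classes)
    counts = {c: classes.count(c) for c in Geocodability}
    assert sum(counts.values()) == total
    assert counts[Geocodability.GEOCODABLE] == total - (
        counts[Geocodability.BLANK] + counts[Geocodability.PO_BOX] + counts[Geocodability.NUMBERLESS]
    )
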