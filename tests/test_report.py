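"""Record taxonomy, jurisdiction summaries, and processing evaluation."""

import pytest

import commaddr as ca
from commaddr.errors import InputValidationError
from commaddr.report import JurisdictionReport, ProcessingEvalReport, RecordCategory


@pytest.mark.parametrize(
    "on_comm,affil,expected",
    [
        (True, True, RecordCategory.ON_COMMUNITY_WITH_AFFILIATION),
        (True, False, RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION),
        (False, True, RecordCategory.AFFILIATION_ONLY),
        (False, False, RecordCategory.UNRELATED),
    ],
)
def test_classify_record(on_comm, affil, expected):
    assert ca.classify_record(on_comm, affil) is expected


def test_po_box_with_affiliation_is_affiliation_only(small_reference):
    """An affiliated record whose address is a PO box cannot be an address
    match, so it lands in affiliation_only."""
    rec = ca.SurveillanceRecord("p1", "PO BOX 12", "86544", affiliation="Desert River Nation")
    res = ca.run_stages([rec], small_reference.points, keyword_set=small_reference.keywords)
    assert res.categories["p1"] is RecordCategory.AFFILIATION_ONLY


def test_round_half_up():
    assert ca.round_half_up(47.735) == 47.74
    assert ca.round_half_up(47.734) == 47.73
    assert ca.round_half_up(2.005) == 2.01
    assert ca.round_half_up(1.91499) == 1.91


def test_summarize_hand_enumerated_fixture():
    """4 on-community (2 affiliated) + 1 affiliation-only + 1 unrelated:
    jurisdiction total 5, ratio 4/2 = 2.00."""
    categories = {
        "a": RecordCategory.ON_COMMUNITY_WITH_AFFILIATION,
        "b": RecordCategory.ON_COMMUNITY_WITH_AFFILIATION,
        "c": RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION,
        "d": RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION,
        "e": RecordCategory.AFFILIATION_ONLY,
        "f": RecordCategory.UNRELATED,
    }
    aian = {k: k in {"a", "c", "e"} for k in categories}
    rep = ca.summarize(categories, aian)
    assert rep.on_community_total == 4
    assert rep.jurisdiction_total == 5
    assert rep.times_as_many_ratio == 2.00
    assert rep.pct_on_with_affiliation == 50.0
    assert rep.affiliation_total == 3
    assert rep.jurisdiction_with_aian == 3
    assert rep.total_records == 6


def test_summarize_zero_denominator_reports_not_applicable():
    rep = ca.summarize({"x": RecordCategory.UNRELATED}, {"x": False})
    assert rep.times_as_many_ratio is None
    assert rep.pct_on_with_affiliation is None


def test_percentage_partition_sums_to_100_within_rounding():
    rep = JurisdictionReport.from_counts(
        total_records=1000,
        on_with_affiliation=331,
        on_without_affiliation=271,
        on_with_aian=400,
        affiliation_off_community=97,
        affiliation_with_aian=300,
        jurisdiction_with_aian=450,
    )
    assert abs(rep.pct_on_with_affiliation + rep.pct_on_without_affiliation - 100.0) <= 0.01
    assert abs(rep.pct_affiliation_on + rep.pct_affiliation_off - 100.0) <= 0.01


def test_category_partition_on_pipeline_fixture(small_reference, noisy_extract):
    res = ca.run_stages(
        noisy_extract.records,
        small_reference.points,
        rule_set=small_reference.rule_set,
        keyword_set=small_reference.keywords,
        exclusion_keys=small_reference.exclusion_keys,
    )
    counts = {c: 0 for c in RecordCategory}
    for cat in res.categories.values():
        counts[cat] += 1
    assert sum(counts.values()) == len(noisy_extract.records)
    rep = res.report
    assert rep.on_community_total == (
        counts[RecordCategory.ON_COMMUNITY_WITH_AFFILIATION]
        + counts[RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION]
    )
    assert rep.jurisdiction_total == rep.on_community_total + counts[RecordCategory.AFFILIATION_ONLY]


def test_ratio_at_least_one_by_construction(small_reference, noisy_extract):
    """Every affiliated on-community record is also an address match, so
    the times-as-many ratio can never drop below 1."""
    res = ca.run_stages(
        noisy_extract.records, small_reference.points, keyword_set=small_reference.keywords
    )
    if res.report.times_as_many_ratio is not None:
        assert res.report.times_as_many_ratio >= 1.0


def test_evaluate_processing_no_noise_limit(small_reference, quiet_extract):
    """With zero noise both arms geocode everything: no additional matches
    and both rates exactly 1."""
    kwargs = dict(
        rule_set=small_reference.rule_set,
        keyword_set=small_reference.keywords,
        exclusion_keys=small_reference.exclusion_keys,
    )
    with_rules = ca.run_stages(quiet_extract.records, small_reference.points, **kwargs)
    without_rules = ca.run_stages(
        quiet_extract.records, small_reference.points, apply_rules=False, **kwargs
    )
    rep = ca.evaluate_processing(without_rules, with_rules)
    assert rep.additional_matches == 0
    assert rep.geocoding_rate_without_processing == 1.0
    assert rep.geocoding_rate_with_processing == 1.0
    assert rep.pct_matches_with_noncommunity_zip == 0.0


def test_evaluate_processing_rejects_mismatched_extracts(small_reference, quiet_extract, noisy_extract):
    a = ca.run_stages(quiet_extract.records, small_reference.points)
    b = ca.run_stages(noisy_extract.records, small_reference.points)
    with pytest.raises(InputValidationError, match="different extracts"):
        ca.evaluate_processing(a, b)


def test_eval_report_from_counts_percentages():
    rep = ProcessingEvalReport.from_counts(
        n_without=1000, geocoded_without=900, n_subset=950, geocoded_with=930,
        matches_without=94, matches_with=100, noncommunity_zip_matches=2,
    )
    assert rep.additional_matches == 6
    assert rep.pct_additional_matches == 6.0
    assert rep.pct_matches_with_noncommunity_zip == 2.0
    assert rep.geocoding_rate_without_processing == pytest.approx(0.9)
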