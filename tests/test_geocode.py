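"""Match scoring, threshold behavior, tie-breaks, and blocked-index
equivalence with a brute-force scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import commaddr as ca
from commaddr.errors import ConfigError
from commaddr.geocode import _zip_agreement
from conftest import dp_levenshtein


def _ref(number=100, name="MESQUITE FLATS RD", zip5="86544", lon=-112.0, lat=32.0, comm=True):
    return ca.ReferenceAddressPoint(number, name, zip5, lon, lat, comm)


def _parsed(number=100, name="MESQUITE FLATS RD", zip5="86544"):
    from commaddr.normalize import Geocodability, ParsedAddress

    return ParsedAddress(number, name, None, zip5, Geocodability.GEOCODABLE)


def test_exact_match_scores_100():
    score, sim, num, zp = ca.match_score(_parsed(), _ref())
    assert (score, sim, num, zp) == (100.0, 1.0, 1.0, 1.0)


def test_wrong_zip_scores_exactly_85():
    """Exact street and number with a completely wrong zip must score
    exactly 85.0 and pass the inclusive threshold — this is what lets
    zip-typo records with an otherwise correct address still match."""
    score, sim, num, zp = ca.match_score(_parsed(zip5="99901"), _ref())
    assert score == 85.0
    assert (sim, num, zp) == (1.0, 1.0, 0.0)
    index = ca.build_index([_ref()])
    m = ca.geocode(_parsed(zip5="99901"), index)
    assert m is not None and m.score == 85.0


def test_zip_prefix_partial_agreement():
    assert _zip_agreement("86599", "86544") == 0.5
    assert _zip_agreement(None, "86544") == 0.0
    score, *_ = ca.match_score(_parsed(zip5="86599"), _ref())
    assert score == pytest.approx(92.5)


def test_one_edit_typo_score_matches_dp_oracle():
    query, refname = "MESQUIT FLATS RD", "MESQUITE FLATS RD"
    d = dp_levenshtein(query, refname)
    assert ca.levenshtein(query, refname) == d
    expected = 60.0 * (1 - d / len(refname)) + 25.0 + 15.0
    score, *_ = ca.match_score(_parsed(name=query), _ref())
    assert score == pytest.approx(expected)


@given(
    a=st.text(alphabet="ABCDEFG ", min_size=1, max_size=12),
    b=st.text(alphabet="ABCDEFG ", min_size=1, max_size=12),
)
def test_levenshtein_agrees_with_dp_oracle(a, b):
    assert ca.levenshtein(a, b) == dp_levenshtein(a, b)


def test_completely_different_address_below_threshold():
    score, *_ = ca.match_score(_parsed(7, "ELM GROVE PARK LN", "85701"), _ref())
    assert score < 85.0


def test_wrong_number_alone_fails():
    """A wrong street number caps the score at 75 even with perfect name
    and zip, so it cannot pass the default threshold."""
    score, *_ = ca.match_score(_parsed(number=999), _ref())
    assert score == pytest.approx(75.0)
    assert ca.geocode(_parsed(number=999), ca.build_index([_ref()])) is None


def test_score_is_100_iff_all_components_perfect():
    cases = [
        _parsed(),
        _parsed(zip5="86599"),
        _parsed(number=101),
        _parsed(name="MESQUITE FLAT RD"),
    ]
    for p in cases:
        score, sim, num, zp = ca.match_score(p, _ref())
        assert (score == 100.0) == (sim == 1.0 and num == 1.0 and zp == 1.0)


def test_threshold_is_inclusive_boundary():
    index = ca.build_index([_ref()])
    assert ca.geocode(_parsed(zip5="99901"), index, min_score=85.0) is not None
    assert ca.geocode(_parsed(zip5="99901"), index, min_score=85.1) is None


def test_tie_break_exact_zip_wins():
    """Two candidates with identical score and name similarity: the one
    whose zip matches the query exactly is chosen."""
    a = _ref(number=100, name="MESQUITE FLATS RD", zip5="86544")
    b = _ref(number=100, name="MESQUITE FLATS RD", zip5="86545")
    index = ca.build_index([a, b])
    # zip absent -> both score 85, both zip_agreement 0 -> lexicographic key
    m = ca.geocode(_parsed(zip5=None), index)
    assert m.matched_point.zip == "86544"
    # exact zip present -> that candidate wins outright on score
    m = ca.geocode(_parsed(zip5="86545"), index)
    assert m.matched_point.zip == "86545"


def test_empty_reference_is_config_error():
    with pytest.raises(ConfigError):
        ca.build_index([])


def test_index_blocks_reach_every_point(small_reference):
    index = ca.build_index(small_reference.points)
    reachable = set()
    for block in (index.by_zip, index.by_zip3, index.by_token):
        for idxs in block.values():
            reachable.update(idxs)
    assert reachable == set(range(len(index.points)))


def test_candidate_via_name_token_when_zip_wrong(small_reference):
    """A query with a wrong zip still reaches its point through the
    street-name token block."""
    index = ca.build_index(small_reference.points)
    pt = small_reference.community_points[0]
    p = _parsed(pt.street_number, pt.street_name, "99901")
    cand = index.candidates(p)
    assert any(index.points[i] == pt for i in cand)


def _brute_force_geocode(parsed, points, min_score=85.0):
    """Oracle: score every reference point with no blocking, identical
    tie-break ordering."""
    best, best_rank = None, None
    for ref in points:
        score, sim, num, zp = ca.match_score(parsed, ref)
        if score < min_score:
            continue
        rank = (-score, -sim, 0 if zp == 1.0 else 1, ref.key)
        if best_rank is None or rank < best_rank:
            best_rank, best = rank, ref
    return best


def test_blocked_geocode_equals_brute_force(small_reference):
    """Blocking is a pure optimization: on perturbed queries the blocked
    geocoder returns exactly the brute-force best candidate (or no-match)."""
    rng = np.random.default_rng(5)
    points = small_reference.points
    index = ca.build_index(points)
    noise = ca.NoiseProfile(
        abbreviation_variant=0.2, spelling_typo=0.2, number_typo=0.1, zip_typo=0.2,
        historical_street_alias=0.1, po_box_substitution=0.0, blank_address=0.0,
        numberless=0.0, seed=5,
    )
    ext = ca.generate_extract(300, 0.5, noise, small_reference)
    for rec in ext.records:
        parsed = ca.parse_address(rec.raw_street, rec.raw_zip)
        if parsed.geocodability is not ca.Geocodability.GEOCODABLE:
            continue
        got = ca.geocode(parsed, index)
        expected = _brute_force_geocode(parsed, points)
        if expected is None:
            assert got is None
        else:
            assert got is not None and got.matched_point == expected


def test_geocoding_rate():
    assert ca.geocoding_rate(10, 9) == pytest.approx(0.9)
    assert ca.geocoding_rate(10, 0) == 0.0
    assert ca.geocoding_rate(0, 0) is None
    assert ca.geocoding_rate(list(range(4)), [1, 2]) == pytest.approx(0.5)
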