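"""Reference-file geocoder with a composite match score.

Replicates the behavior of an address locator built on a county
address-point layer: a standardized address is matched to the best-scoring
reference point, and coordinates are returned only when the composite score
meets the minimum (default 85, inclusive).

The commercial locator's score formula is proprietary; this implementation
defines a transparent weighted composite over three components —

    score = 60·name_similarity + 25·number_agreement + 15·zip_agreement

with name_similarity a normalized Levenshtein similarity, number agreement
binary, and zip agreement 1 / 0.5 (3-digit prefix) / 0.  The weights are
chosen so that an exact street+number with a wrong zip scores exactly 85
and still passes — zip typos with an otherwise correct address must match —
while a wrong street number alone (≤ 75) fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .errors import ConfigError
from .normalize import Geocodability, ParsedAddress
from .records import ReferenceAddressPoint

#: Score weights in points (they sum to 100): street-name similarity,
#: street-number agreement, zip agreement.
DEFAULT_WEIGHTS = (60.0, 25.0, 15.0)
DEFAULT_MIN_SCORE = 85.0


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def name_similarity(a: str, b: str) -> float:
    """1 − levenshtein/max(len); 1.0 iff identical, 0.0 for disjoint."""
    if not a and not b:
        return 1.0
    m = max(len(a), len(b))
    return 1.0 - levenshtein(a, b) / m


@dataclass(frozen=True)
class GeocodeMatch:
    record_id: str
    matched_point: ReferenceAddressPoint
    score: float
    name_similarity: float
    number_agreement: float
    zip_agreement: float


def _zip_agreement(parsed_zip: Optional[str], ref_zip: str) -> float:
    if not parsed_zip:
        return 0.0
    if parsed_zip == ref_zip:
        return 1.0
    if parsed_zip[:3] == ref_zip[:3]:
        return 0.5
    return 0.0


def match_score(
    parsed: ParsedAddress,
    reference_point: ReferenceAddressPoint,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> tuple[float, float, float, float]:
    """Score a geocodable parsed address against one reference point.

    Returns ``(score, name_similarity, number_agreement, zip_agreement)``.
    """
    sim = name_similarity(parsed.street_name, reference_point.street_name)
    num = 1.0 if parsed.street_number == reference_point.street_number else 0.0
    zp = _zip_agreement(parsed.zip, reference_point.zip)
    w_name, w_num, w_zip = weights
    return (w_name * sim + w_num * num + w_zip * zp, sim, num, zp)


class GeocoderIndex:
    """Blocked candidate index over reference points.

    Candidate generation for a query is the union of the query's 5-digit
    zip block, its 3-digit zip-prefix block, and the blocks of its exact
    street-name tokens.  This is complete for any threshold
    ``min_score ≥ w_name + w_num``: a reference point outside all three
    blocks has zero zip agreement, so reaching the threshold would require
    perfect name similarity — an identical name, which shares every token.
    Below that threshold :func:`geocode` scans all points instead, so
    blocking is always a pure optimization.
    """

    def __init__(self, points: Sequence[ReferenceAddressPoint]):
        if not points:
            raise ConfigError("reference point list is empty")
        self.points: tuple[ReferenceAddressPoint, ...] = tuple(sorted(points))
        self.by_zip: dict[str, list[int]] = {}
        self.by_zip3: dict[str, list[int]] = {}
        self.by_token: dict[str, list[int]] = {}
        for i, p in enumerate(self.points):
            self.by_zip.setdefault(p.zip, []).append(i)
            self.by_zip3.setdefault(p.zip[:3], []).append(i)
            for tok in set(p.street_name.split()):
                self.by_token.setdefault(tok, []).append(i)
        # street names repeat across points; memoize pairwise similarity
        self._sim_cache: dict[tuple[str, str], float] = {}

    def similarity(self, query_name: str, ref_name: str) -> float:
        key = (query_name, ref_name)
        sim = self._sim_cache.get(key)
        if sim is None:
            sim = name_similarity(query_name, ref_name)
            self._sim_cache[key] = sim
        return sim

    def candidates(self, parsed: ParsedAddress) -> list[int]:
        idx: set[int] = set()
        if parsed.zip:
            idx.update(self.by_zip.get(parsed.zip, ()))
            idx.update(self.by_zip3.get(parsed.zip[:3], ()))
        for tok in set(parsed.street_name.split()):
            idx.update(self.by_token.get(tok, ()))
        return sorted(idx)


def build_index(reference_points: Sequence[ReferenceAddressPoint]) -> GeocoderIndex:
    """Build the deterministic blocked index (error on an empty reference)."""
    return GeocoderIndex(reference_points)


def geocode(
    parsed: ParsedAddress,
    index: GeocoderIndex,
    min_score: float = DEFAULT_MIN_SCORE,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    full_scan: bool = False,
) -> Optional[GeocodeMatch]:
    """Best-scoring reference point at or above ``min_score`` (inclusive),
    or None.

    Ties break deterministically: higher name similarity, then exact zip,
    then the lexicographically smallest (number, name, zip) reference key.
    """
    if parsed.geocodability is not Geocodability.GEOCODABLE:
        return None
    w_name, w_num, w_zip = weights
    if full_scan or min_score < w_name + w_num:
        cand = range(len(index.points))
    else:
        cand = index.candidates(parsed)

    best = None
    best_rank = None
    for i in cand:
        ref = index.points[i]
        sim = index.similarity(parsed.street_name, ref.street_name)
        num = 1.0 if parsed.street_number == ref.street_number else 0.0
        zp = _zip_agreement(parsed.zip, ref.zip)
        score = w_name * sim + w_num * num + w_zip * zp
        if score < min_score:
            continue
        rank = (-score, -sim, 0 if zp == 1.0 else 1, ref.key)
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best = GeocodeMatch("", ref, score, sim, num, zp)
    return best


def geocoding_rate(records, matches) -> Optional[float]:
    """Fraction of the denominator population that geocoded; None when the
    denominator is empty (reported as not-applicable).

    Accepts the collections themselves or their counts.
    """
    n_records = records if isinstance(records, int) else len(records)
    n_matched = matches if isinstance(matches, int) else len(matches)
    if n_records == 0:
        return None
    return n_matched / n_records
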