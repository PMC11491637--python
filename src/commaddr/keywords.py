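"""Keyword fallback for records the geocoder could not place.

Addresses that fail to geocode (score below threshold, or numberless) are
scanned for keywords — unique parts of community street names or words that
commonly appear in community addresses.  A flagged record is confirmed as a
community match only when its street number and zip both match the same
known community address point; flagged-but-unconfirmed records are emitted
as a manual-review queue so the human adjudication step stays auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError
from .normalize import ParsedAddress, _clean_text
from .records import ReferenceAddressPoint, SurveillanceRecord


@dataclass(frozen=True)
class KeywordSet:
    """Uppercase keywords with optional provenance comments.

    Matching is whole-word (token-boundary) substring search, so the
    keyword AGENCY flags "123 OLD AGENCY RD" but not "123 REGENCY DR".
    Typos inside the keyword itself are deliberately not matched — such
    records route to manual review instead.
    """

    keywords: tuple[str, ...]
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ConfigError("keyword set is empty")
        for kw in self.keywords:
            if not kw or kw != kw.strip() or kw != kw.upper():
                raise ConfigError(f"keyword must be non-empty, trimmed, uppercase: {kw!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "KeywordSet":
        with open(path) as fh:
            data = json.load(fh)
        kws, comments = [], []
        for item in data:
            if isinstance(item, str):
                kws.append(item)
                comments.append("")
            else:
                kws.append(item["keyword"])
                comments.append(item.get("comment", ""))
        return cls(tuple(kws), tuple(comments))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"keyword": k, "comment": c}
                    for k, c in zip(self.keywords, self.comments or [""] * len(self.keywords))
                ],
                fh,
                indent=1,
            )


def _keyword_pattern(keyword: str) -> re.Pattern:
    toks = [re.escape(t) for t in keyword.split()]
    return re.compile(r"(?<![A-Z0-9])" + r"\s+".join(toks) + r"(?![A-Z0-9])")


@dataclass(frozen=True)
class FallbackOutcome:
    record_id: str
    flagged: bool
    confirmed: bool
    matched_keyword: Optional[str] = None
    review_reason: Optional[str] = None  # no_number | zip_mismatch | number_not_found


def flag_by_keyword(
    non_geocoded_records: Sequence[SurveillanceRecord], keyword_set: KeywordSet
) -> list[tuple[SurveillanceRecord, str]]:
    """Flag records whose raw street contains any keyword as a whole-word
    substring (first matching keyword in set order is recorded)."""
    patterns = [(_keyword_pattern(kw), kw) for kw in keyword_set.keywords]
    flagged = []
    for rec in non_geocoded_records:
        text = _clean_text(rec.raw_street)
        for pat, kw in patterns:
            if pat.search(text):
                flagged.append((rec, kw))
                break
    return flagged


def confirm_flagged(
    record_id: str,
    parsed: ParsedAddress,
    matched_keyword: str,
    community_points: Sequence[ReferenceAddressPoint],
) -> FallbackOutcome:
    """Confirm a flagged record iff its street number and zip match the
    same community address point; otherwise record why it needs review."""
    if parsed.street_number is None:
        return FallbackOutcome(record_id, True, False, matched_keyword, "no_number")
    with_number = [p for p in community_points if p.street_number == parsed.street_number]
    if not with_number:
        return FallbackOutcome(record_id, True, False, matched_keyword, "number_not_found")
    if parsed.zip is not None and any(p.zip == parsed.zip for p in with_number):
        return FallbackOutcome(record_id, True, True, matched_keyword)
    return FallbackOutcome(record_id, True, False, matched_keyword, "zip_mismatch")


def emit_review_queue(
    outcomes: Iterable[FallbackOutcome],
    records_by_id: Mapping[str, SurveillanceRecord],
    path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Build (and optionally write) the manual-review queue: flagged but
    unconfirmed records, deterministically ordered by record id."""
    rows = []
    for o in sorted(outcomes, key=lambda o: o.record_id):
        if o.flagged and not o.confirmed:
            rec = records_by_id.get(o.record_id)
            rows.append(
                {
                    "record_id": o.record_id,
                    "raw_street": rec.raw_street if rec else "",
                    "raw_zip": rec.raw_zip if rec else "",
                    "matched_keyword": o.matched_keyword or "",
                    "review_reason": o.review_reason or "",
                }
            )
    df = pd.DataFrame(
        rows, columns=["record_id", "raw_street", "raw_zip", "matched_keyword", "review_reason"]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def suggest_keywords(reference_points: Sequence[ReferenceAddressPoint]) -> KeywordSet:
    """Derive a keyword set from the reference layer: street-name tokens
    that occur in community addresses but in no non-community address
    (generic suffixes and directionals are excluded by construction)."""
    community_tokens: set[str] = set()
    other_tokens: set[str] = set()
    for p in reference_points:
        toks = set(p.street_name.split())
        (community_tokens if p.is_community else other_tokens).update(toks)
    unique = sorted(t for t in community_tokens - other_tokens if not t.isdigit())
    if not unique:
        raise ConfigError("no community-unique street tokens to build keywords from")
    return KeywordSet(tuple(unique), tuple("unique community street token" for _ in unique))
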