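"""Record taxonomy and jurisdiction summary reports.

Combines the address-match outcome (geocode-join within buffer, or
keyword-confirmed) with the affiliation and race fields into four mutually
exclusive categories, then aggregates them into a jurisdiction summary
(how many records belong to the community, how many of those carry an
affiliation or an AI/AN race) and a processing evaluation (how much the
address standardization step raised the geocoding rate and match count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Optional

import pandas as pd

from .errors import InputValidationError


class RecordCategory(str, Enum):
    """Partition of all records in an extract.

    On-community (by address) takes precedence; an affiliation with an
    off-community, PO-box, blank or otherwise non-geocodable address is
    affiliation_only; everything else is unrelated to the jurisdiction.
    """

    ON_COMMUNITY_WITH_AFFILIATION = "on_community_with_affiliation"
    ON_COMMUNITY_WITHOUT_AFFILIATION = "on_community_without_affiliation"
    AFFILIATION_ONLY = "affiliation_only"
    UNRELATED = "unrelated"


def classify_record(on_community: bool, affiliation_present: bool) -> RecordCategory:
    """Assign the category from the resolved address match and the
    affiliation flag."""
    if on_community:
        if affiliation_present:
            return RecordCategory.ON_COMMUNITY_WITH_AFFILIATION
        return RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION
    if affiliation_present:
        return RecordCategory.AFFILIATION_ONLY
    return RecordCategory.UNRELATED


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention the summary tables print)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(part: int, whole: int) -> Optional[float]:
    if whole == 0:
        return None
    return round_half_up(100.0 * part / whole)


@dataclass(frozen=True)
class JurisdictionReport:
    """Summary of matches by community address and affiliation.

    ``jurisdiction_total`` is the union: on-community records plus
    affiliation-only records.  ``times_as_many_ratio`` is the on-community
    total over its with-affiliation subset — how many times as many records
    the address method finds compared to filtering by affiliation alone.
    Counts are record rows (dose-level for vaccination extracts), never
    deduplicated persons.
    """

    total_records: int
    on_community_total: int
    on_community_with_affiliation: int
    on_community_without_affiliation: int
    on_community_with_aian: int
    affiliation_total: int
    affiliation_on_community: int
    affiliation_off_community: int
    affiliation_with_aian: int
    jurisdiction_total: int
    jurisdiction_with_aian: int
    jurisdiction_with_affiliation: int
    pct_on_with_affiliation: Optional[float]
    pct_on_without_affiliation: Optional[float]
    pct_on_with_aian: Optional[float]
    pct_affiliation_on: Optional[float]
    pct_affiliation_off: Optional[float]
    pct_affiliation_with_aian: Optional[float]
    pct_jurisdiction_with_aian: Optional[float]
    pct_jurisdiction_with_affiliation: Optional[float]
    times_as_many_ratio: Optional[float]

    @classmethod
    def from_counts(
        cls,
        total_records: int,
        on_with_affiliation: int,
        on_without_affiliation: int,
        on_with_aian: int,
        affiliation_off_community: int,
        affiliation_with_aian: int,
        jurisdiction_with_aian: int,
    ) -> "JurisdictionReport":
        """Derive every percentage and ratio from the primitive counts.

        The on-community total is with+without affiliation; the affiliation
        total is its on-community subset plus the off-community/unknown
        remainder; the jurisdiction union adds exactly the affiliation-only
        remainder to the on-community total.
        """
        on_total = on_with_affiliation + on_without_affiliation
        aff_total = on_with_affiliation + affiliation_off_community
        jur_total = on_total + affiliation_off_community
        ratio = (
            round_half_up(on_total / on_with_affiliation)
            if on_with_affiliation
            else None
        )
        return cls(
            total_records=total_records,
            on_community_total=on_total,
            on_community_with_affiliation=on_with_affiliation,
            on_community_without_affiliation=on_without_affiliation,
            on_community_with_aian=on_with_aian,
            affiliation_total=aff_total,
            affiliation_on_community=on_with_affiliation,
            affiliation_off_community=affiliation_off_community,
            affiliation_with_aian=affiliation_with_aian,
            jurisdiction_total=jur_total,
            jurisdiction_with_aian=jurisdiction_with_aian,
            jurisdiction_with_affiliation=aff_total,
            pct_on_with_affiliation=_pct(on_with_affiliation, on_total),
            pct_on_without_affiliation=_pct(on_without_affiliation, on_total),
            pct_on_with_aian=_pct(on_with_aian, on_total),
            pct_affiliation_on=_pct(on_with_affiliation, aff_total),
            pct_affiliation_off=_pct(affiliation_off_community, aff_total),
            pct_affiliation_with_aian=_pct(affiliation_with_aian, aff_total),
            pct_jurisdiction_with_aian=_pct(jurisdiction_with_aian, jur_total),
            pct_jurisdiction_with_affiliation=_pct(aff_total, jur_total),
            times_as_many_ratio=ratio,
        )

    def to_frame(self) -> pd.DataFrame:
        def fmt(count, pct):
            return f"{count}" + (f" ({pct}%)" if pct is not None else "")

        rows = [
            ("Total # of records", f"{self.total_records}"),
            ("Total # of records on-community", f"{self.on_community_total}"),
            ("  With affiliation", fmt(self.on_community_with_affiliation, self.pct_on_with_affiliation)),
            ("  W/o affiliation", fmt(self.on_community_without_affiliation, self.pct_on_without_affiliation)),
            ("  With AI/AN race", fmt(self.on_community_with_aian, self.pct_on_with_aian)),
            ("Total # of records w/affiliation", f"{self.affiliation_total}"),
            ("  On-community", fmt(self.affiliation_on_community, self.pct_affiliation_on)),
            ("  Off-community or unknown residence", fmt(self.affiliation_off_community, self.pct_affiliation_off)),
            ("  With AI/AN race", fmt(self.affiliation_with_aian, self.pct_affiliation_with_aian)),
            ("Total # of jurisdiction records identified", f"{self.jurisdiction_total}"),
            ("  With AI/AN race", fmt(self.jurisdiction_with_aian, self.pct_jurisdiction_with_aian)),
            ("  With affiliation", fmt(self.jurisdiction_with_affiliation, self.pct_jurisdiction_with_affiliation)),
            ("Times as many as affiliation alone", "NA" if self.times_as_many_ratio is None else f"{self.times_as_many_ratio:.2f}"),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    categories: Mapping[str, RecordCategory], aian_flags: Mapping[str, bool]
) -> JurisdictionReport:
    """Aggregate per-record categories and AI/AN flags into the report."""
    on_with = on_without = aff_only = 0
    on_aian = jur_aian = aff_aian = 0
    for rid, cat in categories.items():
        aian = bool(aian_flags.get(rid, False))
        if cat is RecordCategory.ON_COMMUNITY_WITH_AFFILIATION:
            on_with += 1
            on_aian += aian
            aff_aian += aian
            jur_aian += aian
        elif cat is RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION:
            on_without += 1
            on_aian += aian
            jur_aian += aian
        elif cat is RecordCategory.AFFILIATION_ONLY:
            aff_only += 1
            aff_aian += aian
            jur_aian += aian
    return JurisdictionReport.from_counts(
        total_records=len(categories),
        on_with_affiliation=on_with,
        on_without_affiliation=on_without,
        on_with_aian=on_aian,
        affiliation_off_community=aff_only,
        affiliation_with_aian=aff_aian,
        jurisdiction_with_aian=jur_aian,
    )


@dataclass(frozen=True)
class ProcessingEvalReport:
    """Evaluation of geocoding with and without address processing.

    Geocoding rates count records placed anywhere in the reference layer
    (community or not); match counts are community matches.  The
    without-processing denominator is every record with a non-blank raw
    address; the with-processing denominator is the subset surviving
    blank/PO-box/numberless removal.
    """

    geocoding_rate_without_processing: Optional[float]
    geocoding_rate_with_processing: Optional[float]
    n_without_processing: int
    n_with_processing_subset: int
    matches_without_processing: int
    matches_with_processing: int
    additional_matches: int
    pct_additional_matches: Optional[float]
    matches_with_noncommunity_zip: int
    pct_matches_with_noncommunity_zip: Optional[float]

    @classmethod
    def from_counts(
        cls,
        n_without: int,
        geocoded_without: int,
        n_subset: int,
        geocoded_with: int,
        matches_without: int,
        matches_with: int,
        noncommunity_zip_matches: int,
    ) -> "ProcessingEvalReport":
        additional = matches_with - matches_without
        return cls(
            geocoding_rate_without_processing=(
                None if n_without == 0 else geocoded_without / n_without
            ),
            geocoding_rate_with_processing=(
                None if n_subset == 0 else geocoded_with / n_subset
            ),
            n_without_processing=n_without,
            n_with_processing_subset=n_subset,
            matches_without_processing=matches_without,
            matches_with_processing=matches_with,
            additional_matches=additional,
            pct_additional_matches=_pct(additional, matches_with),
            matches_with_noncommunity_zip=noncommunity_zip_matches,
            pct_matches_with_noncommunity_zip=_pct(noncommunity_zip_matches, matches_with),
        )

    def to_frame(self) -> pd.DataFrame:
        def pct(x):
            return "NA" if x is None else f"{round_half_up(100.0 * x)}%"

        rows = [
            ("Geocoding rate w/o address processing", pct(self.geocoding_rate_without_processing)),
            (
                "Geocoding rate of subset w/address processing",
                f"{pct(self.geocoding_rate_with_processing)} (n = {self.n_with_processing_subset})",
            ),
            ("# of matches w/o address processing", f"{self.matches_without_processing}"),
            ("# of matches w/address processing", f"{self.matches_with_processing}"),
            (
                "# of additional matches w/address processing",
                f"{self.additional_matches} ({self.pct_additional_matches}%)",
            ),
            (
                "% of matches with non-community zip code",
                f"{self.pct_matches_with_noncommunity_zip}% "
                f"({self.matches_with_noncommunity_zip}/{self.matches_with_processing})",
            ),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_processing(run_without, run_with) -> ProcessingEvalReport:
    """Build the evaluation from two pipeline runs over the same extract —
    identical apart from whether address standardization is applied."""
    if run_without.record_ids != run_with.record_ids:
        raise InputValidationError("the two runs cover different extracts")
    return ProcessingEvalReport.from_counts(
        n_without=run_without.n_nonblank,
        geocoded_without=run_without.n_geocoded,
        n_subset=run_with.n_geocoder_input,
        geocoded_with=run_with.n_geocoded,
        matches_without=run_without.n_matches,
        matches_with=run_with.n_matches,
        noncommunity_zip_matches=run_with.n_matches_noncommunity_zip,
    )
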