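"""Address standardization and correction.

Raw line-list addresses arrive as free text with spelling variants,
abbreviation differences, unit designators, historical street names and
outright typos.  This module parses them into a structured form, classifies
geocodability (blank / PO box / numberless addresses cannot be geocoded and
are removed from the geocoder input), and applies an ordered, data-driven
correction rule set followed by a built-in USPS-style abbreviation table so
that what reaches the geocoder matches what the reference layer expects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import RuleSetError


class Geocodability(str, Enum):
    GEOCODABLE = "geocodable"
    BLANK = "blank"
    PO_BOX = "po_box"
    NUMBERLESS = "numberless"


@dataclass(frozen=True)
class ParsedAddress:
    """A standardized street address: number, name, optional unit and zip.

    ``geocodable`` requires a street number and a non-empty street name;
    everything else is classified blank / po_box / numberless and routed
    around the geocoder.
    """

    street_number: Optional[int]
    street_name: str
    unit: Optional[str]
    zip: Optional[str]
    geocodability: Geocodability


# Conservative PO-box detector: applied at string start after uppercasing
# and punctuation removal, so "P.O. Box 12", "PO BOX 12", "POB 12" and
# "BOX 12" are all caught, but "42 BOX ELDER RD" is not.
_PO_BOX_RE = re.compile(r"^(P\s*O\s*BOX|POB|BOX)\s+\S")

_UNIT_RE = re.compile(
    r"\s+(?:(APT|UNIT|STE|SUITE|LOT|TRLR|SPC|SP|RM|BLDG|NO)\s*#?\s*|#\s*)([A-Z0-9/-]+)$"
)

_NUMBER_RE = re.compile(r"^(\d+)(?:\s+|$)")

#: Token-level abbreviation table applied after the correction rules:
#: street-type suffixes and directionals to their canonical short forms.
ABBREVIATIONS = {
    "STREET": "ST",
    "ROAD": "RD",
    "AVENUE": "AVE",
    "DRIVE": "DR",
    "LANE": "LN",
    "BOULEVARD": "BLVD",
    "CIRCLE": "CIR",
    "COURT": "CT",
    "PLACE": "PL",
    "TERRACE": "TER",
    "TRAIL": "TRL",
    "HIGHWAY": "HWY",
    "PARKWAY": "PKWY",
    "EXPRESSWAY": "EXPY",
    "ROUTE": "RTE",
    "CROSSING": "XING",
    "NORTH": "N",
    "SOUTH": "S",
    "EAST": "E",
    "WEST": "W",
    "NORTHEAST": "NE",
    "NORTHWEST": "NW",
    "SOUTHEAST": "SE",
    "SOUTHWEST": "SW",
}


def _clean_text(s: str) -> str:
    s = s.upper()
    s = re.sub(r"[^A-Z0-9#/ -]", " ", s)
    s = s.replace("-", " ")
    return re.sub(r"\s+", " ", s).strip()


def parse_address(raw_street: str, raw_zip: str) -> ParsedAddress:
    """Parse free-text street + zip into a :class:`ParsedAddress`.

    Never raises on bad input: malformed addresses degrade to a
    non-geocodable class instead.  The zip keeps the first five digits of a
    5- or 9-digit string and is otherwise absent (the geocoder tolerates a
    missing zip; it only lowers the match score).
    """
    street = _clean_text(raw_street or "")
    zip5 = _parse_zip(raw_zip)

    if not street:
        return ParsedAddress(None, "", None, None, Geocodability.BLANK)
    if _PO_BOX_RE.match(street):
        return ParsedAddress(None, street, None, zip5, Geocodability.PO_BOX)

    unit = None
    m = _UNIT_RE.search(street)
    if m:
        designator = m.group(1)
        unit = (designator + " " if designator else "# ") + m.group(2)
        street = street[: m.start()].strip()

    number = None
    m = _NUMBER_RE.match(street)
    if m:
        number = int(m.group(1))
        street = street[m.end():].strip()

    if number is None or not street:
        return ParsedAddress(number, street, unit, zip5, Geocodability.NUMBERLESS)
    return ParsedAddress(number, street, unit, zip5, Geocodability.GEOCODABLE)


def _parse_zip(raw_zip: str) -> Optional[str]:
    digits = re.sub(r"\D", "", str(raw_zip or ""))
    return digits[:5] if len(digits) in (5, 9) else None


@dataclass(frozen=True)
class Rule:
    pattern: str
    replacement: str
    comment: str = ""

    @property
    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class RuleSet:
    """An ordered list of regex correction rules, applied to the street
    name in list order, each once; rules are data (JSON), not code, so the
    same engine ports to other communities."""

    rules: tuple[Rule, ...] = ()
    version: str = "0"

    def __post_init__(self) -> None:
        for r in self.rules:
            try:
                pat = re.compile(r.pattern)
            except re.error as exc:
                raise RuleSetError(f"rule pattern does not compile: {r.pattern!r}") from exc
            # A replacement that still matches its own pattern would grow
            # without bound under repeated application.
            if "\\" not in r.replacement and pat.search(r.replacement):
                raise RuleSetError(
                    f"rule replacement {r.replacement!r} reintroduces its own "
                    f"pattern {r.pattern!r}"
                )

    @classmethod
    def from_json(cls, path: str | Path, version: str | None = None) -> "RuleSet":
        with open(path) as fh:
            data = json.load(fh)
        rules = tuple(
            Rule(d["pattern"], d["replacement"], d.get("comment", "")) for d in data
        )
        return cls(rules=rules, version=version or str(Path(path).name))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"pattern": r.pattern, "replacement": r.replacement, "comment": r.comment}
                    for r in self.rules
                ],
                fh,
                indent=1,
            )


EMPTY_RULESET = RuleSet()


def standardize(parsed: ParsedAddress, rule_set: RuleSet = EMPTY_RULESET) -> ParsedAddress:
    """Apply correction rules (in order, once each) then the built-in
    abbreviation table to the street name.

    Only the street name changes; the street number and zip are preserved
    (no shipped rule targets them).  Idempotent on its own output provided
    each rule's replacement does not re-match the pattern of any earlier
    rule — the load-time check guards each rule against itself.
    """
    name = parsed.street_name
    for rule in rule_set.rules:
        name = rule.compiled.sub(rule.replacement, name)
    tokens = [ABBREVIATIONS.get(t, t) for t in name.split()]
    name = " ".join(tokens)
    if name == parsed.street_name:
        return parsed
    return replace(parsed, street_name=name)


@dataclass
class RuleFlag:
    pattern: str
    matched_street: str


@dataclass
class ReviewAddress:
    original: str
    rewritten: str
    zip: Optional[str]


@dataclass
class ValidationReport:
    """Outcome of testing a rule set against the county street inventory:
    rules whose pattern also hits a non-community street (risk of pulling in
    look-alike county addresses), and rewritten addresses whose zip is not a
    community zip (queued for manual review)."""

    rule_flags: list[RuleFlag] = field(default_factory=list)
    review_addresses: list[ReviewAddress] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.rule_flags and not self.review_addresses

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "rule_flag", "pattern": f.pattern, "detail": f.matched_street}
            for f in self.rule_flags
        ] + [
            {
                "kind": "non_community_zip",
                "pattern": a.original,
                "detail": f"{a.rewritten} zip={a.zip or ''}",
            }
            for a in self.review_addresses
        ]
        return pd.DataFrame(rows, columns=["kind", "pattern", "detail"])


def validate_ruleset(
    rule_set: RuleSet,
    county_street_names: Iterable[str],
    community_zips: Iterable[str],
    addresses: Sequence[ParsedAddress] = (),
) -> ValidationReport:
    """Test every rule against the full non-community street inventory and
    flag any rule that would rewrite a county street; additionally flag any
    supplied address that a rule rewrote but whose zip is outside the
    community zip set (those go to manual review)."""
    report = ValidationReport()
    county = [s.strip().upper() for s in county_street_names]
    zips = set(community_zips)
    for rule in rule_set.rules:
        pat = rule.compiled
        for street in county:
            if pat.search(street):
                report.rule_flags.append(RuleFlag(rule.pattern, street))
    for parsed in addresses:
        rewritten = standardize(parsed, rule_set)
        if rewritten.street_name != standardize(parsed, EMPTY_RULESET).street_name:
            if parsed.zip not in zips:
                report.review_addresses.append(
                    ReviewAddress(parsed.street_name, rewritten.street_name, parsed.zip)
                )
    return report
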