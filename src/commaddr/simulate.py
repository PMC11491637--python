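"""Synthetic reference layers and perturbed surveillance extracts.

The real inputs — county extracts of case and dose-level vaccination
records and the county GIS address-point layer — are protected health
information and cannot ship.  This module generates stand-ins with known
ground truth: a synthetic street grid whose community points are spatially
clustered and well separated from the rest of the county (with optional
"confusable" non-community points planted just inside the join buffer to
exercise the exclusion list), and extracts whose addresses are perturbed
with the noise patterns seen in practice: abbreviation and spelling
variants, historical street renames, typos in street number and zip,
PO boxes, blanks, and numberless addresses.

All street names come from a fictional desert lexicon; no real community
addresses are embedded.  Every generator draws from one seeded pseudo-random
stream, and each record's applied perturbation is logged in the truth table
so pipeline failures are diagnosable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputValidationError
from .keywords import KeywordSet, suggest_keywords
from .normalize import ABBREVIATIONS, Rule, RuleSet
from .records import (
    ReferenceAddressPoint,
    SchemaMap,
    SurveillanceRecord,
    case_extract_schema,
    write_extract,
    write_reference,
)
from .spatial import EARTH_RADIUS_M, METERS_PER_FOOT

_M_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0

# Fictional lexicons; community and non-community word pools are disjoint
# so community street names carry unique, keyword-able tokens.
_COMM_FIRST = (
    "MESQUITE", "SAGUARO", "OCOTILLO", "CHOLLA", "IRONWOOD", "YUCCA",
    "TURQUOISE", "PINTO", "BADGER", "RATTLER", "ARROYO", "TALUS",
    "COYOTE", "ROADRUNNER", "SILVERBELL",
)
_COMM_SECOND = (
    "FLATS", "BASIN", "WELL", "BEND", "RUN", "HOLLOW", "RIM", "CREEK",
    "POINT", "PASS", "SPRINGS", "SEEP",
)
_OTHER_FIRST = (
    "MAPLE", "OAK", "ELM", "CEDAR", "BIRCH", "WALNUT", "SPRUCE", "ASPEN",
    "JUNIPER", "SYCAMORE", "MAGNOLIA", "DOGWOOD", "HICKORY", "LAUREL",
    "POPLAR",
)
_OTHER_SECOND = (
    "HILL", "GROVE", "PARK", "GARDEN", "VIEW", "CREST", "MEADOW", "FIELD",
    "RIDGE", "COMMONS", "VALE", "KNOLL",
)
_SUFFIXES = ("RD", "DR", "LN", "TRL", "WAY", "LOOP", "AVE", "ST", "CIR", "PL")
_ALIAS_WORDS = (
    "STAGE", "TELEGRAPH", "WAGON", "CAVALRY", "PROSPECT", "MINERS",
    "FERRY", "DEPOT", "SIGNAL", "GARRISON",
)
_ALIAS_ORDINALS = (
    "ONE", "TWO", "THREE", "FOUR", "FIVE", "SIX", "SEVEN", "EIGHT",
    "NINE", "TEN",
)

_COMMUNITY_ZIPS = ("86544", "86545")
_OTHER_ZIPS = ("85701", "85702", "85703")

_AFFILIATION_VALUE = "Desert River Nation"
_AIAN_VALUE = "American Indian or Alaska Native"
_OTHER_RACES = ("White", "Black or African American", "Asian", "Other", "")


def _street_names(first_pool, second_pool, n: int, suffix_pool=_SUFFIXES) -> list[str]:
    names = []
    for i in range(n):
        f = first_pool[i % len(first_pool)]
        s = second_pool[(i // len(first_pool)) % len(second_pool)]
        suf = suffix_pool[i % len(suffix_pool)]
        names.append(f"{f} {s} {suf}")
    if len(set(names)) != n:
        raise ConfigError(f"cannot generate {n} unique street names from the lexicon")
    return names


@dataclass
class ReferenceFixture:
    """A generated reference layer plus the configuration artifacts that go
    with it: the community zip set, historical-alias correction rules, the
    keyword set derived from community-unique street tokens, and the
    exclusion keys of the planted confusable points."""

    points: list[ReferenceAddressPoint]
    community_zips: set[str]
    alias_map: dict[str, str]  # current street name -> historical alias
    rule_set: RuleSet
    keywords: Optional[KeywordSet]
    exclusion_keys: list[str]
    seed: int

    @property
    def community_points(self) -> list[ReferenceAddressPoint]:
        return [p for p in self.points if p.is_community]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference(self.points, out / "reference.csv")
        self.rule_set.to_json(out / "rules.json")
        if self.keywords is not None:
            self.keywords.to_json(out / "keywords.json")
        pd.DataFrame({"key": self.exclusion_keys}).to_csv(out / "exclusions.csv", index=False)
        with open(out / "reference_meta.json", "w") as fh:
            json.dump(
                {
                    "community_zips": sorted(self.community_zips),
                    "alias_map": dict(sorted(self.alias_map.items())),
                    "seed": self.seed,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def generate_reference(
    n_streets: int,
    points_per_street: int,
    community_fraction: float,
    seed: int,
    n_confusable: int = 0,
) -> ReferenceFixture:
    """Generate a synthetic address-point layer around a fixed anchor
    (lon −112, lat 32).

    Community streets form a cluster ≥ 300 ft from every ordinary
    non-community point, so the 150-ft buffer is unambiguous; the
    non-community grid sits kilometres to the east.  ``n_confusable``
    non-community points are planted 100–149 ft from distinct community
    points to exercise the manual-exclusion list.  Every community street
    gets a historical alias and a correction rule rewriting the alias to
    the current name.
    """
    if n_streets < 1 or points_per_street < 1:
        raise ConfigError("n_streets and points_per_street must be >= 1")
    if not 0.0 <= community_fraction <= 1.0:
        raise ConfigError("community_fraction must be in [0, 1]")
    n_comm_streets = int(round(n_streets * community_fraction))
    n_other_streets = n_streets - n_comm_streets
    if n_confusable > 0 and n_comm_streets == 0:
        raise ConfigError("confusable points require at least one community street")
    if n_confusable > n_comm_streets * points_per_street:
        raise ConfigError("more confusables requested than community points")

    rng = np.random.default_rng(seed)
    comm_names = _street_names(_COMM_FIRST, _COMM_SECOND, n_comm_streets)
    other_names = _street_names(_OTHER_FIRST, _OTHER_SECOND, n_other_streets)

    points: list[ReferenceAddressPoint] = []
    # community cluster at the anchor; rows ~130 m apart, points ~47 m apart
    for i, name in enumerate(comm_names):
        zip5 = _COMMUNITY_ZIPS[i % len(_COMMUNITY_ZIPS)]
        lat = 32.0 + i * 0.0012
        for j in range(points_per_street):
            points.append(
                ReferenceAddressPoint(
                    street_number=100 + 2 * j + 10 * (i % 7),
                    street_name=name,
                    zip=zip5,
                    lon=-112.0 + j * 0.0005,
                    lat=lat,
                    is_community=True,
                )
            )
    # ordinary county grid, kilometres east of the community cluster
    for i, name in enumerate(other_names):
        zip5 = _OTHER_ZIPS[i % len(_OTHER_ZIPS)]
        lat = 32.0 + i * 0.0012
        for j in range(points_per_street):
            points.append(
                ReferenceAddressPoint(
                    street_number=101 + 2 * j + 10 * (i % 7),
                    street_name=name,
                    zip=zip5,
                    lon=-111.90 + j * 0.0005,
                    lat=lat,
                    is_community=False,
                )
            )

    community_points = [p for p in points if p.is_community]
    exclusion_keys: list[str] = []
    if n_confusable:
        anchor_idx = rng.choice(len(community_points), size=n_confusable, replace=False)
        for k, ai in enumerate(sorted(int(a) for a in anchor_idx)):
            cp = community_points[ai]
            dist_ft = float(rng.uniform(100.0, 149.0))
            dlat = dist_ft * METERS_PER_FOOT / _M_PER_DEG_LAT
            confusable = ReferenceAddressPoint(
                street_number=9000 + k,
                street_name=f"PERIMETER GAP {_ALIAS_ORDINALS[k % len(_ALIAS_ORDINALS)]} RD",
                zip=_OTHER_ZIPS[0],
                lon=cp.lon,
                lat=cp.lat + dlat,
                is_community=False,
            )
            points.append(confusable)
            exclusion_keys.append(confusable.key_str)

    alias_map: dict[str, str] = {}
    rules: list[Rule] = []
    for i, name in enumerate(comm_names):
        alias = (
            f"{_ALIAS_WORDS[i % len(_ALIAS_WORDS)]} "
            f"{_ALIAS_ORDINALS[(i // len(_ALIAS_WORDS)) % len(_ALIAS_ORDINALS)]} RTE"
        )
        alias_map[name] = alias
        rules.append(
            Rule(
                pattern=r"\b" + alias + r"\b",
                replacement=name,
                comment=f"historical rename: {alias} -> {name}",
            )
        )

    keywords = suggest_keywords(points) if community_points else None
    community_zips = {p.zip for p in community_points}
    return ReferenceFixture(
        points=points,
        community_zips=community_zips,
        alias_map=alias_map,
        rule_set=RuleSet(rules=tuple(rules), version=f"synthetic-{seed}"),
        keywords=keywords,
        exclusion_keys=exclusion_keys,
        seed=seed,
    )


@dataclass(frozen=True)
class NoiseProfile:
    """Per-record perturbation probabilities (at most one perturbation is
    applied per record, drawn categorically) plus field-noise rates.

    The defaults are the toolkit's standing study conditions, set to the
    order of magnitude of the address-noise patterns reported for real
    county extracts; they are configuration, not constants.
    """

    abbreviation_variant: float = 0.10
    spelling_typo: float = 0.03
    number_typo: float = 0.01
    zip_typo: float = 0.012
    historical_street_alias: float = 0.02
    po_box_substitution: float = 0.02
    blank_address: float = 0.02
    numberless: float = 0.014
    affiliation_missing_rate: float = 0.48
    aian_misclassification_rate: float = 0.32
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self._perturbation_probs()
        for name, p in list(probs.items()) + [
            ("affiliation_missing_rate", self.affiliation_missing_rate),
            ("aian_misclassification_rate", self.aian_misclassification_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"noise probability {name} out of [0, 1]: {p}")
        if sum(probs.values()) > 1.0 + 1e-12:
            raise ConfigError("perturbation probabilities sum to more than 1")

    def _perturbation_probs(self) -> dict[str, float]:
        return {
            "abbreviation_variant": self.abbreviation_variant,
            "spelling_typo": self.spelling_typo,
            "number_typo": self.number_typo,
            "zip_typo": self.zip_typo,
            "historical_street_alias": self.historical_street_alias,
            "po_box_substitution": self.po_box_substitution,
            "blank_address": self.blank_address,
            "numberless": self.numberless,
        }

    @classmethod
    def quiet(cls, seed: int = 0) -> "NoiseProfile":
        """All rates zero: the no-noise limit in which the pipeline must
        recover the planted truth exactly."""
        return cls(
            abbreviation_variant=0.0,
            spelling_typo=0.0,
            number_typo=0.0,
            zip_typo=0.0,
            historical_street_alias=0.0,
            po_box_substitution=0.0,
            blank_address=0.0,
            numberless=0.0,
            affiliation_missing_rate=0.0,
            aian_misclassification_rate=0.0,
            seed=seed,
        )


@dataclass(frozen=True)
class TruthRow:
    record_id: str
    is_community_resident: bool
    perturbations: tuple[str, ...]
    recoverable_by_rules: bool
    source_key: str  # reference key the address was drawn from


@dataclass
class ExtractFixture:
    """A generated extract with its per-record ground truth."""

    records: list[SurveillanceRecord]
    truth: dict[str, TruthRow]
    schema: SchemaMap

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_extract(self.records, out / "extract.csv", self.schema)
        pd.DataFrame(
            [
                {
                    "record_id": t.record_id,
                    "is_community_resident": t.is_community_resident,
                    "perturbations": ";".join(t.perturbations),
                    "recoverable_by_rules": t.recoverable_by_rules,
                    "source_key": t.source_key,
                }
                for t in sorted(self.truth.values(), key=lambda t: t.record_id)
            ]
        ).to_csv(out / "truth.csv", index=False)


_REVERSE_ABBREV = {v: k for k, v in ABBREVIATIONS.items()}

_PERTURBATIONS = (
    "abbreviation_variant",
    "spelling_typo",
    "number_typo",
    "zip_typo",
    "historical_street_alias",
    "po_box_substitution",
    "blank_address",
    "numberless",
    "none",
)


def _typo(name: str, rng: np.random.Generator) -> str:
    """One random edit (substitution, deletion or insertion) in a letter of
    the street name."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    pos = [i for i, ch in enumerate(name) if ch.isalpha()]
    if not pos:
        return name
    i = int(rng.choice(pos))
    op = int(rng.integers(3))
    if op == 0:  # substitute
        repl = letters[int(rng.integers(26))]
        while repl == name[i]:
            repl = letters[int(rng.integers(26))]
        return name[:i] + repl + name[i + 1 :]
    if op == 1:  # delete
        return name[:i] + name[i + 1 :]
    return name[:i] + letters[int(rng.integers(26))] + name[i:]  # insert


def _digit_typo(s: str, rng: np.random.Generator, max_pos: Optional[int] = None) -> str:
    pos = [i for i, ch in enumerate(s) if ch.isdigit()]
    if max_pos is not None:
        pos = pos[:max_pos]
    if not pos:
        return s
    i = int(rng.choice(pos))
    new = str(rng.integers(10))
    while new == s[i]:
        new = str(rng.integers(10))
    return s[:i] + new + s[i + 1 :]


def generate_extract(
    n_records: int,
    community_resident_fraction: float,
    noise_profile: NoiseProfile,
    reference: ReferenceFixture,
    schema: Optional[SchemaMap] = None,
    offsite_affiliated_fraction: float = 0.06,
) -> ExtractFixture:
    """Generate a line-list extract with planted truth.

    Exactly ``round(n_records · community_resident_fraction)`` records are
    community residents (deterministic allocation; positions shuffled by the
    seeded stream).  Community residents draw their address from community
    points, everyone else from ordinary non-community points (including any
    planted confusables).  At most one address perturbation is applied per
    record; affiliation and AI/AN race fields are populated with the
    configured missing/misclassification rates, plus a small off-community
    affiliated subpopulation.
    """
    if not 0.0 <= community_resident_fraction <= 1.0:
        raise ConfigError("community_resident_fraction must be in [0, 1]")
    schema = schema or case_extract_schema()
    rng = np.random.default_rng(noise_profile.seed)

    comm_pts = reference.community_points
    other_pts = [p for p in reference.points if not p.is_community]
    n_comm = int(round(n_records * community_resident_fraction))
    if n_comm > 0 and not comm_pts:
        raise ConfigError("community residents requested but reference has no community points")
    if n_comm < n_records and not other_pts:
        raise ConfigError("non-community residents requested but reference has none")

    is_comm = np.zeros(n_records, dtype=bool)
    is_comm[:n_comm] = True
    rng.shuffle(is_comm)

    probs = noise_profile._perturbation_probs()
    pvec = np.array([probs[p] for p in _PERTURBATIONS[:-1]] + [0.0])
    pvec[-1] = 1.0 - pvec[:-1].sum()

    records: list[SurveillanceRecord] = []
    truth: dict[str, TruthRow] = {}
    n_races = len(schema.race_cols)

    for i in range(n_records):
        rid = f"S{i:06d}"
        comm = bool(is_comm[i])
        pool = comm_pts if comm else other_pts
        pt = pool[int(rng.integers(len(pool)))]

        pert = _PERTURBATIONS[int(rng.choice(len(_PERTURBATIONS), p=pvec))]
        if pert == "historical_street_alias" and pt.street_name not in reference.alias_map:
            pert = "none"

        name = pt.street_name
        number: Optional[int] = pt.street_number
        zip5 = pt.zip
        street_override: Optional[str] = None
        if pert == "abbreviation_variant":
            toks = [(_REVERSE_ABBREV.get(t, t)) for t in name.split()]
            expanded = " ".join(toks)
            if expanded == name:
                pert = "none"
            else:
                name = expanded
        elif pert == "spelling_typo":
            name = _typo(name, rng)
        elif pert == "number_typo":
            number = int(_digit_typo(str(pt.street_number), rng))
            if number == pt.street_number:
                pert = "none"
        elif pert == "zip_typo":
            # hit one of the first 3 digits so even the prefix disagrees
            zip5 = _digit_typo(pt.zip, rng, max_pos=3)
        elif pert == "historical_street_alias":
            name = reference.alias_map[pt.street_name]
        elif pert == "po_box_substitution":
            street_override = f"PO BOX {int(rng.integers(1, 9999))}"
        elif pert == "blank_address":
            street_override = ""
        elif pert == "numberless":
            number = None

        if street_override is not None:
            raw_street = street_override
        elif number is None:
            raw_street = name
        else:
            raw_street = f"{number} {name}"
        if rng.random() < 0.5 and raw_street:
            raw_street = raw_street.title()

        affiliated = bool(
            rng.random() < (1.0 - noise_profile.affiliation_missing_rate)
            if comm
            else rng.random() < offsite_affiliated_fraction
        )
        aian_person = comm or affiliated
        races = [""] * n_races
        if aian_person and rng.random() >= noise_profile.aian_misclassification_rate:
            slot = int(rng.integers(n_races))
            races[slot] = _AIAN_VALUE
            for j in range(n_races):
                if j != slot and rng.random() < 0.2:
                    races[j] = "White"
        else:
            races[0] = _OTHER_RACES[int(rng.integers(len(_OTHER_RACES)))]

        records.append(
            SurveillanceRecord(
                record_id=rid,
                raw_street=raw_street,
                raw_zip=zip5,
                affiliation=_AFFILIATION_VALUE if affiliated else "",
                races=tuple(races),
                source_schema=schema.source_schema,
            )
        )
        truth[rid] = TruthRow(
            record_id=rid,
            is_community_resident=comm,
            perturbations=() if pert == "none" else (pert,),
            recoverable_by_rules=(pert == "historical_street_alias"),
            source_key=pt.key_str,
        )
    return ExtractFixture(records=records, truth=truth, schema=schema)


def read_truth(path: str | Path) -> dict[str, TruthRow]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        perts = tuple(p for p in row.perturbations.split(";") if p)
        out[row.record_id] = TruthRow(
            record_id=row.record_id,
            is_community_resident=row.is_community_resident in ("True", "true", "1"),
            perturbations=perts,
            recoverable_by_rules=row.recoverable_by_rules in ("True", "true", "1"),
            source_key=row.source_key,
        )
    return out
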