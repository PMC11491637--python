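"""Domain types and delimited-file I/O for surveillance line lists and
reference address points.

A surveillance extract is a line list: one row per case or per vaccine dose,
with a free-text street address, a zip code, an optional affiliation field
(e.g. a tribal-affiliation or reservation field) and one or more race fields.
A reference address file is the stand-in for a county GIS address-point
layer: canonical street number / street name / zip with WGS84 coordinates
and a flag marking the points that define the community jurisdiction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, InputValidationError

#: Race-field values treated as American Indian / Alaska Native, compared
#: case-insensitively after trimming.
DEFAULT_AIAN_CODES = frozenset(
    {
        "AMERICAN INDIAN OR ALASKA NATIVE",
        "AMERICAN INDIAN/ALASKA NATIVE",
        "AMERICAN INDIAN AND ALASKA NATIVE",
        "AMERICAN INDIAN",
        "ALASKA NATIVE",
        "AI/AN",
        "AIAN",
    }
)

#: Affiliation values that count as "no affiliation recorded".  Source
#: surveillance systems do not document their null conventions, so this is
#: a configurable construct of the toolkit.
DEFAULT_NULL_TOKENS = frozenset({"", "UNKNOWN", "NA", "NONE"})


@dataclass(frozen=True)
class SchemaMap:
    """Column mapping for one extract schema.

    ``affiliation_col`` may name a column that is absent from a particular
    file (the vaccination system has a Reservation field only; other systems
    may lack the field entirely): absent columns yield empty affiliations
    rather than an error.  Street and zip columns are mandatory.
    """

    street_col: str
    zip_col: str
    race_cols: tuple[str, ...]
    affiliation_col: Optional[str] = None
    id_col: Optional[str] = None
    source_schema: str = "custom"
    aian_codes: frozenset[str] = DEFAULT_AIAN_CODES

    def __post_init__(self) -> None:
        if not self.street_col or not self.zip_col:
            raise ConfigError("SchemaMap requires street and zip columns")
        if not self.race_cols:
            raise ConfigError("SchemaMap requires at least one race column")
        object.__setattr__(
            self, "aian_codes", frozenset(c.strip().upper() for c in self.aian_codes)
        )

    def to_dict(self) -> dict:
        return {
            "street_col": self.street_col,
            "zip_col": self.zip_col,
            "race_cols": list(self.race_cols),
            "affiliation_col": self.affiliation_col,
            "id_col": self.id_col,
            "source_schema": self.source_schema,
            "aian_codes": sorted(self.aian_codes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SchemaMap":
        return cls(
            street_col=d["street_col"],
            zip_col=d["zip_col"],
            race_cols=tuple(d["race_cols"]),
            affiliation_col=d.get("affiliation_col"),
            id_col=d.get("id_col"),
            source_schema=d.get("source_schema", "custom"),
            aian_codes=frozenset(d.get("aian_codes", DEFAULT_AIAN_CODES)),
        )


def case_extract_schema() -> SchemaMap:
    """Schema of a disease-surveillance (case) extract: home address, home
    zip, a tribal-affiliation field, and three race columns (the source
    system initially allowed one race and later several)."""
    return SchemaMap(
        street_col="Patient Home Street Address",
        zip_col="Patient Home Zip Code",
        affiliation_col="Tribal Affiliation",
        race_cols=("Race 1", "Race 2", "Race 3"),
        id_col="Record ID",
        source_schema="case_extract",
    )


def vaccination_extract_schema() -> SchemaMap:
    """Schema of an immunization (dose-level) extract: mailing address,
    zip, a Reservation field standing in for affiliation, and two
    single-race columns."""
    return SchemaMap(
        street_col="Patient Mailing Address",
        zip_col="Patient Zip Code",
        affiliation_col="Reservation",
        race_cols=("Race 1", "Race 2"),
        id_col="Record ID",
        source_schema="vaccination_extract",
    )


_SCHEMA_PRESETS = {
    "case_extract": case_extract_schema,
    "vaccination_extract": vaccination_extract_schema,
}


def schema_by_name(name: str) -> SchemaMap:
    try:
        return _SCHEMA_PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown schema preset {name!r}; expected one of {sorted(_SCHEMA_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SurveillanceRecord:
    """One line-list row (one case, or one administered dose)."""

    record_id: str
    raw_street: str
    raw_zip: str
    affiliation: str = ""
    races: tuple[str, ...] = ()
    source_schema: str = "custom"
    event_date: Optional[str] = None


@dataclass(frozen=True, order=True)
class ReferenceAddressPoint:
    """A canonical address point with WGS84 coordinates.

    The key ``(street_number, street_name, zip)`` is unique within a
    reference file; ``is_community`` marks the points whose residents
    belong to the jurisdiction being extracted.
    """

    street_number: int
    street_name: str
    zip: str
    lon: float
    lat: float
    is_community: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise InputValidationError(
                f"coordinate out of range for {self.key}: lon={self.lon}, lat={self.lat}"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.street_number, self.street_name, self.zip)

    @property
    def key_str(self) -> str:
        return f"{self.street_number}|{self.street_name}|{self.zip}"


def parse_key_str(s: str) -> tuple[int, str, str]:
    number, name, zip5 = s.split("|")
    return (int(number), name, zip5)


def read_extract(path: str | Path, schema_map: SchemaMap) -> list[SurveillanceRecord]:
    """Read a delimited extract into records, one per row, order preserved.

    Missing cells become empty strings; no row is ever dropped here (removal
    of blank/PO-box/numberless addresses is a later, counted stage).  An
    absent affiliation column is tolerated; an absent street or zip column
    is a configuration error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except OSError:
        raise
    for col, label in ((schema_map.street_col, "street"), (schema_map.zip_col, "zip")):
        if col not in df.columns:
            raise ConfigError(f"extract {path} is missing the mapped {label} column {col!r}")

    def cell(row, col):
        return str(row[col]).strip() if col is not None and col in df.columns else ""

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rid = cell(row, schema_map.id_col) or f"R{i:06d}"
        races = tuple(cell(row, c) for c in schema_map.race_cols)
        records.append(
            SurveillanceRecord(
                record_id=rid,
                raw_street=cell(row, schema_map.street_col),
                raw_zip=cell(row, schema_map.zip_col),
                affiliation=cell(row, schema_map.affiliation_col),
                races=races,
                source_schema=schema_map.source_schema,
                event_date=cell(row, "Event Date") or None,
            )
        )
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise InputValidationError(f"duplicate record ids in extract {path}")
    return records


def write_extract(records: Sequence[SurveillanceRecord], path: str | Path, schema_map: SchemaMap) -> None:
    """Write records back out in the schema's column layout (round-trips
    with :func:`read_extract`)."""
    rows = []
    has_date = any(r.event_date for r in records)
    for r in records:
        row = {
            schema_map.id_col or "Record ID": r.record_id,
            schema_map.street_col: r.raw_street,
            schema_map.zip_col: r.raw_zip,
        }
        if schema_map.affiliation_col:
            row[schema_map.affiliation_col] = r.affiliation
        for col, val in zip(schema_map.race_cols, r.races):
            row[col] = val
        if has_date:
            row["Event Date"] = r.event_date or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _clean_zip(z: str) -> str:
    digits = "".join(ch for ch in str(z) if ch.isdigit())
    return digits[:5] if len(digits) in (5, 9) else str(z).strip()


def read_reference(path: str | Path) -> list[ReferenceAddressPoint]:
    """Read a reference address-point file (CSV, or GeoJSON point features).

    The list is deduplicated on the (number, name, zip) key; the same key
    appearing with conflicting coordinates or community flags is a
    validation error.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        rows = _geojson_rows(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"street_number", "street_name", "zip", "lon", "lat", "is_community"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"reference {path} is missing columns {sorted(missing)}")
        rows = df.to_dict("records")

    seen: dict[tuple, ReferenceAddressPoint] = {}
    for i, row in enumerate(rows):
        try:
            pt = ReferenceAddressPoint(
                street_number=int(str(row["street_number"]).strip()),
                street_name=str(row["street_name"]).strip().upper(),
                zip=_clean_zip(row["zip"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                is_community=_parse_bool(row["is_community"]),
            )
        except (ValueError, TypeError) as exc:
            raise InputValidationError(f"bad reference row {i} in {path}: {row!r}") from exc
        prev = seen.get(pt.key)
        if prev is None:
            seen[pt.key] = pt
        elif prev != pt:
            raise InputValidationError(
                f"duplicate reference address {pt.key} with conflicting attributes in {path}"
            )
    return sorted(seen.values())


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no", ""}:
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _geojson_rows(path: Path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise InputValidationError(f"non-point geometry in {path}")
        lon, lat = geom["coordinates"][:2]
        props = dict(feat.get("properties") or {})
        props["lon"], props["lat"] = lon, lat
        rows.append(props)
    return rows


def write_reference(points: Iterable[ReferenceAddressPoint], path: str | Path) -> None:
    path = Path(path)
    pts = sorted(points)
    if path.suffix.lower() in {".json", ".geojson"}:
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                    "properties": {
                        "street_number": p.street_number,
                        "street_name": p.street_name,
                        "zip": p.zip,
                        "is_community": p.is_community,
                    },
                }
                for p in pts
            ],
        }
        with open(path, "w") as fh:
            json.dump(gj, fh, indent=1, sort_keys=True)
    else:
        pd.DataFrame(
            [
                {
                    "street_number": p.street_number,
                    "street_name": p.street_name,
                    "zip": p.zip,
                    "lon": repr(p.lon),
                    "lat": repr(p.lat),
                    "is_community": p.is_community,
                }
                for p in pts
            ]
        ).to_csv(path, index=False)


def is_aian(record: SurveillanceRecord, schema_map: SchemaMap) -> bool:
    """True iff ANY race field matches an AI/AN code (case-insensitive,
    trimmed) — single and multiple-race selections are both honored."""
    return any(r.strip().upper() in schema_map.aian_codes for r in record.races)


def affiliation_present(
    record: SurveillanceRecord, null_tokens: frozenset[str] = DEFAULT_NULL_TOKENS
) -> bool:
    """An affiliation is present iff non-empty after trimming and not in the
    configured null-token set."""
    return record.affiliation.strip().upper() not in {t.upper() for t in null_tokens}


@dataclass(frozen=True)
class MatchResult:
    """Per-record pipeline outcome: how (if at all) the record was matched
    to the community, with score/distance evidence and final category."""

    record_id: str
    method: Optional[str]  # "geocode" | "keyword" | None
    on_community: bool
    score: Optional[float] = None
    distance_feet: Optional[float] = None
    nearest_key: Optional[str] = None
    category: Optional[str] = None
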