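"""End-to-end extract workflow.

One call runs the whole flow: parse → standardize → geocode → buffer join →
exclusions → keyword fallback → classify → report, with stage counts
conserved and logged, and every artifact written to the output directory.
Everything is offline: the only inputs are the files named in the
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import ConfigError
from .geocode import (
    DEFAULT_MIN_SCORE,
    DEFAULT_WEIGHTS,
    GeocodeMatch,
    build_index,
    geocode,
)
from .keywords import FallbackOutcome, KeywordSet, confirm_flagged, emit_review_queue, flag_by_keyword
from .normalize import EMPTY_RULESET, Geocodability, ParsedAddress, RuleSet, parse_address, standardize
from .records import (
    DEFAULT_AIAN_CODES,
    DEFAULT_NULL_TOKENS,
    MatchResult,
    ReferenceAddressPoint,
    SchemaMap,
    SurveillanceRecord,
    affiliation_present,
    is_aian,
    read_extract,
    read_reference,
    schema_by_name,
)
from .report import (
    JurisdictionReport,
    RecordCategory,
    classify_record,
    summarize,
)
from .spatial import DEFAULT_BUFFER_FEET, CommunityIndex, apply_exclusions, within_buffer

logger = logging.getLogger("commaddr")


class PipelineConfig(BaseModel):
    """Serializable run configuration.

    Defaults reproduce the method's standing parameters: minimum match
    score 85 (inclusive) and a 150-ft join buffer.  The configuration
    round-trips through JSON unchanged, and its hash is embedded in every
    output for provenance.
    """

    extract_path: Optional[str] = None
    reference_path: Optional[str] = None
    community_path: Optional[str] = None
    rules_path: Optional[str] = None
    keywords_path: Optional[str] = None
    exclusions_path: Optional[str] = None
    out_dir: Optional[str] = None
    schema_name: str = "case_extract"
    schema_custom: Optional[dict] = None
    min_score: float = DEFAULT_MIN_SCORE
    buffer_feet: float = DEFAULT_BUFFER_FEET
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    aian_codes: list[str] = Field(default_factory=lambda: sorted(DEFAULT_AIAN_CODES))
    null_tokens: list[str] = Field(default_factory=lambda: sorted(DEFAULT_NULL_TOKENS))
    apply_rules: bool = True
    seed: int = 0

    @field_validator("min_score")
    @classmethod
    def _score_in_range(cls, v: float) -> float:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"min_score must be in [0, 100], got {v}")
        return v

    @field_validator("buffer_feet")
    @classmethod
    def _buffer_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"buffer_feet must be non-negative, got {v}")
        return v

    def schema_map(self) -> SchemaMap:
        if self.schema_custom:
            d = dict(self.schema_custom)
            d.setdefault("aian_codes", self.aian_codes)
            return SchemaMap.from_dict(d)
        base = schema_by_name(self.schema_name)
        return replace(base, aian_codes=frozenset(self.aian_codes))

    def config_hash(self) -> str:
        # hash the method parameters and inputs, not the output location
        payload = json.dumps(
            self.model_dump(exclude={"out_dir"}), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=1, sort_keys=True, default=list)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, in memory."""

    record_ids: tuple[str, ...]
    parsed: dict[str, ParsedAddress]
    geocode_matches: dict[str, GeocodeMatch]
    match_results: dict[str, MatchResult]
    fallback_outcomes: list[FallbackOutcome]
    categories: dict[str, RecordCategory]
    aian_flags: dict[str, bool]
    affiliation_flags: dict[str, bool]
    report: JurisdictionReport
    review_queue: pd.DataFrame
    stage_counts: dict[str, int]
    community_zips: set[str]
    config_hash: str = ""

    @property
    def n_nonblank(self) -> int:
        return self.stage_counts["input"] - self.stage_counts["blank"]

    @property
    def n_geocoder_input(self) -> int:
        return self.stage_counts["geocoder_input"]

    @property
    def n_geocoded(self) -> int:
        return self.stage_counts["geocoded"]

    @property
    def n_matches(self) -> int:
        return self.stage_counts["matches_total"]

    @property
    def n_matches_noncommunity_zip(self) -> int:
        return self.stage_counts["matches_noncommunity_zip"]

    def classified_frame(self, records: Mapping[str, SurveillanceRecord] | None = None) -> pd.DataFrame:
        rows = []
        for rid in self.record_ids:
            mr = self.match_results[rid]
            rows.append(
                {
                    "record_id": rid,
                    "match_method": mr.method or "",
                    "category": self.categories[rid].value,
                    "aian": self.aian_flags[rid],
                    "affiliation_present": self.affiliation_flags[rid],
                    "score": "" if mr.score is None else f"{mr.score:.6f}",
                    "distance_feet": "" if mr.distance_feet is None else f"{mr.distance_feet:.3f}",
                    "nearest_key": mr.nearest_key or "",
                }
            )
        return pd.DataFrame(rows)

    def matched_frame(self) -> pd.DataFrame:
        df = self.classified_frame()
        return df[df["category"].str.startswith("on_community")].reset_index(drop=True)


def run_stages(
    records: Sequence[SurveillanceRecord],
    reference_points: Sequence[ReferenceAddressPoint],
    rule_set: RuleSet = EMPTY_RULESET,
    keyword_set: Optional[KeywordSet] = None,
    exclusion_keys: Sequence[str] = (),
    schema_map: Optional[SchemaMap] = None,
    min_score: float = DEFAULT_MIN_SCORE,
    buffer_feet: float = DEFAULT_BUFFER_FEET,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    null_tokens: frozenset[str] = DEFAULT_NULL_TOKENS,
    apply_rules: bool = True,
) -> PipelineResult:
    """Run the full stage sequence in memory.

    ``apply_rules=False`` skips standardization entirely (correction rules
    and the abbreviation table), which is the "without address processing"
    arm of the evaluation report.
    """
    schema_map = schema_map or schema_by_name("case_extract")
    by_id = {r.record_id: r for r in records}
    record_ids = tuple(r.record_id for r in records)

    # parse + classify geocodability
    parsed: dict[str, ParsedAddress] = {}
    counts = {
        "input": len(records),
        "blank": 0,
        "po_box": 0,
        "numberless": 0,
        "geocoder_input": 0,
    }
    for r in records:
        p = parse_address(r.raw_street, r.raw_zip)
        if apply_rules and p.geocodability in (Geocodability.GEOCODABLE, Geocodability.NUMBERLESS):
            p = standardize(p, rule_set)
        parsed[r.record_id] = p
        if p.geocodability is Geocodability.GEOCODABLE:
            counts["geocoder_input"] += 1
        else:
            counts[p.geocodability.value] += 1

    # geocode
    index = build_index(reference_points)
    geocode_matches: dict[str, GeocodeMatch] = {}
    for rid in record_ids:
        p = parsed[rid]
        if p.geocodability is not Geocodability.GEOCODABLE:
            continue
        m = geocode(p, index, min_score=min_score, weights=weights)
        if m is not None:
            geocode_matches[rid] = replace(m, record_id=rid)
    counts["geocoded"] = len(geocode_matches)
    counts["non_geocoded"] = counts["geocoder_input"] - counts["geocoded"]

    # buffer join + exclusions
    community_points = [p for p in reference_points if p.is_community]
    community_zips = {p.zip for p in community_points}
    buffer_results = {}
    if community_points:
        cindex = CommunityIndex(community_points)
        raw_results = [
            within_buffer(
                m.matched_point.lon,
                m.matched_point.lat,
                cindex,
                buffer_feet,
                record_id=rid,
                matched_key=m.matched_point.key_str,
            )
            for rid, m in geocode_matches.items()
        ]
        reference_keys = {p.key_str for p in reference_points}
        buffer_results = {
            r.record_id: r
            for r in apply_exclusions(raw_results, exclusion_keys, reference_keys)
        }

    # keyword fallback: geocoder failures plus numberless addresses
    fallback_records = [
        by_id[rid]
        for rid in record_ids
        if (
            parsed[rid].geocodability is Geocodability.GEOCODABLE
            and rid not in geocode_matches
        )
        or parsed[rid].geocodability is Geocodability.NUMBERLESS
    ]
    counts["keyword_pool"] = len(fallback_records)
    outcomes: list[FallbackOutcome] = []
    if keyword_set is not None and fallback_records:
        flagged = flag_by_keyword(fallback_records, keyword_set)
        flagged_ids = set()
        for rec, kw in flagged:
            outcomes.append(
                confirm_flagged(rec.record_id, parsed[rec.record_id], kw, community_points)
            )
            flagged_ids.add(rec.record_id)
        outcomes.extend(
            FallbackOutcome(r.record_id, False, False)
            for r in fallback_records
            if r.record_id not in flagged_ids
        )
    else:
        outcomes = [FallbackOutcome(r.record_id, False, False) for r in fallback_records]
    confirmed_ids = {o.record_id for o in outcomes if o.confirmed}
    counts["keyword_flagged"] = sum(o.flagged for o in outcomes)
    counts["keyword_confirmed"] = len(confirmed_ids)
    counts["review_queue"] = sum(o.flagged and not o.confirmed for o in outcomes)

    # classification
    match_results: dict[str, MatchResult] = {}
    categories: dict[str, RecordCategory] = {}
    aian_flags: dict[str, bool] = {}
    affil_flags: dict[str, bool] = {}
    nulls = frozenset(null_tokens)
    n_noncomm_zip = 0
    for rid in record_ids:
        rec = by_id[rid]
        affil = affiliation_present(rec, nulls)
        aian = is_aian(rec, schema_map)
        gm = geocode_matches.get(rid)
        br = buffer_results.get(rid)
        on_comm = False
        method = None
        if br is not None and br.within:
            on_comm = True
            method = "geocode"
        elif rid in confirmed_ids:
            on_comm = True
            method = "keyword"
        if on_comm and parsed[rid].zip is not None and parsed[rid].zip not in community_zips:
            n_noncomm_zip += 1
        cat = classify_record(on_comm, affil)
        categories[rid] = cat
        aian_flags[rid] = aian
        affil_flags[rid] = affil
        match_results[rid] = MatchResult(
            record_id=rid,
            method=method,
            on_community=on_comm,
            score=gm.score if gm is not None else None,
            distance_feet=br.distance_feet if br is not None else None,
            nearest_key=br.nearest_community_key if br is not None else None,
            category=cat.value,
        )
    counts["matches_geocode"] = sum(
        1 for mr in match_results.values() if mr.method == "geocode"
    )
    counts["matches_keyword"] = sum(
        1 for mr in match_results.values() if mr.method == "keyword"
    )
    counts["matches_total"] = counts["matches_geocode"] + counts["matches_keyword"]
    counts["matches_noncommunity_zip"] = n_noncomm_zip

    # conservation identities (logged and enforced)
    assert (
        counts["input"]
        == counts["blank"] + counts["po_box"] + counts["numberless"]
        + counts["geocoded"] + counts["non_geocoded"]
    )
    assert counts["keyword_pool"] == counts["non_geocoded"] + counts["numberless"]

    report = summarize(categories, aian_flags)
    review_queue = emit_review_queue(outcomes, by_id)
    logger.info("stage counts: %s", counts)
    return PipelineResult(
        record_ids=record_ids,
        parsed=parsed,
        geocode_matches=geocode_matches,
        match_results=match_results,
        fallback_outcomes=outcomes,
        categories=categories,
        aian_flags=aian_flags,
        affiliation_flags=affil_flags,
        report=report,
        review_queue=review_queue,
        stage_counts=counts,
        community_zips=community_zips,
    )


def _load_exclusions(path: Optional[str]) -> list[str]:
    if not path:
        return []
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "key" not in df.columns:
        raise ConfigError(f"exclusion list {path} must have a 'key' column")
    return list(df["key"])


def _load_community_override(points, path: Optional[str]):
    """Optionally override the reference file's community flags with an
    explicit community address list (CSV of reference keys)."""
    if not path:
        return points
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "key" not in df.columns:
        raise ConfigError(f"community list {path} must have a 'key' column")
    keys = set(df["key"])
    return [replace(p, is_community=(p.key_str in keys)) for p in points]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load all configured inputs, run the stages, and (when an output
    directory is configured) write the artifacts: the matched-record
    extract, the full classified extract, the manual-review queue, the
    jurisdiction report (CSV and JSON) and a machine-readable run summary
    with stage counts, versions and the configuration hash."""
    if not config.extract_path or not config.reference_path:
        raise ConfigError("extract_path and reference_path are required")
    schema_map = config.schema_map()
    records = read_extract(config.extract_path, schema_map)
    points = read_reference(config.reference_path)
    points = _load_community_override(points, config.community_path)
    rule_set = RuleSet.from_json(config.rules_path) if config.rules_path else EMPTY_RULESET
    keyword_set = KeywordSet.from_json(config.keywords_path) if config.keywords_path else None
    exclusions = _load_exclusions(config.exclusions_path)

    result = run_stages(
        records,
        points,
        rule_set=rule_set,
        keyword_set=keyword_set,
        exclusion_keys=exclusions,
        schema_map=schema_map,
        min_score=config.min_score,
        buffer_feet=config.buffer_feet,
        weights=tuple(config.weights),
        null_tokens=frozenset(config.null_tokens),
        apply_rules=config.apply_rules,
    )
    result.config_hash = config.config_hash()
    if config.out_dir:
        write_artifacts(result, records, config)
    return result


def write_artifacts(
    result: PipelineResult, records: Sequence[SurveillanceRecord], config: PipelineConfig
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.matched_frame().to_csv(out / "matched_extract.csv", index=False)
    result.classified_frame().to_csv(out / "classified.csv", index=False)
    result.review_queue.to_csv(out / "review_queue.csv", index=False)
    result.report.to_frame().to_csv(out / "jurisdiction_report.csv", index=False)
    with open(out / "jurisdiction_report.json", "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=1, sort_keys=True)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": result.config_hash,
                "stage_counts": result.stage_counts,
                "n_records": len(records),
                "seed": config.seed,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def evaluate_against_truth(result: PipelineResult, truth: Mapping[str, "object"]) -> dict:
    """Recall and precision of the on-community classification against the
    planted truth of a synthetic extract."""
    tp = fp = fn = 0
    for rid in result.record_ids:
        pred = result.categories[rid] in (
            RecordCategory.ON_COMMUNITY_WITH_AFFILIATION,
            RecordCategory.ON_COMMUNITY_WITHOUT_AFFILIATION,
        )
        actual = truth[rid].is_community_resident
        if pred and actual:
            tp += 1
        elif pred and not actual:
            fp += 1
        elif actual and not pred:
            fn += 1
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    return {"tp": tp, "fp": fp, "fn": fn, "recall": recall, "precision": precision}
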