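"""Per-record stewardship rubric: granularity parsing, origin, completeness.

This is the audit's core. Each assembly record is scored on three axes:

* **temporal granularity** — the finest calendar precision recoverable from
  its ``collection_date`` attribute (none < year < month < day);
* **spatial granularity** — the finest location resolution recoverable from
  ``geo_loc_name`` / ``lat_lon`` (none < country < region/city < coordinates);
* **sample origin** — field, laboratory, commercial, managed colony, or
  unknown, decided by an ordered keyword vocabulary over the free-text
  provenance attributes.

A record is *complete* when its collection status is known (origin is not
unknown), its location resolves to at least country level, and its collection
date to at least the year. Records whose attributes leave the origin unknown
can be rescued by literature-backed overrides; attribute-derived
classifications always outrank overrides.

Parsing never hard-fails on malformed values: unparseable tokens degrade the
granularity and emit a parse warning so curation debt stays visible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .countries import normalize_country
from .errors import ValidationError
from .records import (
    AssemblyRecord,
    OriginClass,
    OverrideEntry,
    PartialDate,
    SampleAttributes,
    SpatialGranularity,
    TemporalGranularity,
)

__all__ = [
    "OriginVocabulary",
    "StewardshipAssessment",
    "RescueReport",
    "apply_overrides",
    "assess_completeness",
    "assess_record",
    "classify_origin",
    "is_null_token",
    "null_tokens",
    "parse_collection_date",
    "parse_location",
]


# --------------------------------------------------------------------------
# INSDC null tokens
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def null_tokens() -> frozenset[str]:
    path = resources.files("invaudit.data").joinpath("insdc_null_tokens.txt")
    tokens = set()
    with path.open("r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                tokens.add(line.casefold())
    return frozenset(tokens)


def is_null_token(value: str | None) -> bool:
    """True when a value is absent, empty, or an INSDC null placeholder."""
    if value is None:
        return True
    return value.strip().casefold() in null_tokens() or not value.strip()


# --------------------------------------------------------------------------
# Temporal parsing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalParse:
    granularity: TemporalGranularity
    date: PartialDate | None = None
    warnings: tuple[str, ...] = ()


_MONTHS = {
    name: i + 1
    for i, name in enumerate(
        "jan feb mar apr may jun jul aug sep oct nov dec".split()
    )
}

_ISO_DT_RE = re.compile(
    r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?(?:[T ].*)?$"
)
_DMY_RE = re.compile(r"^(?:(\d{1,2})-)?([A-Za-z]{3})-(\d{4})$")


def _parse_single_date(text: str) -> PartialDate | None:
    """One date token at whatever precision it carries; None if unparseable.

    Accepts ISO 8601 partial dates (optionally with a time part, which is
    discarded) and the INSDC Mon-YYYY / DD-Mon-YYYY spellings.
    """
    text = text.strip()
    m = _ISO_DT_RE.match(text)
    if m:
        y, mo, d = m.groups()
        try:
            return PartialDate(int(y), int(mo) if mo else None, int(d) if d else None)
        except ValidationError:
            return None
    m = _DMY_RE.match(text)
    if m:
        d, mon, y = m.groups()
        month = _MONTHS.get(mon.casefold())
        if month is None:
            return None
        try:
            return PartialDate(int(y), month, int(d) if d else None)
        except ValidationError:
            return None
    return None


def parse_collection_date(raw: str | None) -> TemporalParse:
    """Temporal granularity of a collection_date attribute.

    Null tokens and absent values map to granularity ``none``; a date range
    (``A/B``) resolves to its earliest bound; an unparseable non-null token
    degrades to ``none`` with a warning, never a hard failure.
    """
    if is_null_token(raw):
        return TemporalParse(TemporalGranularity.NONE)
    text = raw.strip()  # type: ignore[union-attr]
    warnings: tuple[str, ...] = ()
    if "/" in text:
        bounds = [_parse_single_date(part) for part in text.split("/")]
        parsed = [b for b in bounds if b is not None]
        if len(parsed) < len(bounds):
            warnings = (f"partially unparseable date range: {text!r}",)
        if not parsed:
            return TemporalParse(
                TemporalGranularity.NONE,
                warnings=(f"unparseable collection_date: {text!r}",),
            )
        earliest = min(parsed, key=PartialDate.sort_key)
        return TemporalParse(earliest.granularity, earliest, warnings)
    date = _parse_single_date(text)
    if date is None:
        return TemporalParse(
            TemporalGranularity.NONE,
            warnings=(f"unparseable collection_date: {text!r}",),
        )
    return TemporalParse(date.granularity, date)


# --------------------------------------------------------------------------
# Spatial parsing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LocationParse:
    granularity: SpatialGranularity
    country_code: str | None = None
    country_name: str = ""
    country_recognized: bool = False
    region: str = ""
    latitude: float | None = None
    longitude: float | None = None
    warnings: tuple[str, ...] = ()


_LATLON_HEMI_RE = re.compile(
    r"^(\d+(?:\.\d+)?)\s*([NS])[,;]?\s+(\d+(?:\.\d+)?)\s*([EW])$", re.IGNORECASE
)
_LATLON_SIGNED_RE = re.compile(
    r"^([+-]?\d+(?:\.\d+)?)[,;\s]\s*([+-]?\d+(?:\.\d+)?)$"
)


def _parse_lat_lon(text: str) -> tuple[float, float] | None:
    """Decimal-degree pair from the two common INSDC spellings.

    Hemisphere form ``30.61 N 96.34 W`` or a signed pair ``30.61, -96.34``;
    degrees-minutes-seconds is deliberately not accepted.
    """
    text = text.strip()
    m = _LATLON_HEMI_RE.match(text)
    if m:
        lat = float(m.group(1)) * (1 if m.group(2).upper() == "N" else -1)
        lon = float(m.group(3)) * (1 if m.group(4).upper() == "E" else -1)
    else:
        m = _LATLON_SIGNED_RE.match(text)
        if m is None:
            return None
        lat, lon = float(m.group(1)), float(m.group(2))
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        return None
    return lat, lon


def parse_location(
    geo_loc_name: str | None, lat_lon: str | None
) -> LocationParse:
    """Spatial granularity from geo_loc_name and lat_lon attributes.

    A valid coordinate pair always yields the top level. Otherwise the INSDC
    ``Country: region, locality`` convention applies: any non-empty text after
    the country separator counts as region/city resolution, a recognizable
    bare country as country resolution, anything else as none.
    """
    warnings: list[str] = []
    coords: tuple[float, float] | None = None
    if not is_null_token(lat_lon):
        coords = _parse_lat_lon(lat_lon)  # type: ignore[arg-type]
        if coords is None:
            warnings.append(f"malformed lat_lon: {lat_lon!r}")

    country_code: str | None = None
    country_name = ""
    recognized = False
    region = ""
    geo_level = SpatialGranularity.NONE
    if not is_null_token(geo_loc_name):
        text = geo_loc_name.strip()  # type: ignore[union-attr]
        country_part, _, remainder = text.partition(":")
        match = normalize_country(country_part)
        country_code, country_name, recognized = (
            match.code,
            match.name,
            match.recognized,
        )
        region = remainder.strip()
        if region:
            geo_level = SpatialGranularity.REGION_CITY
            if not recognized:
                warnings.append(f"unrecognized country name: {country_part.strip()!r}")
        elif recognized:
            geo_level = SpatialGranularity.COUNTRY
        else:
            warnings.append(f"unrecognized geo_loc_name: {text!r}")

    if coords is not None:
        return LocationParse(
            SpatialGranularity.COORDINATES,
            country_code,
            country_name,
            recognized,
            region,
            coords[0],
            coords[1],
            tuple(warnings),
        )
    return LocationParse(
        geo_level,
        country_code,
        country_name,
        recognized,
        region,
        warnings=tuple(warnings),
    )


# --------------------------------------------------------------------------
# Origin classification
# --------------------------------------------------------------------------

# Precedence on multi-category keyword matches: a commercial or laboratory
# token indicates captive propagation regardless of founder provenance, so
# captive classes outrank field; conflicts are flagged, never silently lost.
ORIGIN_PRECEDENCE = (
    OriginClass.COMMERCIAL,
    OriginClass.LABORATORY,
    OriginClass.MANAGED_COLONY,
    OriginClass.FIELD,
)

#: Attribute keys scanned for origin-bearing free text.
ORIGIN_KEYS = ("isolation_source", "strain", "isolate", "sample_name")


class OriginVocabulary:
    """Editable keyword lexicon mapping free text to origin classes.

    Keywords are matched case-insensitively on word boundaries; multi-word
    phrases match as literal sequences. The packaged default lives in
    ``data/origin_vocab.tsv`` and can be replaced per run so the rubric stays
    auditable.
    """

    def __init__(self, keywords: dict[OriginClass, tuple[str, ...]]):
        self.keywords = keywords
        self._patterns = {
            category: re.compile(
                "|".join(
                    r"(?<![A-Za-z])" + re.escape(kw) + r"(?![A-Za-z])"
                    for kw in sorted(words, key=len, reverse=True)
                ),
                re.IGNORECASE,
            )
            for category, words in keywords.items()
            if words
        }

    @classmethod
    def from_tsv(cls, path: Path | str) -> "OriginVocabulary":
        grouped: dict[OriginClass, list[str]] = {}
        with open(path, encoding="utf-8") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                category = OriginClass(row["category"])
                if category is OriginClass.UNKNOWN:
                    raise ValidationError("vocabulary may not define 'unknown' keywords")
                grouped.setdefault(category, []).append(row["keyword"].strip())
        return cls({c: tuple(ws) for c, ws in grouped.items()})

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "OriginVocabulary":
        with resources.as_file(
            resources.files("invaudit.data").joinpath("origin_vocab.tsv")
        ) as path:
            return cls.from_tsv(path)

    def matches(self, text: str) -> set[OriginClass]:
        return {
            category
            for category, pattern in self._patterns.items()
            if pattern.search(text)
        }


def classify_origin(
    attributes: SampleAttributes,
    vocabulary: OriginVocabulary | None = None,
) -> tuple[OriginClass, bool]:
    """Classify sample origin from provenance attributes.

    Returns the class and a conflict flag. Keyword matches in two or more
    distinct categories resolve to the highest-precedence class with the flag
    set; no match at all yields ``unknown``. Total: never raises.
    """
    vocab = vocabulary or OriginVocabulary.default()
    matched: set[OriginClass] = set()
    for key in ORIGIN_KEYS:
        value = attributes.get(key)
        if is_null_token(value):
            continue
        matched |= vocab.matches(value)  # type: ignore[arg-type]
    if not matched:
        return OriginClass.UNKNOWN, False
    for category in ORIGIN_PRECEDENCE:
        if category in matched:
            return category, len(matched) > 1
    return OriginClass.UNKNOWN, False  # pragma: no cover - precedence is total


# --------------------------------------------------------------------------
# Completeness and per-record assessment
# --------------------------------------------------------------------------

def assess_completeness(
    origin: OriginClass,
    spatial: SpatialGranularity,
    temporal: TemporalGranularity,
) -> bool:
    """Spatiotemporally complete: known collection status, location to at
    least country, collection date to at least year."""
    return (
        origin is not OriginClass.UNKNOWN
        and spatial >= SpatialGranularity.COUNTRY
        and temporal >= TemporalGranularity.YEAR
    )


@dataclass(frozen=True)
class StewardshipAssessment:
    """Rubric outcome for one assembly record."""

    accession: str
    origin: OriginClass
    origin_source: str  # "attributes" | "override" | "unresolved"
    conflict_flag: bool
    spatial: SpatialGranularity
    spatial_country_code: str | None
    spatial_country: str
    spatial_region: str
    latitude: float | None
    longitude: float | None
    temporal: TemporalGranularity
    collection_date: PartialDate | None
    has_tissue: bool
    has_dev_stage: bool
    has_sex: bool
    complete: bool
    warnings: tuple[str, ...] = field(default=())


def assess_record(
    record: AssemblyRecord,
    vocabulary: OriginVocabulary | None = None,
) -> StewardshipAssessment:
    """Run the full rubric on one record (deterministic, never fails)."""
    attrs = record.attributes
    loc = parse_location(attrs.get("geo_loc_name"), attrs.get("lat_lon"))
    temp = parse_collection_date(attrs.get("collection_date"))
    origin, conflict = classify_origin(attrs, vocabulary)
    return StewardshipAssessment(
        accession=record.accession,
        origin=origin,
        origin_source="unresolved" if origin is OriginClass.UNKNOWN else "attributes",
        conflict_flag=conflict,
        spatial=loc.granularity,
        spatial_country_code=loc.country_code,
        spatial_country=loc.country_name,
        spatial_region=loc.region,
        latitude=loc.latitude,
        longitude=loc.longitude,
        temporal=temp.granularity,
        collection_date=temp.date,
        has_tissue=not is_null_token(attrs.get("tissue")),
        has_dev_stage=not is_null_token(attrs.get("dev_stage")),
        has_sex=not is_null_token(attrs.get("sex")),
        complete=assess_completeness(origin, loc.granularity, temp.granularity),
        warnings=loc.warnings + temp.warnings,
    )


# --------------------------------------------------------------------------
# Literature rescue
# --------------------------------------------------------------------------

@dataclass
class RescueReport:
    """Outcome of applying an origin override table to a cohort."""

    reclassified_to_field: int = 0
    reclassified_to_nonfield: int = 0  # laboratory / commercial / managed colony
    remaining_unknown: int = 0
    skipped: list[tuple[OverrideEntry, str]] = field(default_factory=list)


def apply_overrides(
    records: list[AssemblyRecord],
    assessments: list[StewardshipAssessment],
    overrides: list[OverrideEntry],
) -> tuple[list[StewardshipAssessment], RescueReport]:
    """Apply literature-backed origin overrides to unknown-origin records.

    Conservative by construction: attribute-derived classifications outrank
    literature, so an override targeting a non-unknown record is skipped with
    a warning, as is one whose accession is absent from the cohort. Range
    overrides are not consumed here (see the range classifier).
    """
    if len(records) != len(assessments):
        raise ValidationError("records and assessments are misaligned")
    index = {record.accession: i for i, record in enumerate(records)}
    updated = list(assessments)
    report = RescueReport()
    for entry in overrides:
        if entry.field != "origin":
            continue
        pos = index.get(entry.accession)
        if pos is None:
            report.skipped.append((entry, "accession not in cohort"))
            continue
        current = updated[pos]
        if current.origin is not OriginClass.UNKNOWN:
            report.skipped.append((entry, "origin already resolved from attributes"))
            continue
        origin = OriginClass(entry.value)
        updated[pos] = replace(
            current,
            origin=origin,
            origin_source="override",
            complete=assess_completeness(origin, current.spatial, current.temporal),
        )
        if origin is OriginClass.FIELD:
            report.reclassified_to_field += 1
        else:
            report.reclassified_to_nonfield += 1
    report.remaining_unknown = sum(
        1 for a in updated if a.origin is OriginClass.UNKNOWN
    )
    return updated, report
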