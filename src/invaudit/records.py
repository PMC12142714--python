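"""Core domain types for the metadata stewardship audit.

The audit works on genome-assembly submission records: one
:class:`AssemblyRecord` per assembly, carrying the submission-level fields
(accession, species, assembly level, submitter, SRA linkage) together with the
verbatim sample attributes (`collection_date`, `geo_loc_name`, `lat_lon`, ...)
attached to the underlying biological sample. Classification outcomes use the
ordered granularity enums defined here: spatial resolution is ranked
none < country < region/city < coordinates, and temporal resolution
none < year < month < day.
"""

from __future__ import annotations

import datetime as _dt
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum, IntEnum

from .errors import ValidationError

__all__ = [
    "AssemblyLevel",
    "AssemblyRecord",
    "HomeRangeEntry",
    "IncomeGroup",
    "IncomeTable",
    "OriginClass",
    "OverrideEntry",
    "PartialDate",
    "RangeStatus",
    "SampleAttributes",
    "SpatialGranularity",
    "TemporalGranularity",
]


class AssemblyLevel(IntEnum):
    """Assembly completeness tier; ordered contig < scaffold < chromosome."""

    CONTIG = 1
    SCAFFOLD = 2
    CHROMOSOME = 3

    @classmethod
    def from_string(cls, token: str) -> "AssemblyLevel":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown assembly level: {token!r}") from None

    def __str__(self) -> str:  # canonical lowercase token for TSV output
        return self.name.lower()


class OriginClass(str, Enum):
    """Sample origin. Exhaustive and mutually exclusive per record."""

    FIELD = "field"
    LABORATORY = "laboratory"
    COMMERCIAL = "commercial"
    MANAGED_COLONY = "managed_colony"
    UNKNOWN = "unknown"

    def __str__(self) -> str:
        return self.value


class SpatialGranularity(IntEnum):
    """Finest spatial resolution recoverable from the record."""

    NONE = 0
    COUNTRY = 1
    REGION_CITY = 2
    COORDINATES = 3

    def __str__(self) -> str:
        return self.name.lower()


class TemporalGranularity(IntEnum):
    """Finest calendar precision recoverable from collection_date."""

    NONE = 0
    YEAR = 1
    MONTH = 2
    DAY = 3

    def __str__(self) -> str:
        return self.name.lower()


class RangeStatus(str, Enum):
    """Native/expanded status of a field-collected sample's location."""

    NATIVE = "native"
    EXPANDED = "expanded"
    UNDETERMINED = "undetermined"
    NOT_APPLICABLE = "not_applicable"  # non-field records

    def __str__(self) -> str:
        return self.value


class IncomeGroup(str, Enum):
    """World-Bank-style income grouping by GNI per capita threshold."""

    HIGH_INCOME = "high_income"
    OTHER = "other"
    UNRESOLVED = "unresolved"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to year, month or day precision.

    Used both for submission dates and for normalized collection dates, where
    submitters routinely provide only a year or a year-month.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValidationError("day precision requires a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValidationError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegates day-in-month validation (leap years etc.)
            _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    @property
    def granularity(self) -> TemporalGranularity:
        if self.day is not None:
            return TemporalGranularity.DAY
        if self.month is not None:
            return TemporalGranularity.MONTH
        return TemporalGranularity.YEAR

    def sort_key(self) -> tuple[int, int, int]:
        """Earliest-possible-instant ordering; missing parts count as 1."""
        return (self.year, self.month or 1, self.day or 1)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    _ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")

    @classmethod
    def from_iso(cls, text: str) -> "PartialDate":
        m = cls._ISO_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"not a partial ISO date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)


_KEY_RE = re.compile(r"[\s\-/]+")


def normalize_attribute_key(key: str) -> str:
    """Lower-case snake_case normalization, applied exactly once at ingest."""
    return _KEY_RE.sub("_", key.strip().lower())


class SampleAttributes(Mapping[str, str]):
    """Verbatim sample attribute map with normalized keys.

    Values are stored exactly as submitted, stripped of surrounding whitespace
    only; unrecognized keys are preserved. Recognized keys include
    collection_date, geo_loc_name, lat_lon, isolation_source, strain, isolate,
    tissue, dev_stage, sex and host.
    """

    RECOGNIZED = frozenset(
        {
            "collection_date",
            "geo_loc_name",
            "lat_lon",
            "isolation_source",
            "strain",
            "isolate",
            "tissue",
            "dev_stage",
            "sex",
            "host",
        }
    )

    __slots__ = ("_data",)

    def __init__(self, raw: Mapping[str, str] | None = None):
        data: dict[str, str] = {}
        for key, value in (raw or {}).items():
            data[normalize_attribute_key(key)] = str(value).strip()
        self._data = data

    def __getitem__(self, key: str) -> str:
        return self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"SampleAttributes({self._data!r})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, SampleAttributes):
            return self._data == other._data
        return NotImplemented

    def to_dict(self) -> dict[str, str]:
        return dict(self._data)


@dataclass(frozen=True)
class AssemblyRecord:
    """One genome assembly submission with its sample provenance."""

    accession: str
    species: str
    taxonomic_order: str
    assembly_level: AssemblyLevel
    submission_date: PartialDate
    submitter_institute: str
    submitter_country: str  # normalized country code, or "" when unresolved
    is_reference: bool
    sra_linked: bool
    attributes: SampleAttributes = field(default_factory=SampleAttributes)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")

    @property
    def submission_year(self) -> int:
        return self.submission_date.year


Region = tuple[str, str | None]  # (country code/name, optional admin region)


@dataclass(frozen=True)
class HomeRangeEntry:
    """Known native and expanded geography for one species.

    Regions are (country, admin) pairs with admin optional; a bare country on
    both sides is only legal when at least one side also carries admin-level
    qualifiers, which is how same-country native/expanded splits (e.g. a
    species native to Texas but invasive in California) are encoded.
    """

    species: str
    native_regions: frozenset[Region]
    expanded_regions: frozenset[Region]
    feral: bool = False

    def __post_init__(self) -> None:
        if not self.native_regions:
            raise ValidationError(f"{self.species}: native region set is empty")
        overlap = self.native_regions & self.expanded_regions
        if overlap:
            raise ValidationError(
                f"{self.species}: regions on both sides: {sorted(overlap)}"
            )

    def countries(self, side: str) -> set[str]:
        regions = self.native_regions if side == "native" else self.expanded_regions
        return {country for country, _ in regions}


_OVERRIDE_ORIGIN_VALUES = {c.value for c in OriginClass} - {"unknown"}
_OVERRIDE_RANGE_VALUES = {"native", "expanded", "undetermined"}


@dataclass(frozen=True)
class OverrideEntry:
    """A manual, literature-backed reclassification of one record.

    Models the curation step where a record's repository metadata is
    insufficient and the classification is rescued from an associated
    publication; an override without a citation is rejected.
    """

    accession: str
    field: str  # "origin" | "range"
    value: str
    evidence: str

    def __post_init__(self) -> None:
        if not self.evidence.strip():
            raise ValidationError(
                f"override for {self.accession}: evidence citation is empty"
            )
        if self.field == "origin":
            legal = _OVERRIDE_ORIGIN_VALUES
        elif self.field == "range":
            legal = _OVERRIDE_RANGE_VALUES
        else:
            raise ValidationError(
                f"override for {self.accession}: unknown field {self.field!r}"
            )
        if self.value not in legal:
            raise ValidationError(
                f"override for {self.accession}: illegal {self.field} "
                f"value {self.value!r}"
            )


@dataclass(frozen=True)
class IncomeTable:
    """Country code -> GNI per capita (USD), with a high-income cutoff.

    The default threshold of USD 12,055 is the World Bank high-income cutoff
    used to group submitter and collection countries; a country is high income
    iff its GNI per capita strictly exceeds the threshold.
    """

    gni: Mapping[str, float]
    threshold: float = 12055.0

    def __post_init__(self) -> None:
        bad = {c: v for c, v in self.gni.items() if not v > 0}
        if bad:
            raise ValidationError(f"non-positive GNI values: {bad}")

    def classify(self, country: str | None) -> IncomeGroup:
        if not country or country not in self.gni:
            return IncomeGroup.UNRESOLVED
        if self.gni[country] > self.threshold:
            return IncomeGroup.HIGH_INCOME
        return IncomeGroup.OTHER
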