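"""Native- vs expanded-range classification of field-collected samples.

A field-collected genome is only reusable for invasion questions when its
collection site can be placed inside the species' historical (native) range
or its invaded (expanded) range. Classification is a desk-scale lookup of the
record's normalized collection country — plus admin region when the metadata
resolves that far — against a per-species home-range gazetteer; there is
deliberately no polygon containment or geocoding.

Decision rules, applied in order:

1. no gazetteer entry for the species, a feral-listed species, or a record
   with no spatial resolution -> ``undetermined``;
2. the country appears on exactly one side of the gazetteer -> that side;
3. the country appears on both sides (the same-country split, e.g. native
   Texas / expanded California): an exact admin-region match decides; a
   record without admin resolution is ``undetermined``.
"""

from __future__ import annotations

from .errors import ContractError
from .records import (
    AssemblyRecord,
    HomeRangeEntry,
    OriginClass,
    OverrideEntry,
    RangeStatus,
)
from .rubric import StewardshipAssessment

__all__ = [
    "build_gazetteer_index",
    "classify_range",
    "classify_cohort_ranges",
    "find_dual_range_species",
]


def build_gazetteer_index(
    gazetteer: list[HomeRangeEntry],
) -> dict[str, HomeRangeEntry]:
    return {entry.species: entry for entry in gazetteer}


def _record_country_key(assessment: StewardshipAssessment) -> str | None:
    if assessment.spatial_country_code:
        return assessment.spatial_country_code
    if assessment.spatial_country:
        return assessment.spatial_country.casefold()
    return None


def classify_range(
    record: AssemblyRecord,
    assessment: StewardshipAssessment,
    gazetteer: list[HomeRangeEntry] | dict[str, HomeRangeEntry],
) -> RangeStatus:
    """Range status of one field-collected record.

    Raises :class:`ContractError` when called on a non-field record;
    non-field records carry :data:`RangeStatus.NOT_APPLICABLE` instead.
    """
    if assessment.origin is not OriginClass.FIELD:
        raise ContractError(
            f"{record.accession}: range classification requires origin=field, "
            f"got {assessment.origin}"
        )
    index = (
        gazetteer
        if isinstance(gazetteer, dict)
        else build_gazetteer_index(gazetteer)
    )
    entry = index.get(record.species)
    if entry is None or entry.feral:
        return RangeStatus.UNDETERMINED
    country = _record_country_key(assessment)
    if country is None:
        return RangeStatus.UNDETERMINED

    in_native = country in entry.countries("native")
    in_expanded = country in entry.countries("expanded")
    if in_native and not in_expanded:
        return RangeStatus.NATIVE
    if in_expanded and not in_native:
        return RangeStatus.EXPANDED
    if not in_native and not in_expanded:
        return RangeStatus.UNDETERMINED

    # Country on both sides: only an admin-region qualifier can decide.
    admin = assessment.spatial_region.strip().casefold()
    if not admin:
        return RangeStatus.UNDETERMINED
    native_hit = (country, admin) in {
        (c, (a or "").casefold()) for c, a in entry.native_regions if a is not None
    }
    expanded_hit = (country, admin) in {
        (c, (a or "").casefold()) for c, a in entry.expanded_regions if a is not None
    }
    if native_hit and not expanded_hit:
        return RangeStatus.NATIVE
    if expanded_hit and not native_hit:
        return RangeStatus.EXPANDED
    # No qualified match: fall back to a bare-country entry on one side only.
    native_bare = (country, None) in entry.native_regions
    expanded_bare = (country, None) in entry.expanded_regions
    if native_bare and not expanded_bare:
        return RangeStatus.NATIVE
    if expanded_bare and not native_bare:
        return RangeStatus.EXPANDED
    return RangeStatus.UNDETERMINED


def classify_cohort_ranges(
    records: list[AssemblyRecord],
    assessments: list[StewardshipAssessment],
    gazetteer: list[HomeRangeEntry],
    overrides: list[OverrideEntry] | None = None,
) -> list[RangeStatus]:
    """Range status for every record; non-field records are not applicable.

    Range overrides from the curated table apply only to records whose
    computed status is undetermined (attributes outrank literature).
    """
    if len(records) != len(assessments):
        raise ContractError("records and assessments are misaligned")
    index = build_gazetteer_index(gazetteer)
    statuses = [
        classify_range(record, assessment, index)
        if assessment.origin is OriginClass.FIELD
        else RangeStatus.NOT_APPLICABLE
        for record, assessment in zip(records, assessments)
    ]
    if overrides:
        positions = {record.accession: i for i, record in enumerate(records)}
        for entry in overrides:
            if entry.field != "range":
                continue
            pos = positions.get(entry.accession)
            if pos is None or statuses[pos] is not RangeStatus.UNDETERMINED:
                continue
            statuses[pos] = RangeStatus(entry.value)
    return statuses


def find_dual_range_species(
    records: list[AssemblyRecord],
    assessments: list[StewardshipAssessment],
    gazetteer: list[HomeRangeEntry],
    range_statuses: list[RangeStatus] | None = None,
) -> list[str]:
    """Species with field-collected assemblies from both of their ranges.

    Returns the lexicographically sorted species whose field-collected
    records include at least one native and at least one expanded
    classification.
    """
    if range_statuses is None:
        range_statuses = classify_cohort_ranges(records, assessments, gazetteer)
    sides: dict[str, set[RangeStatus]] = {}
    for record, status in zip(records, range_statuses):
        if status in (RangeStatus.NATIVE, RangeStatus.EXPANDED):
            sides.setdefault(record.species, set()).add(status)
    return sorted(
        species
        for species, seen in sides.items()
        if {RangeStatus.NATIVE, RangeStatus.EXPANDED} <= seen
    )
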