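"""Seeded synthetic-cohort generator with planted, recoverable ground truth.

The audit was designed against repository snapshots that cannot be rebuilt
offline, so every pipeline stage is exercised instead on generated cohorts
that emulate INSDC-style submission records: ISO dates at a planted calendar
precision, ``Country: region`` location strings, hemisphere-style coordinate
pairs, origin keyword phrases and INSDC null placeholders for planted-missing
fields.

Category counts are realized *exactly* by largest-remainder allocation rather
than sampled, so a planted mixture is recovered as an identical partition by
the classifiers on every seed; seeds only shuffle which record receives which
category. The default configuration reproduces the structure of the audited
assembly cohort: 199 submissions over 2010-2022 with 64 field / 39 laboratory
/ 17 commercial / 3 managed-colony / 76 unknown origins, about a quarter of
records lacking location and a third lacking a collection year.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .countries import normalize_country
from .errors import ConfigError
from .records import (
    AssemblyLevel,
    AssemblyRecord,
    HomeRangeEntry,
    IncomeTable,
    OriginClass,
    OverrideEntry,
    PartialDate,
    RangeStatus,
    SampleAttributes,
    SpatialGranularity,
    TemporalGranularity,
)

__all__ = [
    "DEFAULT_SPECIES_POOL",
    "PlantedTruth",
    "SpeciesSpec",
    "SyntheticConfig",
    "Table1Fixture",
    "assembly_study_config",
    "build_gazetteer",
    "build_rescue_overrides",
    "field_subset_study_config",
    "default_income_table",
    "generate_cohort",
    "generate_table1_fixture",
    "write_planted_truth",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One species in the generator pool with disjoint home-range sides."""

    name: str
    order: str
    native: tuple[str, ...]
    expanded: tuple[str, ...]


# Real invasive terrestrial arthropods with plausible (coarse, country-level)
# native/expanded geographies; within each species the two sides are disjoint
# so planted range status is always recoverable.
DEFAULT_SPECIES_POOL: tuple[SpeciesSpec, ...] = (
    SpeciesSpec("Drosophila suzukii", "Diptera", ("Japan", "China"), ("United States", "France", "Italy")),
    SpeciesSpec("Halyomorpha halys", "Hemiptera", ("China", "Japan"), ("United States", "Switzerland")),
    SpeciesSpec("Vespula vulgaris", "Hymenoptera", ("United Kingdom", "Germany"), ("New Zealand", "Australia")),
    SpeciesSpec("Harmonia axyridis", "Coleoptera", ("Japan", "Kazakhstan"), ("United Kingdom", "United States")),
    SpeciesSpec("Solenopsis invicta", "Hymenoptera", ("Brazil", "Argentina"), ("United States", "China")),
    SpeciesSpec("Aedes albopictus", "Diptera", ("Thailand", "Indonesia"), ("Italy", "United States")),
    SpeciesSpec("Lymantria dispar", "Lepidoptera", ("France", "Germany"), ("United States", "Canada")),
    SpeciesSpec("Bactrocera dorsalis", "Diptera", ("Thailand", "Malaysia"), ("Kenya", "China")),
    SpeciesSpec("Linepithema humile", "Hymenoptera", ("Argentina", "Brazil"), ("Spain", "Australia")),
    SpeciesSpec("Diaphorina citri", "Hemiptera", ("Taiwan", "India"), ("Uruguay", "United States")),
    SpeciesSpec("Homalodisca vitripennis", "Hemiptera", ("Mexico",), ("Chile",)),
    SpeciesSpec("Pieris rapae", "Lepidoptera", ("United Kingdom", "France"), ("United States", "Australia")),
    SpeciesSpec("Anoplophora glabripennis", "Coleoptera", ("China", "South Korea"), ("United States", "Austria")),
    SpeciesSpec("Tuta absoluta", "Lepidoptera", ("Peru", "Chile"), ("Spain", "Kenya")),
    SpeciesSpec("Frankliniella occidentalis", "Thysanoptera", ("United States",), ("Netherlands", "Australia")),
    SpeciesSpec("Blattella germanica", "Blattodea", ("Ethiopia",), ("Germany", "United States")),
    SpeciesSpec("Varroa destructor", "Mesostigmata", ("Japan", "South Korea"), ("Germany", "New Zealand")),
    SpeciesSpec("Haemaphysalis longicornis", "Ixodida", ("China", "Japan"), ("New Zealand", "United States")),
    SpeciesSpec("Vespa velutina", "Hymenoptera", ("China", "Indonesia"), ("France", "South Korea")),
    SpeciesSpec("Ceratitis capitata", "Diptera", ("Kenya", "Tanzania"), ("Spain", "Australia")),
)


def _fractions(counts: dict, total: int) -> dict:
    return {key: value / total for key, value in counts.items()}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic cohort.

    Mixtures are proportions that must sum to one; they are converted to
    exact per-category counts by largest-remainder allocation. Defaults
    mirror the audited 199-record assembly cohort.
    """

    n: int = 199
    seed: int = 0
    origin_mixture: dict[OriginClass, float] = field(
        default_factory=lambda: _fractions(
            {
                OriginClass.FIELD: 64,
                OriginClass.LABORATORY: 39,
                OriginClass.COMMERCIAL: 17,
                OriginClass.MANAGED_COLONY: 3,
                OriginClass.UNKNOWN: 76,
            },
            199,
        )
    )
    spatial_mixture: dict[SpatialGranularity, float] = field(
        default_factory=lambda: _fractions(
            {
                SpatialGranularity.NONE: 45,
                SpatialGranularity.COUNTRY: 20,
                SpatialGranularity.REGION_CITY: 89,
                SpatialGranularity.COORDINATES: 45,
            },
            199,
        )
    )
    temporal_mixture: dict[TemporalGranularity, float] = field(
        default_factory=lambda: _fractions(
            {
                TemporalGranularity.NONE: 69,
                TemporalGranularity.YEAR: 40,
                TemporalGranularity.MONTH: 30,
                TemporalGranularity.DAY: 60,
            },
            199,
        )
    )
    presence_rates: dict[str, float] = field(
        default_factory=lambda: {"tissue": 134 / 199, "dev_stage": 134 / 199, "sex": 100 / 199}
    )
    year_range: tuple[int, int] = (2010, 2022)
    species_pool: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES_POOL
    dual_range_species: int = 2
    reference_fraction: float | None = None  # None = one per species (earliest)
    sra_rate: float = 0.64
    adversarial: bool = False

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"cohort size must be positive, got {self.n}")
        for name, mixture in (
            ("origin_mixture", self.origin_mixture),
            ("spatial_mixture", self.spatial_mixture),
            ("temporal_mixture", self.temporal_mixture),
        ):
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in mixture.values()):
                raise ConfigError(f"{name} has a negative proportion")
        for key, rate in {
            **self.presence_rates,
            "sra_rate": self.sra_rate,
            **(
                {"reference_fraction": self.reference_fraction}
                if self.reference_fraction is not None
                else {}
            ),
        }.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {key} outside [0, 1]: {rate}")
        if not self.species_pool:
            raise ConfigError("species pool is empty")
        if self.dual_range_species > len(self.species_pool):
            raise ConfigError("more dual-range species requested than pool size")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError(f"invalid year range: {self.year_range}")
        for spec in self.species_pool:
            if not spec.native or not spec.expanded:
                raise ConfigError(f"{spec.name}: both range sides must be non-empty")
            if set(spec.native) & set(spec.expanded):
                raise ConfigError(f"{spec.name}: native/expanded countries overlap")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one generated record, one row per accession."""

    accession: str
    species: str
    origin: OriginClass
    spatial: SpatialGranularity
    temporal: TemporalGranularity
    range_status: RangeStatus
    has_tissue: bool
    has_dev_stage: bool
    has_sex: bool
    adversarial: bool = False


def largest_remainder(n: int, weights: list[float]) -> list[int]:
    """Integer allocation of n among weights, exact and deterministic.

    Floors the ideal shares, then hands remaining units to the largest
    fractional remainders (ties broken by position).
    """
    ideal = [n * w for w in weights]
    counts = [int(x) for x in ideal]
    order = sorted(
        range(len(weights)), key=lambda i: (ideal[i] - counts[i], -i), reverse=True
    )
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _allocate(n: int, mixture: dict) -> list:
    """Expanded category list of length n realizing the mixture exactly."""
    keys = list(mixture)
    counts = largest_remainder(n, [mixture[k] for k in keys])
    out: list = []
    for key, count in zip(keys, counts):
        out.extend([key] * count)
    return out


_NULL_CHOICES = ("missing", "not collected", "not applicable", None)  # None=absent
_REGIONS = (
    "Northland", "Canterbury Plains", "Lakeside Reserve", "Hilltop Station",
    "River Delta", "Eastern Highlands", "Port District", "Orchard Valley",
    "Coastal Dunes", "Central Plateau",
)
_FIELD_PHRASES = (
    "wild caught, pheromone trap",
    "field collected from host plant",
    "wild caught by sweep net",
    "collected from nature reserve",
    "wild population, light trap",
)
_LAB_PHRASES = (
    "inbred laboratory culture",
    "isofemale laboratory line G12",
    "long-term lab culture",
    "inbred strain, generation F20",
)
_COMMERCIAL_PHRASES = (
    "purchased from commercial supplier",
    "commercially obtained",
    "obtained from vendor",
)
_COLONY_PHRASES = (
    "managed apiary",
    "managed colony, hive 7",
    "apiary colony",
)
_ORIGIN_PHRASES = {
    OriginClass.FIELD: _FIELD_PHRASES,
    OriginClass.LABORATORY: _LAB_PHRASES,
    OriginClass.COMMERCIAL: _COMMERCIAL_PHRASES,
    OriginClass.MANAGED_COLONY: _COLONY_PHRASES,
}
_COUNTRY_VARIANTS = {
    "United States": ("United States", "USA"),
    "United Kingdom": ("United Kingdom", "UK"),
}
_TISSUES = ("whole organism", "thorax", "head", "abdomen", "whole body, pooled")
_STAGES = ("adult", "larva", "pupa", "nymph")
_SUBMITTERS = (
    ("Wellcome Sanger Institute", "GB"),
    ("USDA-ARS", "US"),
    ("BGI", "CN"),
    ("INRAE", "FR"),
    ("University of Otago", "NZ"),
    ("CSIRO", "AU"),
    ("University of Tokyo", "JP"),
    ("i5K Consortium", ""),  # multi-country consortium: country left blank
)


def build_gazetteer(pool: tuple[SpeciesSpec, ...]) -> list[HomeRangeEntry]:
    """Country-level home-range gazetteer implied by a species pool."""
    entries = []
    for spec in pool:
        entries.append(
            HomeRangeEntry(
                species=spec.name,
                native_regions=frozenset(
                    (normalize_country(c).code or c, None) for c in spec.native
                ),
                expanded_regions=frozenset(
                    (normalize_country(c).code or c, None) for c in spec.expanded
                ),
            )
        )
    return entries


def default_income_table() -> IncomeTable:
    """Plausible GNI-per-capita values (USD) for the generator's countries."""
    gni = {
        "US": 70000, "GB": 45000, "NZ": 45000, "AU": 57000, "JP": 41000,
        "FR": 43000, "DE": 48000, "CH": 88000, "IT": 35000, "ES": 29000,
        "NL": 53000, "AT": 51000, "CA": 48000, "KR": 34000, "TW": 33000,
        "CL": 15000, "UY": 16000, "CN": 11000, "BR": 7800, "AR": 10000,
        "MX": 9500, "TH": 7000, "ID": 4100, "MY": 10900, "IN": 2200,
        "KE": 2000, "TZ": 1100, "ET": 940, "PE": 6400, "KZ": 9200,
    }
    return IncomeTable(gni={k: float(v) for k, v in gni.items()})


def _maybe_null(rng: random.Random) -> str | None:
    return rng.choice(_NULL_CHOICES)


def _format_lat_lon(rng: random.Random) -> str:
    lat = round(rng.uniform(-55.0, 65.0), 2)
    lon = round(rng.uniform(-170.0, 170.0), 2)
    if rng.random() < 0.5:
        return (
            f"{abs(lat):.2f} {'N' if lat >= 0 else 'S'} "
            f"{abs(lon):.2f} {'E' if lon >= 0 else 'W'}"
        )
    return f"{lat:.2f}, {lon:.2f}"


def _country_display(rng: random.Random, canonical: str) -> str:
    variants = _COUNTRY_VARIANTS.get(canonical)
    if variants and rng.random() < 0.3:
        return variants[1]
    return canonical


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[AssemblyRecord], list[PlantedTruth]]:
    """Generate a cohort realizing the configured mixtures exactly.

    Deterministic under (config, seed): the same configuration always yields
    byte-identical records; different seeds permute category-to-record
    assignment but preserve every planted marginal count.
    """
    config.validate()
    rng = random.Random(config.seed)
    n = config.n

    origins = _allocate(n, config.origin_mixture)
    rng.shuffle(origins)
    spatials = _allocate(n, config.spatial_mixture)
    rng.shuffle(spatials)
    temporals = _allocate(n, config.temporal_mixture)
    rng.shuffle(temporals)
    presence = {}
    for key, rate in config.presence_rates.items():
        flags = _allocate(n, {True: rate, False: 1.0 - rate})
        rng.shuffle(flags)
        presence[key] = flags
    sra_flags = _allocate(n, {True: config.sra_rate, False: 1.0 - config.sra_rate})
    rng.shuffle(sra_flags)

    # Dual-range planting needs 2k field records resolvable to >= country;
    # spatial labels are swapped between records (marginals preserved) to
    # guarantee feasibility before species assignment.
    k = config.dual_range_species
    field_idx = [i for i in range(n) if origins[i] is OriginClass.FIELD]
    located = lambda i: spatials[i] >= SpatialGranularity.COUNTRY  # noqa: E731
    if k > 0:
        if len(field_idx) < 2 * k:
            raise ConfigError(
                f"cannot plant {k} dual-range species with only "
                f"{len(field_idx)} field records"
            )
        eligible = [i for i in field_idx if located(i)]
        deficit = 2 * k - len(eligible)
        if deficit > 0:
            donors = [i for i in range(n) if located(i) and origins[i] is not OriginClass.FIELD]
            takers = [i for i in field_idx if not located(i)]
            if deficit > min(len(donors), len(takers)):
                raise ConfigError(
                    "spatial mixture plants too few located records for the "
                    "requested dual-range species"
                )
            for taker, donor in zip(takers[:deficit], donors[:deficit]):
                spatials[taker], spatials[donor] = spatials[donor], spatials[taker]

    pool = list(config.species_pool)
    rng.shuffle(pool)
    dual_species = pool[:k]
    # Non-dual species keep a single range side so planted dual-range
    # membership is exact, not merely a lower bound.
    side_map = {
        spec.name: rng.choice(("native", "expanded")) for spec in pool[k:]
    }

    species_for: list[SpeciesSpec | None] = [None] * n
    side_for: list[str] = [""] * n
    eligible = [i for i in field_idx if located(i)]
    rng.shuffle(eligible)
    for j, spec in enumerate(dual_species):
        native_i, expanded_i = eligible[2 * j], eligible[2 * j + 1]
        species_for[native_i], side_for[native_i] = spec, "native"
        species_for[expanded_i], side_for[expanded_i] = spec, "expanded"
    for i in range(n):
        if species_for[i] is not None:
            continue
        spec = rng.choice(pool)
        species_for[i] = spec
        if spec in dual_species:
            side_for[i] = rng.choice(("native", "expanded"))
        else:
            side_for[i] = side_map[spec.name]

    levels = _allocate(
        n,
        {AssemblyLevel.CHROMOSOME: 0.34, AssemblyLevel.SCAFFOLD: 0.54, AssemblyLevel.CONTIG: 0.12},
    )
    rng.shuffle(levels)

    records: list[AssemblyRecord] = []
    truths: list[PlantedTruth] = []
    for i in range(n):
        spec = species_for[i]
        assert spec is not None
        accession = f"GCA_{910000000 + i}.1"
        attrs: dict[str, str] = {}
        adversarial_row = False

        sub_year = rng.randint(*config.year_range)
        submission = PartialDate(sub_year, rng.randint(1, 12), rng.randint(1, 28))

        # --- spatial ---
        spatial = spatials[i]
        side_countries = spec.native if side_for[i] == "native" else spec.expanded
        country = rng.choice(side_countries)
        display = _country_display(rng, country)
        if spatial is SpatialGranularity.NONE:
            token = _maybe_null(rng)
            if token is not None:
                attrs["geo_loc_name"] = token
        elif spatial is SpatialGranularity.COUNTRY:
            attrs["geo_loc_name"] = display
        else:
            attrs["geo_loc_name"] = f"{display}: {rng.choice(_REGIONS)}"
            if spatial is SpatialGranularity.COORDINATES:
                attrs["lat_lon"] = _format_lat_lon(rng)

        # --- temporal ---
        temporal = temporals[i]
        coll_year = sub_year - rng.randint(0, 3)
        if temporal is TemporalGranularity.NONE:
            token = _maybe_null(rng)
            if token is not None:
                attrs["collection_date"] = token
        elif temporal is TemporalGranularity.YEAR:
            text = f"{coll_year}"
            if config.adversarial and rng.random() < 0.3:
                text = f"{coll_year}/{coll_year + 1}"  # range resolves to bound
                adversarial_row = True
            attrs["collection_date"] = text
        elif temporal is TemporalGranularity.MONTH:
            attrs["collection_date"] = f"{coll_year}-{rng.randint(1, 12):02d}"
        else:
            attrs["collection_date"] = (
                f"{coll_year}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
            )

        # --- origin ---
        origin = origins[i]
        if origin is OriginClass.UNKNOWN:
            token = _maybe_null(rng)
            if token is not None:
                attrs["isolation_source"] = token
        else:
            phrase = rng.choice(_ORIGIN_PHRASES[origin])
            if (
                config.adversarial
                and origin is OriginClass.LABORATORY
                and rng.random() < 0.3
            ):
                # founders wild, propagation captive: precedence keeps the
                # planted class but the conflict flag is raised
                phrase = "field-collected founders, lab colony F12"
                adversarial_row = True
            attrs["isolation_source"] = phrase

        # --- presence flags ---
        if presence["tissue"][i]:
            attrs["tissue"] = rng.choice(_TISSUES)
        else:
            token = _maybe_null(rng)
            if token is not None:
                attrs["tissue"] = token
        if presence["dev_stage"][i]:
            attrs["dev_stage"] = rng.choice(_STAGES)
        if presence["sex"][i]:
            attrs["sex"] = rng.choice(("female", "male"))

        institute, inst_country = rng.choice(_SUBMITTERS)
        records.append(
            AssemblyRecord(
                accession=accession,
                species=spec.name,
                taxonomic_order=spec.order,
                assembly_level=levels[i],
                submission_date=submission,
                submitter_institute=institute,
                submitter_country=inst_country,
                is_reference=False,  # assigned below
                sra_linked=sra_flags[i],
                attributes=SampleAttributes(attrs),
            )
        )
        if origin is OriginClass.FIELD:
            if spatial >= SpatialGranularity.COUNTRY:
                range_status = (
                    RangeStatus.NATIVE if side_for[i] == "native" else RangeStatus.EXPANDED
                )
            else:
                range_status = RangeStatus.UNDETERMINED
        else:
            range_status = RangeStatus.NOT_APPLICABLE
        truths.append(
            PlantedTruth(
                accession=accession,
                species=spec.name,
                origin=origin,
                spatial=spatial,
                temporal=temporal,
                range_status=range_status,
                has_tissue=bool(presence["tissue"][i]),
                has_dev_stage=bool(presence["dev_stage"][i]),
                has_sex=bool(presence["sex"][i]),
                adversarial=adversarial_row,
            )
        )

    records = _assign_reference_flags(records, config, rng)
    return records, truths


def _assign_reference_flags(
    records: list[AssemblyRecord],
    config: SyntheticConfig,
    rng: random.Random,
) -> list[AssemblyRecord]:
    if config.reference_fraction is None:
        # repository convention: one designated representative per species,
        # here the earliest-submitted assembly
        best: dict[str, int] = {}
        for i, record in enumerate(records):
            j = best.get(record.species)
            if j is None or record.submission_date.sort_key() < records[
                j
            ].submission_date.sort_key():
                best[record.species] = i
        chosen = set(best.values())
    else:
        flags = _allocate(
            len(records),
            {True: config.reference_fraction, False: 1.0 - config.reference_fraction},
        )
        rng.shuffle(flags)
        chosen = {i for i, flag in enumerate(flags) if flag}
    return [
        replace(record, is_reference=i in chosen) for i, record in enumerate(records)
    ]


def write_planted_truth(truths: list[PlantedTruth], path: Path | str) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "accession", "species", "origin", "spatial", "temporal",
                "range_status", "has_tissue", "has_dev_stage", "has_sex",
                "adversarial",
            ]
        )
        for t in truths:
            writer.writerow(
                [
                    t.accession, t.species, str(t.origin), str(t.spatial),
                    str(t.temporal), str(t.range_status),
                    str(t.has_tissue).lower(), str(t.has_dev_stage).lower(),
                    str(t.has_sex).lower(), str(t.adversarial).lower(),
                ]
            )


# --------------------------------------------------------------------------
# Study-condition configurations
# --------------------------------------------------------------------------

def assembly_study_config(seed: int = 0) -> SyntheticConfig:
    """The audited assembly cohort's structure: 199 records, 76 unknown.

    This is simply the default configuration with a chosen seed; the origin
    partition plants 64 field / 39 laboratory / 17 commercial / 3 managed
    colony / 76 unknown records.
    """
    return SyntheticConfig(seed=seed)


def field_subset_study_config(seed: int = 0) -> SyntheticConfig:
    """The 76-record field-collected subset's spatiotemporal structure.

    Spatial mixture plants 27 coordinate-level, 38 region/city, 8 country and
    3 unlocated records; temporal mixture plants 25 records without a usable
    collection date. All records are field-collected.
    """
    return SyntheticConfig(
        n=76,
        seed=seed,
        origin_mixture={OriginClass.FIELD: 1.0},
        spatial_mixture=_fractions(
            {
                SpatialGranularity.COORDINATES: 27,
                SpatialGranularity.REGION_CITY: 38,
                SpatialGranularity.COUNTRY: 8,
                SpatialGranularity.NONE: 3,
            },
            76,
        ),
        temporal_mixture=_fractions(
            {
                TemporalGranularity.NONE: 25,
                TemporalGranularity.YEAR: 20,
                TemporalGranularity.MONTH: 10,
                TemporalGranularity.DAY: 21,
            },
            76,
        ),
        dual_range_species=2,
    )


def build_rescue_overrides(
    records: list[AssemblyRecord],
    n_field: int = 12,
    n_nonfield: int = 17,
) -> list[OverrideEntry]:
    """A literature-rescue override table against a cohort's unknown records.

    Emulates post-hoc curation: the first ``n_field`` attribute-unknown
    records (in cohort order) are reclassified as field-collected and the
    next ``n_nonfield`` as laboratory, each with a synthetic citation.
    """
    from .rubric import assess_record

    unknown = [
        record.accession
        for record in records
        if assess_record(record).origin is OriginClass.UNKNOWN
    ]
    if len(unknown) < n_field + n_nonfield:
        raise ConfigError(
            f"cohort has only {len(unknown)} unknown-origin records, "
            f"cannot rescue {n_field + n_nonfield}"
        )
    overrides = [
        OverrideEntry(acc, "origin", "field", f"curated source {i + 1}")
        for i, acc in enumerate(unknown[:n_field])
    ]
    overrides += [
        OverrideEntry(acc, "origin", "laboratory", f"curated source {n_field + i + 1}")
        for i, acc in enumerate(unknown[n_field : n_field + n_nonfield])
    ]
    return overrides


# --------------------------------------------------------------------------
# Worked-example fixture: the seven dual-range species
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Fixture:
    records: list[AssemblyRecord]
    gazetteer: list[HomeRangeEntry]
    overrides: list[OverrideEntry]


def _fixture_record(
    accession: str,
    species: str,
    order: str,
    level: AssemblyLevel,
    year: int,
    institute: str,
    country: str,
    geo: str | None,
    lat_lon: str | None = None,
    collection_date: str | None = None,
    isolation: str | None = "wild caught",
) -> AssemblyRecord:
    attrs: dict[str, str] = {}
    if geo is not None:
        attrs["geo_loc_name"] = geo
    if lat_lon is not None:
        attrs["lat_lon"] = lat_lon
    if collection_date is not None:
        attrs["collection_date"] = collection_date
    if isolation is not None:
        attrs["isolation_source"] = isolation
    return AssemblyRecord(
        accession=accession,
        species=species,
        taxonomic_order=order,
        assembly_level=level,
        submission_date=PartialDate(year, 6, 15),
        submitter_institute=institute,
        submitter_country=country,
        is_reference=False,
        sra_linked=True,
        attributes=SampleAttributes(attrs),
    )


def generate_table1_fixture() -> Table1Fixture:
    """Fifteen field-collected assemblies of seven dual-range species.

    A deterministic worked example: seven invasive arthropods each with at
    least one field-collected assembly from the native range and one from the
    expanded range. One record (the Asian longhorned tick's New Zealand
    assembly) deliberately lacks origin-bearing attributes and is rescued by
    a cited override, mirroring literature-based curation.
    """
    CHR = AssemblyLevel.CHROMOSOME
    SCA = AssemblyLevel.SCAFFOLD
    records = [
        _fixture_record("GCA_021130785.2", "Homalodisca vitripennis", "Hemiptera", CHR,
                        2021, "USDA-ARS", "US", "USA: Texas", collection_date="2019-05"),
        _fixture_record("GCA_019364655.1", "Homalodisca vitripennis", "Hemiptera", SCA,
                        2021, "University of California", "US", "USA: California",
                        collection_date="2020"),
        _fixture_record("GCA_905475345.1", "Vespula vulgaris", "Hymenoptera", CHR,
                        2021, "Wellcome Sanger Institute", "GB",
                        "United Kingdom: Wytham Great Wood",
                        lat_lon="51.77 N 1.33 W", collection_date="2020-07-12"),
        _fixture_record("GCA_014466185.1", "Vespula vulgaris", "Hymenoptera", CHR,
                        2020, "Manaaki Whenua Landcare Research", "NZ",
                        "New Zealand: Pelorus", collection_date="2017-03"),
        _fixture_record("GCA_905147795.1", "Pieris rapae", "Lepidoptera", CHR,
                        2021, "Wellcome Sanger Institute", "GB",
                        "United Kingdom: West Linton, Scotland",
                        lat_lon="55.74 N 3.35 W", collection_date="2020-06-02"),
        _fixture_record("GCA_001856805.1", "Pieris rapae", "Lepidoptera", SCA,
                        2016, "University of Texas", "US", "USA: Texas",
                        collection_date="2015"),
        _fixture_record("GCA_013339765.2", "Haemaphysalis longicornis", "Ixodida", CHR,
                        2020, "Shandong Agricultural University", "CN",
                        "China: Shandong", collection_date="2018-04"),
        _fixture_record("GCA_008122185.1", "Haemaphysalis longicornis", "Ixodida", SCA,
                        2019, "AgResearch", "NZ", "New Zealand",
                        collection_date="2017", isolation=None),
        _fixture_record("GCA_003402655.1", "Harmonia axyridis", "Coleoptera", SCA,
                        2018, "University of Tokyo", "JP", "Japan",
                        collection_date="2016"),
        _fixture_record("GCA_914767665.1", "Harmonia axyridis", "Coleoptera", CHR,
                        2021, "Wellcome Sanger Institute", "GB",
                        "United Kingdom: Wytham Great Wood",
                        lat_lon="51.77 N 1.33 W", collection_date="2021-05-20"),
        _fixture_record("GCA_024506325.2", "Diaphorina citri", "Hemiptera", CHR,
                        2022, "USDA-ARS", "US", "Taiwan", collection_date="2019-11"),
        _fixture_record("GCA_024506275.2", "Diaphorina citri", "Hemiptera", CHR,
                        2022, "USDA-ARS", "US", "Uruguay", collection_date="2019-09"),
        _fixture_record("GCA_024506315.2", "Diaphorina citri", "Hemiptera", CHR,
                        2022, "USDA-ARS", "US", "USA: Los Angeles, California",
                        collection_date="2019-06"),
        _fixture_record("GCA_905340365.1", "Vespula germanica", "Hymenoptera", CHR,
                        2021, "Wellcome Sanger Institute", "GB",
                        "United Kingdom: Wytham Rough Common",
                        lat_lon="51.77 N 1.32 W", collection_date="2020-08-01"),
        _fixture_record("GCA_014466195.1", "Vespula germanica", "Hymenoptera", CHR,
                        2020, "Manaaki Whenua Landcare Research", "NZ",
                        "New Zealand: Lincoln", collection_date="2016-12"),
    ]
    gazetteer = [
        HomeRangeEntry("Homalodisca vitripennis",
                       frozenset({("US", "Texas")}), frozenset({("US", "California")})),
        HomeRangeEntry("Vespula vulgaris",
                       frozenset({("GB", None)}), frozenset({("NZ", None)})),
        HomeRangeEntry("Pieris rapae",
                       frozenset({("GB", None)}), frozenset({("US", None)})),
        HomeRangeEntry("Haemaphysalis longicornis",
                       frozenset({("CN", None)}), frozenset({("NZ", None)})),
        HomeRangeEntry("Harmonia axyridis",
                       frozenset({("JP", None)}), frozenset({("GB", None)})),
        HomeRangeEntry("Diaphorina citri",
                       frozenset({("TW", None)}),
                       frozenset({("UY", None), ("US", None)})),
        HomeRangeEntry("Vespula germanica",
                       frozenset({("GB", None)}), frozenset({("NZ", None)})),
    ]
    overrides = [
        OverrideEntry(
            accession="GCA_008122185.1",
            field="origin",
            value="field",
            evidence="Guerrero et al. 2019",
        )
    ]
    return Table1Fixture(records=records, gazetteer=gazetteer, overrides=overrides)
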