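"""Native/expanded range classification against the home-range gazetteer."""

import random

import pytest

import invaudit as iv
from invaudit.errors import ContractError

R = iv.RangeStatus


def _field_record(accession, species, geo=None):
    attrs = {"isolation_source": "wild caught"}
    if geo is not None:
        attrs["geo_loc_name"] = geo
    return iv.AssemblyRecord(
        accession=accession, species=species, taxonomic_order="Hemiptera",
        assembly_level=iv.AssemblyLevel.SCAFFOLD,
        submission_date=iv.PartialDate(2020),
        submitter_institute="", submitter_country="",
        is_reference=False, sra_linked=False,
        attributes=iv.SampleAttributes(attrs),
    )


WASP_GAZ = [
    iv.HomeRangeEntry("Vespula vulgaris",
                      frozenset({("GB", None)}), frozenset({("NZ", None)})),
]
SHARPSHOOTER_GAZ = [
    iv.HomeRangeEntry("Homalodisca vitripennis",
                      frozenset({("US", "Texas")}),
                      frozenset({("US", "California")})),
]


def _classify(record, gazetteer):
    return iv.classify_range(record, iv.assess_record(record), gazetteer)


@pytest.mark.parametrize(
    "species,geo,gazetteer,expected",
    [
        ("Vespula vulgaris", "New Zealand: Pelorus", WASP_GAZ, R.EXPANDED),
        ("Vespula vulgaris", "United Kingdom", WASP_GAZ, R.NATIVE),
        ("Homalodisca vitripennis", "USA: Texas", SHARPSHOOTER_GAZ, R.NATIVE),
        ("Homalodisca vitripennis", "USA: California", SHARPSHOOTER_GAZ, R.EXPANDED),
        # country on both gazetteer sides, record lacks admin resolution
        ("Homalodisca vitripennis", "USA", SHARPSHOOTER_GAZ, R.UNDETERMINED),
        # admin region matching neither qualified side
        ("Homalodisca vitripennis", "USA: Florida", SHARPSHOOTER_GAZ, R.UNDETERMINED),
        # no spatial data at all
        ("Vespula vulgaris", None, WASP_GAZ, R.UNDETERMINED),
        # species absent from gazetteer
        ("Apis mellifera", "France", WASP_GAZ, R.UNDETERMINED),
        # country in neither side
        ("Vespula vulgaris", "Japan", WASP_GAZ, R.UNDETERMINED),
    ],
)
def test_range_decision_rules(species, geo, gazetteer, expected):
    assert _classify(_field_record("GCA_1.1", species, geo), gazetteer) is expected


def test_feral_species_forced_undetermined():
    gaz = [
        iv.HomeRangeEntry("Apis mellifera", frozenset({("FR", None)}),
                          frozenset({("NZ", None)}), feral=True)
    ]
    record = _field_record("GCA_1.1", "Apis mellifera", "France")
    assert _classify(record, gaz) is R.UNDETERMINED


def test_non_field_record_is_a_contract_violation():
    record = _field_record("GCA_1.1", "Vespula vulgaris", "United Kingdom")
    lab = iv.AssemblyRecord(
        **{**record.__dict__,
           "attributes": iv.SampleAttributes({"strain": "inbred lab culture"})}
    )
    with pytest.raises(ContractError):
        iv.classify_range(lab, iv.assess_record(lab), WASP_GAZ)


def test_cohort_ranges_mark_non_field_not_applicable(default_cohort):
    config, records, truths = default_cohort
    assessments = [iv.assess_record(r) for r in records]
    statuses = iv.classify_cohort_ranges(
        records, assessments, iv.build_gazetteer(config.species_pool)
    )
    for a, s in zip(assessments, statuses):
        if a.origin is iv.OriginClass.FIELD:
            assert s is not R.NOT_APPLICABLE
        else:
            assert s is R.NOT_APPLICABLE
        if s in (R.NATIVE, R.EXPANDED):
            assert a.spatial >= iv.SpatialGranularity.COUNTRY


def test_gazetteer_order_invariance(default_cohort):
    config, records, _ = default_cohort
    assessments = [iv.assess_record(r) for r in records]
    gaz = iv.build_gazetteer(config.species_pool)
    shuffled = list(gaz)
    random.Random(5).shuffle(shuffled)
    assert iv.classify_cohort_ranges(records, assessments, gaz) == \
        iv.classify_cohort_ranges(records, assessments, shuffled)


def _bruteforce_dual(records, statuses):
    out = []
    for species in {r.species for r in records}:
        seen = {
            s
            for r, s in zip(records, statuses)
            if r.species == species and s in (R.NATIVE, R.EXPANDED)
        }
        if seen == {R.NATIVE, R.EXPANDED}:
            out.append(species)
    return sorted(out)


@pytest.mark.parametrize("seed", range(6))
def test_dual_range_detection_equals_bruteforce(seed):
    config = iv.SyntheticConfig(n=120, seed=seed, dual_range_species=3)
    records, truths = iv.generate_cohort(config)
    gaz = iv.build_gazetteer(config.species_pool)
    assessments = [iv.assess_record(r) for r in records]
    statuses = iv.classify_cohort_ranges(records, assessments, gaz)
    dual = iv.find_dual_range_species(records, assessments, gaz, statuses)
    assert dual == _bruteforce_dual(records, statuses)
    assert len(dual) == 3  # exactly the planted dual-range species


def test_single_sided_species_never_reported():
    records = [
        _field_record("GCA_1.1", "Vespula vulgaris", "United Kingdom"),
        _field_record("GCA_2.1", "Vespula vulgaris", "United Kingdom"),
    ]
    assessments = [iv.assess_record(r) for r in records]
    assert iv.find_dual_range_species(records, assessments, WASP_GAZ) == []


def test_range_override_applies_only_to_undetermined():
    records = [
        _field_record("GCA_1.1", "Vespula vulgaris", None),  # undetermined
        _field_record("GCA_2.1", "Vespula vulgaris", "United Kingdom"),  # native
    ]
    assessments = [iv.assess_record(r) for r in records]
    overrides = [
        iv.OverrideEntry("GCA_1.1", "range", "expanded", "lit"),
        iv.OverrideEntry("GCA_2.1", "range", "expanded", "lit"),
    ]
    statuses = iv.classify_cohort_ranges(records, assessments, WASP_GAZ, overrides)
    assert statuses == [R.EXPANDED, R.NATIVE]
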