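"""Generator contracts: determinism, exact allocation, recoverable truth."""

from collections import Counter

import pytest

import invaudit as iv
from invaudit.errors import ConfigError
from invaudit.synthetic import largest_remainder

O = iv.OriginClass
S = iv.SpatialGranularity
T = iv.TemporalGranularity


def test_largest_remainder_is_exact_and_deterministic():
    assert largest_remainder(199, [64 / 199, 39 / 199, 17 / 199, 3 / 199, 76 / 199]) \
        == [64, 39, 17, 3, 76]
    assert sum(largest_remainder(7, [1 / 3, 1 / 3, 1 / 3])) == 7
    assert largest_remainder(1, [0.5, 0.5]) == [1, 0]


def test_same_config_and_seed_is_byte_identical(tmp_path):
    config = iv.SyntheticConfig(n=80, seed=21)
    a_records, a_truth = iv.generate_cohort(config)
    b_records, b_truth = iv.generate_cohort(config)
    assert a_records == b_records and a_truth == b_truth
    iv.write_assembly_table(a_records, tmp_path / "a.tsv")
    iv.write_assembly_table(b_records, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_seeds_vary_assignment_but_preserve_marginals():
    base = iv.SyntheticConfig(n=101, seed=0)
    other = iv.SyntheticConfig(n=101, seed=1)
    a_records, a_truth = iv.generate_cohort(base)
    b_records, b_truth = iv.generate_cohort(other)
    assert a_records != b_records
    for axis in ("origin", "spatial", "temporal"):
        assert Counter(getattr(t, axis) for t in a_truth) == Counter(
            getattr(t, axis) for t in b_truth
        )


def test_all_mass_on_temporal_none_yields_only_null_dates():
    config = iv.SyntheticConfig(
        n=40, seed=4, temporal_mixture={T.NONE: 1.0}
    )
    records, truths = iv.generate_cohort(config)
    for record in records:
        value = record.attributes.get("collection_date")
        assert value is None or iv.rubric.is_null_token(value)
    assert all(t.temporal is T.NONE for t in truths)


@pytest.mark.parametrize("seed", range(20))
def test_pipeline_recovers_planted_truth_exactly(seed):
    """Generator -> classifier round trip is lossless on every axis."""
    n = {0: 10_000, 1: 2_000}.get(seed, 199)
    config = iv.SyntheticConfig(n=n, seed=seed)
    records, truths = iv.generate_cohort(config)
    gaz = iv.build_gazetteer(config.species_pool)
    assessments = [iv.assess_record(r) for r in records]
    statuses = iv.classify_cohort_ranges(records, assessments, gaz)
    for truth, assessment, status in zip(truths, assessments, statuses):
        assert assessment.origin is truth.origin
        assert assessment.spatial is truth.spatial
        assert assessment.temporal is truth.temporal
        assert assessment.has_tissue is truth.has_tissue
        assert assessment.has_dev_stage is truth.has_dev_stage
        assert assessment.has_sex is truth.has_sex
        assert status is truth.range_status


def test_stress_config_covers_every_category():
    config = iv.SyntheticConfig(
        n=400,
        seed=9,
        origin_mixture={c: 0.2 for c in O},
        spatial_mixture={g: 0.25 for g in S},
        temporal_mixture={g: 0.25 for g in T},
    )
    _, truths = iv.generate_cohort(config)
    assert {t.origin for t in truths} == set(O)
    assert {t.spatial for t in truths} == set(S)
    assert {t.temporal for t in truths} == set(T)


def test_reference_flags_default_to_one_per_species(default_cohort):
    _, records, _ = default_cohort
    refs = [r for r in records if r.is_reference]
    species = {r.species for r in records}
    assert len(refs) == len(species)
    assert {r.species for r in refs} == species


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n": 0},
        {"origin_mixture": {O.FIELD: 0.5}},  # does not sum to 1
        {"dual_range_species": 99},
        {"sra_rate": 1.5},
        {"year_range": (2022, 2010)},
        # one field record cannot host a native/expanded pair
        {"n": 1, "origin_mixture": {O.FIELD: 1.0}, "dual_range_species": 1},
        # no locatable records to anchor a dual-range pair
        {
            "n": 10,
            "origin_mixture": {O.FIELD: 1.0},
            "spatial_mixture": {S.NONE: 1.0},
            "dual_range_species": 1,
        },
    ],
)
def test_infeasible_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        iv.generate_cohort(iv.SyntheticConfig(seed=0, **kwargs))


def test_adversarial_templates_only_when_enabled():
    plain_records, plain_truths = iv.generate_cohort(
        iv.SyntheticConfig(n=150, seed=5)
    )
    assert not any(t.adversarial for t in plain_truths)
    _, adv_truths = iv.generate_cohort(
        iv.SyntheticConfig(n=150, seed=5, adversarial=True)
    )
    assert any(t.adversarial for t in adv_truths)


def test_adversarial_truth_rows_remain_recoverable():
    config = iv.SyntheticConfig(n=150, seed=6, adversarial=True)
    records, truths = iv.generate_cohort(config)
    for record, truth in zip(records, truths):
        assessment = iv.assess_record(record)
        assert assessment.origin is truth.origin
        assert assessment.temporal is truth.temporal


def test_table1_fixture_shape(table1):
    assert len(table1.records) == 15
    assert len({r.species for r in table1.records}) == 7
    assert len({r.accession for r in table1.records}) == 15
    assert len(table1.gazetteer) == 7
    # one record is rescued by a cited override; the rest carry field attributes
    assert len(table1.overrides) == 1
    assessments = [iv.assess_record(r) for r in table1.records]
    rescued, _ = iv.apply_overrides(table1.records, assessments, table1.overrides)
    assert all(a.origin is O.FIELD for a in rescued)
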