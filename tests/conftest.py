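import pytest
from hypothesis import HealthCheck, settings

import invaudit as iv

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The seven-species / fifteen-accession dual-range worked example."""
    return iv.generate_table1_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """A default-condition synthetic cohort with its planted truth."""
    config = iv.SyntheticConfig(seed=11)
    records, truths = iv.generate_cohort(config)
    return config, records, truths


@pytest.fixture()
def cohort_on_disk(tmp_path, default_cohort):
    """Default cohort written in the canonical dialect plus side tables."""
    config, records, _ = default_cohort
    table = tmp_path / "cohort.tsv"
    iv.write_assembly_table(records, table)
    gaz = tmp_path / "gazetteer.tsv"
    iv.write_home_ranges(iv.build_gazetteer(config.species_pool), gaz)
    income = tmp_path / "income.tsv"
    iv.write_income_table(iv.default_income_table(), income)
    return table, gaz, income
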