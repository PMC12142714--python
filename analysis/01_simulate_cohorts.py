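#!/usr/bin/env python
"""Generate the study cohorts the downstream analyses audit.

Writes three cohorts under results/cohorts/ in the canonical dialects, each
with its planted ground truth:

* ``assembly/`` — 199 records mirroring the audited assembly dataset's
  structure (64 field / 39 laboratory / 17 commercial / 3 managed colony /
  76 unknown origins, submissions 2010-2022);
* ``field_subset/`` — 76 all-field records with the field subset's
  spatiotemporal mixture (27 coordinate-level, 3 unlocated, 25 undated);
* a shared home-range gazetteer and GNI-per-capita table.
"""

from pathlib import Path

import invaudit as iv

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
SEED = 1


def write_cohort(name: str, config: iv.SyntheticConfig) -> None:
    outdir = OUT / name
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = iv.generate_cohort(config)
    iv.write_assembly_table(records, outdir / "cohort.tsv")
    iv.synthetic.write_planted_truth(truths, outdir / "truth.tsv")
    print(f"{name}: wrote {len(records)} records to {outdir}")


def main() -> None:
    assembly = iv.assembly_study_config(seed=SEED)
    write_cohort("assembly", assembly)
    write_cohort("field_subset", iv.field_subset_study_config(seed=SEED + 1))

    OUT.mkdir(parents=True, exist_ok=True)
    iv.write_home_ranges(
        iv.build_gazetteer(assembly.species_pool), OUT / "gazetteer.tsv"
    )
    iv.write_income_table(iv.default_income_table(), OUT / "income.tsv")

    # the literature-rescue table targets the assembly cohort's unknowns
    records = iv.read_assembly_table(OUT / "assembly" / "cohort.tsv")
    overrides = iv.build_rescue_overrides(records, n_field=12, n_nonfield=17)
    iv.write_overrides(overrides, OUT / "overrides.tsv")
    print(f"gazetteer, income table and {len(overrides)} overrides written")


if __name__ == "__main__":
    main()
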