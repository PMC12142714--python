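#!/usr/bin/env python
"""Cohort-level tabulations and the per-year deposition trend.

Summarizes the audited assembly cohort and its field subset: granularity and
completeness partitions, income groups, SRA linkage, and the per-year
field-vs-other deposition series with completeness counts. Writes a plot of
the yearly series to results/summaries/deposition_by_year.png alongside the
TSV tables.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import invaudit as iv

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohorts = BASE / "cohorts"
    records = iv.read_assembly_table(cohorts / "assembly" / "cohort.tsv")
    gazetteer = iv.read_home_ranges(cohorts / "gazetteer.tsv")
    overrides = iv.read_overrides(cohorts / "overrides.tsv")
    income = iv.read_income_table(cohorts / "income.tsv")
    result = iv.run_audit(records, gazetteer, overrides, income)

    outdir = BASE / "summaries"
    iv.write_audit_outputs(result, outdir)

    assembly = result.summaries["assembly"]
    field = result.summaries.get("field_subset")
    print(f"assembly cohort n={assembly.n}")
    for name in ("spatial", "temporal", "complete", "income_group", "sra_linked"):
        print(f"  {name}: "
              + ", ".join(f"{k}={v}" for k, v in assembly.partitions[name].items()))
    if field is not None:
        coords = field.partitions["spatial"].get("coordinates", 0)
        undated = field.partitions["temporal"].get("none", 0)
        print(f"field subset n={field.n}: "
              f"{coords} with coordinates ({iv.percent(coords, field.n, 1)}%), "
              f"{undated} lacking a date ({iv.percent(undated, field.n, 0):g}%)")

    years = sorted(assembly.per_year)
    field_series = [assembly.per_year[y].field_count for y in years]
    other_series = [assembly.per_year[y].other_count for y in years]
    complete_series = [assembly.per_year[y].complete_count for y in years]
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.bar(years, other_series, label="other origin", color="#b0b0b0")
    ax1.bar(years, field_series, bottom=other_series,
            label="field-collected", color="#2a7f3f")
    ax1.set_ylabel("assemblies deposited")
    ax1.legend(frameon=False)
    ax2.plot(years, complete_series, marker="o", color="#205080")
    ax2.set_ylabel("complete records")
    ax2.set_xlabel("submission year")
    fig.tight_layout()
    fig.savefig(outdir / "deposition_by_year.png", dpi=150)
    print(f"wrote {outdir / 'deposition_by_year.png'}")


if __name__ == "__main__":
    main()
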