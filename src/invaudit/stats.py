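"""Cohort-level tabulations of the per-record rubric outcomes.

Aggregates assessments into the partitions an audit reports: origin classes,
assembly levels, spatial/temporal granularity, completeness, range status,
income groups, SRA linkage and presence flags, plus per-year deposition
series and per-order/per-species composition. Counts are always emitted next
to percentages so rounding never hides data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import ContractError, UndefinedPercentageError
from .records import (
    AssemblyRecord,
    IncomeGroup,
    IncomeTable,
    OriginClass,
    RangeStatus,
)
from .rubric import StewardshipAssessment

__all__ = [
    "CohortSummary",
    "YearRow",
    "classify_income",
    "percent",
    "summarize_cohort",
    "tabulate_by_year",
]

#: Origin classes pooled as "other" in deposition-trend reporting
#: (everything that is not confirmed field-collected).
OTHER_ORIGINS = frozenset(
    {
        OriginClass.LABORATORY,
        OriginClass.COMMERCIAL,
        OriginClass.MANAGED_COLONY,
        OriginClass.UNKNOWN,
    }
)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*numerator/denominator, rounded half away from zero.

    This is the rounding convention used for every reported percentage
    (e.g. 76/199 -> 38 at zero decimals, 27/76 -> 35.5 at one decimal).
    """
    if denominator == 0:
        raise UndefinedPercentageError("percentage with zero denominator")
    if not 0 <= numerator <= denominator:
        raise ContractError(
            f"numerator {numerator} outside [0, {denominator}]"
        )
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def classify_income(country: str | None, table: IncomeTable) -> IncomeGroup:
    """High-income iff GNI per capita strictly exceeds the table threshold."""
    return table.classify(country)


@dataclass(frozen=True)
class YearRow:
    field_count: int
    other_count: int
    complete_count: int


@dataclass
class CohortSummary:
    """All partition counts for one cohort (reference, assembly or field)."""

    cohort_label: str
    n: int
    partitions: dict[str, dict[str, int]] = field(default_factory=dict)
    per_year: dict[int, YearRow] = field(default_factory=dict)
    per_order: dict[str, dict[str, int]] = field(default_factory=dict)
    per_species: dict[str, int] = field(default_factory=dict)

    def percentage(self, partition: str, category: str, decimals: int = 1) -> float:
        return percent(
            self.partitions[partition].get(category, 0), self.n, decimals
        )


def tabulate_by_year(
    records: list[AssemblyRecord],
    assessments: list[StewardshipAssessment],
) -> dict[int, YearRow]:
    """Per-submission-year deposition and completeness series.

    "Other" pools laboratory, commercial, managed-colony and unknown origins;
    years with no submissions inside the cohort's span are emitted as zeros.
    """
    if len(records) != len(assessments):
        raise ContractError("records and assessments are misaligned")
    if not records:
        return {}
    fields: Counter[int] = Counter()
    others: Counter[int] = Counter()
    completes: Counter[int] = Counter()
    for record, assessment in zip(records, assessments):
        year = record.submission_year
        if assessment.origin is OriginClass.FIELD:
            fields[year] += 1
        else:
            others[year] += 1
        if assessment.complete:
            completes[year] += 1
    years = [record.submission_year for record in records]
    return {
        year: YearRow(fields[year], others[year], completes[year])
        for year in range(min(years), max(years) + 1)
    }


def _count(pairs) -> dict[str, int]:
    counts: Counter[str] = Counter(pairs)
    return dict(sorted(counts.items()))


def summarize_cohort(
    records: list[AssemblyRecord],
    assessments: list[StewardshipAssessment],
    range_statuses: list[RangeStatus] | None = None,
    income_table: IncomeTable | None = None,
    cohort_label: str = "assembly",
) -> CohortSummary:
    """Aggregate aligned per-record outcomes into a cohort summary.

    Income grouping uses the submitter country, except for the field subset
    (``cohort_label="field_subset"``) where the collection country is the
    relevant geography.
    """
    if len(records) != len(assessments):
        raise ContractError("records and assessments are misaligned")
    if range_statuses is not None and len(range_statuses) != len(records):
        raise ContractError("range statuses are misaligned")

    summary = CohortSummary(cohort_label=cohort_label, n=len(records))
    pairs = list(zip(records, assessments))
    summary.partitions["origin"] = _count(str(a.origin) for _, a in pairs)
    summary.partitions["origin_source"] = _count(a.origin_source for _, a in pairs)
    summary.partitions["assembly_level"] = _count(
        str(r.assembly_level) for r, _ in pairs
    )
    summary.partitions["spatial"] = _count(str(a.spatial) for _, a in pairs)
    summary.partitions["temporal"] = _count(str(a.temporal) for _, a in pairs)
    summary.partitions["complete"] = _count(
        "true" if a.complete else "false" for _, a in pairs
    )
    summary.partitions["sra_linked"] = _count(
        "true" if r.sra_linked else "false" for r, _ in pairs
    )
    summary.partitions["is_reference"] = _count(
        "true" if r.is_reference else "false" for r, _ in pairs
    )
    for flag in ("has_tissue", "has_dev_stage", "has_sex"):
        summary.partitions[flag] = _count(
            "true" if getattr(a, flag) else "false" for _, a in pairs
        )
    if range_statuses is not None:
        summary.partitions["range"] = _count(str(s) for s in range_statuses)
    if income_table is not None:
        use_collection = cohort_label == "field_subset"
        summary.partitions["income_group"] = _count(
            str(
                classify_income(
                    a.spatial_country_code if use_collection else r.submitter_country,
                    income_table,
                )
            )
            for r, a in pairs
        )

    summary.per_year = tabulate_by_year(records, assessments)
    summary.per_species = _count(r.species for r, _ in pairs)
    per_order: dict[str, dict[str, int]] = {}
    species_by_order: dict[str, set[str]] = {}
    for record, _ in pairs:
        order = record.taxonomic_order
        per_order.setdefault(order, {"assemblies": 0})["assemblies"] += 1
        species_by_order.setdefault(order, set()).add(record.species)
    for order, seen in species_by_order.items():
        per_order[order]["species"] = len(seen)
    summary.per_order = dict(sorted(per_order.items()))
    return summary
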