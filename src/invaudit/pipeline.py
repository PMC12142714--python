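"""End-to-end audit orchestration: assess -> rescue -> range -> summarize.

This module strings the rubric, the override rescue, the range classifier and
the cohort tabulations into one deterministic run, and writes the report
files the command-line interface and the analysis drivers share:

* ``assessments.tsv`` — one row per accession with every rubric field;
* ``ranges.tsv`` — accession, species, country, admin region, range status;
* ``summary.json`` / ``summary.tsv`` — partition counts and percentages for
  the assembly cohort, the reference subset and the field-collected subset;
* ``warnings.tsv`` — aggregated parse fallbacks and skipped overrides, so the
  manual-curation debt of a cohort stays visible;
* ``provenance.json`` — input hashes, thresholds, vocabulary identity and a
  timestamp (the only non-deterministic output field);
* ``geo_points.tsv`` — coordinate-level records for external mapping.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .errors import SchemaError
from .records import (
    AssemblyRecord,
    HomeRangeEntry,
    IncomeTable,
    OriginClass,
    OverrideEntry,
    RangeStatus,
)
from .ranges import classify_cohort_ranges, find_dual_range_species
from .rubric import (
    OriginVocabulary,
    RescueReport,
    StewardshipAssessment,
    apply_overrides,
    assess_record,
)
from .stats import CohortSummary, percent, summarize_cohort

__all__ = ["AuditResult", "run_audit", "write_audit_outputs", "provenance_block"]


@dataclass
class AuditResult:
    records: list[AssemblyRecord]
    assessments: list[StewardshipAssessment]
    pre_rescue_assessments: list[StewardshipAssessment]
    rescue: RescueReport
    range_statuses: list[RangeStatus]
    dual_range_species: list[str]
    summaries: dict[str, CohortSummary] = field(default_factory=dict)


def run_audit(
    records: list[AssemblyRecord],
    gazetteer: list[HomeRangeEntry] | None = None,
    overrides: list[OverrideEntry] | None = None,
    income_table: IncomeTable | None = None,
    vocabulary: OriginVocabulary | None = None,
) -> AuditResult:
    """Run the full stewardship audit on an in-memory cohort."""
    if not records:
        raise SchemaError("empty assembly table: nothing to audit")
    gazetteer = gazetteer or []
    overrides = overrides or []
    assessments = [assess_record(record, vocabulary) for record in records]
    rescued, rescue_report = apply_overrides(records, assessments, overrides)
    range_statuses = classify_cohort_ranges(records, rescued, gazetteer, overrides)
    dual = find_dual_range_species(records, rescued, gazetteer, range_statuses)

    summaries = {
        "assembly": summarize_cohort(
            records, rescued, range_statuses, income_table, "assembly"
        )
    }
    ref_idx = [i for i, record in enumerate(records) if record.is_reference]
    if ref_idx:
        summaries["reference"] = summarize_cohort(
            [records[i] for i in ref_idx],
            [rescued[i] for i in ref_idx],
            [range_statuses[i] for i in ref_idx],
            income_table,
            "reference",
        )
    field_idx = [
        i for i, a in enumerate(rescued) if a.origin is OriginClass.FIELD
    ]
    if field_idx:
        summaries["field_subset"] = summarize_cohort(
            [records[i] for i in field_idx],
            [rescued[i] for i in field_idx],
            [range_statuses[i] for i in field_idx],
            income_table,
            "field_subset",
        )
    return AuditResult(
        records=records,
        assessments=rescued,
        pre_rescue_assessments=assessments,
        rescue=rescue_report,
        range_statuses=range_statuses,
        dual_range_species=dual,
        summaries=summaries,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def provenance_block(
    input_paths: dict[str, Path | str | None],
    income_threshold: float | None,
    rounding_decimals: int,
    vocabulary_path: str | None = None,
    timestamp: bool = True,
) -> dict:
    block: dict = {
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(Path(path))}
            for name, path in input_paths.items()
            if path is not None and Path(path).exists()
        },
        "income_threshold_usd": income_threshold,
        "rounding": {"rule": "half-away-from-zero", "decimals": rounding_decimals},
        "origin_vocabulary": vocabulary_path or "packaged default",
    }
    if timestamp:
        block["generated_at"] = datetime.now(timezone.utc).isoformat()
    return block


_ASSESSMENT_COLUMNS = (
    "accession", "origin", "origin_source", "conflict_flag", "spatial",
    "spatial_country_code", "spatial_country", "spatial_region", "latitude",
    "longitude", "temporal", "collection_date", "has_tissue", "has_dev_stage",
    "has_sex", "complete",
)


def write_audit_outputs(
    result: AuditResult,
    outdir: Path | str,
    decimals: int = 1,
    provenance: dict | None = None,
) -> None:
    """Write the full report bundle; deterministic except the timestamp."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "assessments.tsv", "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_ASSESSMENT_COLUMNS)
        for a in result.assessments:
            writer.writerow(
                [
                    a.accession, str(a.origin), a.origin_source,
                    str(a.conflict_flag).lower(), str(a.spatial),
                    a.spatial_country_code or "", a.spatial_country,
                    a.spatial_region,
                    "" if a.latitude is None else f"{a.latitude:.4f}",
                    "" if a.longitude is None else f"{a.longitude:.4f}",
                    str(a.temporal),
                    a.collection_date.isoformat() if a.collection_date else "",
                    str(a.has_tissue).lower(), str(a.has_dev_stage).lower(),
                    str(a.has_sex).lower(), str(a.complete).lower(),
                ]
            )

    with open(outdir / "ranges.tsv", "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "species", "country", "admin_region", "range_status"]
        )
        for record, a, status in zip(
            result.records, result.assessments, result.range_statuses
        ):
            writer.writerow(
                [
                    record.accession, record.species,
                    a.spatial_country_code or a.spatial_country,
                    a.spatial_region, str(status),
                ]
            )

    with open(outdir / "geo_points.tsv", "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "latitude", "longitude", "range_status"])
        for record, a, status in zip(
            result.records, result.assessments, result.range_statuses
        ):
            if a.latitude is not None and a.longitude is not None:
                writer.writerow(
                    [record.accession, f"{a.latitude:.4f}", f"{a.longitude:.4f}", str(status)]
                )

    summary_doc = {
        "dual_range_species": result.dual_range_species,
        "rescue": {
            "reclassified_to_field": result.rescue.reclassified_to_field,
            "reclassified_to_nonfield": result.rescue.reclassified_to_nonfield,
            "remaining_unknown": result.rescue.remaining_unknown,
            "skipped": [
                {"accession": e.accession, "field": e.field, "reason": reason}
                for e, reason in result.rescue.skipped
            ],
        },
        "cohorts": {},
    }
    for label, summary in result.summaries.items():
        summary_doc["cohorts"][label] = {
            "n": summary.n,
            "partitions": {
                name: {
                    category: {
                        "count": count,
                        "percent": percent(count, summary.n, decimals),
                    }
                    for category, count in partition.items()
                }
                for name, partition in summary.partitions.items()
            },
            "per_year": {
                str(year): asdict(row) for year, row in summary.per_year.items()
            },
            "per_order": summary.per_order,
            "per_species": summary.per_species,
        }
    if provenance is not None:
        summary_doc["provenance"] = provenance
    with open(outdir / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary_doc, handle, indent=2, sort_keys=True)
        handle.write("\n")

    with open(outdir / "summary.tsv", "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["cohort", "partition", "category", "count", "percent"])
        for label, summary in sorted(result.summaries.items()):
            for name, partition in sorted(summary.partitions.items()):
                for category, count in partition.items():
                    writer.writerow(
                        [label, name, category, count, percent(count, summary.n, decimals)]
                    )

    with open(outdir / "warnings.tsv", "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "source", "message"])
        for a in result.assessments:
            for message in a.warnings:
                writer.writerow([a.accession, "parse", message])
        for entry, reason in result.rescue.skipped:
            writer.writerow([entry.accession, "override", reason])

    if provenance is not None:
        with open(outdir / "provenance.json", "w", encoding="utf-8") as handle:
            json.dump(provenance, handle, indent=2, sort_keys=True)
            handle.write("\n")
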