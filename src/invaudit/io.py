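"""Readers and writers for the canonical cohort dialects.

Two equivalent on-disk representations of a cohort are supported:

* ``canonical_tsv`` — a fixed-column TSV of assembly-level fields plus a
  sidecar line-delimited JSON file of per-accession sample attributes
  (``<stem>.attributes.jsonl`` next to the table unless given explicitly);
* ``records_json`` — one combined JSON object per line carrying both the
  assembly fields and the flat attribute map.

Gazetteer, override and income tables are plain TSV. All files are UTF-8;
attribute values are stored verbatim (surrounding whitespace stripped only),
including typographic quotes and dashes.
"""

from __future__ import annotations

import csv
import json
from datetime import date
from pathlib import Path

from .countries import normalize_country
from .errors import IntegrityError, SchemaError, ValidationError
from .records import (
    AssemblyLevel,
    AssemblyRecord,
    HomeRangeEntry,
    IncomeTable,
    OverrideEntry,
    PartialDate,
    Region,
    SampleAttributes,
)

__all__ = [
    "ASSEMBLY_COLUMNS",
    "read_assembly_table",
    "write_assembly_table",
    "read_home_ranges",
    "write_home_ranges",
    "read_overrides",
    "write_overrides",
    "read_income_table",
    "write_income_table",
]

ASSEMBLY_COLUMNS = (
    "accession",
    "species",
    "taxonomic_order",
    "assembly_level",
    "submission_date",
    "submitter_institute",
    "submitter_country",
    "is_reference",
    "sra_linked",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(token: str, column: str, row: int) -> bool:
    try:
        return _BOOL[token.strip().casefold()]
    except KeyError:
        raise ValidationError(
            f"row {row}: column {column!r}: not a boolean: {token!r}"
        ) from None


def _default_attributes_path(path: Path) -> Path:
    return path.with_suffix(".attributes.jsonl")


def _check_submission_year(
    accession: str, submitted: PartialDate, window: tuple[int, int | None]
) -> None:
    low, high = window
    high = high if high is not None else date.today().year
    if not low <= submitted.year <= high:
        raise ValidationError(
            f"{accession}: submission year {submitted.year} outside "
            f"validity window {low}-{high}"
        )


def _build_record(
    fields: dict[str, str],
    attributes: SampleAttributes,
    row: int,
    year_window: tuple[int, int | None],
) -> AssemblyRecord:
    try:
        level = AssemblyLevel.from_string(fields["assembly_level"])
    except ValidationError as exc:
        raise ValidationError(f"row {row}: {exc}") from None
    try:
        submitted = PartialDate.from_iso(fields["submission_date"])
    except ValidationError as exc:
        raise ValidationError(f"row {row}: submission_date: {exc}") from None
    record = AssemblyRecord(
        accession=fields["accession"].strip(),
        species=fields["species"].strip(),
        taxonomic_order=fields["taxonomic_order"].strip(),
        assembly_level=level,
        submission_date=submitted,
        submitter_institute=fields["submitter_institute"].strip(),
        submitter_country=fields["submitter_country"].strip(),
        is_reference=_parse_bool(fields["is_reference"], "is_reference", row),
        sra_linked=_parse_bool(fields["sra_linked"], "sra_linked", row),
        attributes=attributes,
    )
    _check_submission_year(record.accession, submitted, year_window)
    return record


def _check_duplicates(records: list[AssemblyRecord]) -> None:
    seen: dict[str, int] = {}
    for record in records:
        seen[record.accession] = seen.get(record.accession, 0) + 1
    duplicates = sorted(acc for acc, n in seen.items() if n > 1)
    if duplicates:
        raise IntegrityError(f"duplicate accessions: {', '.join(duplicates)}")


def _read_attribute_sidecar(path: Path) -> dict[str, SampleAttributes]:
    attributes: dict[str, SampleAttributes] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            if "accession" not in obj:
                raise SchemaError(f"{path}:{lineno}: missing 'accession'")
            attributes[obj["accession"]] = SampleAttributes(obj.get("attributes", {}))
    return attributes


def read_assembly_table(
    path: Path | str,
    dialect: str = "canonical_tsv",
    attributes_path: Path | str | None = None,
    year_window: tuple[int, int | None] = (1990, None),
) -> list[AssemblyRecord]:
    """Read a cohort into :class:`AssemblyRecord` objects, order preserved.

    Raises :class:`SchemaError` for missing mandatory columns,
    :class:`IntegrityError` for duplicate accessions and
    :class:`ValidationError` for illegal field values.
    """
    path = Path(path)
    if dialect == "canonical_tsv":
        sidecar = (
            Path(attributes_path)
            if attributes_path is not None
            else _default_attributes_path(path)
        )
        attribute_map = _read_attribute_sidecar(sidecar) if sidecar.exists() else {}
        records: list[AssemblyRecord] = []
        with open(path, encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, header row required")
            missing = [c for c in ASSEMBLY_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
            for row_number, row in enumerate(reader, start=2):
                attrs = attribute_map.get(
                    row["accession"].strip(), SampleAttributes()
                )
                records.append(_build_record(row, attrs, row_number, year_window))
    elif dialect == "records_json":
        records = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from None
                missing = [c for c in ASSEMBLY_COLUMNS if c not in obj]
                if missing:
                    raise SchemaError(
                        f"{path}:{lineno}: missing fields: {', '.join(missing)}"
                    )
                fields = {c: str(obj[c]) for c in ASSEMBLY_COLUMNS}
                fields["is_reference"] = str(obj["is_reference"]).lower()
                fields["sra_linked"] = str(obj["sra_linked"]).lower()
                records.append(
                    _build_record(
                        fields,
                        SampleAttributes(obj.get("attributes", {})),
                        lineno,
                        year_window,
                    )
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    _check_duplicates(records)
    return records


def write_assembly_table(
    records: list[AssemblyRecord],
    path: Path | str,
    attributes_path: Path | str | None = None,
) -> None:
    """Write the canonical TSV plus the attribute sidecar (byte-stable)."""
    path = Path(path)
    sidecar = (
        Path(attributes_path)
        if attributes_path is not None
        else _default_attributes_path(path)
    )
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ASSEMBLY_COLUMNS)
        for record in records:
            writer.writerow(
                [
                    record.accession,
                    record.species,
                    record.taxonomic_order,
                    str(record.assembly_level),
                    record.submission_date.isoformat(),
                    record.submitter_institute,
                    record.submitter_country,
                    "true" if record.is_reference else "false",
                    "true" if record.sra_linked else "false",
                ]
            )
    with open(sidecar, "w", encoding="utf-8", newline="") as handle:
        for record in records:
            handle.write(
                json.dumps(
                    {
                        "accession": record.accession,
                        "attributes": record.attributes.to_dict(),
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Gazetteer
# --------------------------------------------------------------------------

def _parse_region_list(text: str, path: Path, species: str) -> frozenset[Region]:
    """Parse ``Country|Country/Admin|...`` into normalized region pairs."""
    regions: set[Region] = set()
    for chunk in text.split("|"):
        chunk = chunk.strip()
        if not chunk:
            continue
        country_part, sep, admin = chunk.partition("/")
        match = normalize_country(country_part)
        key = match.code if match.recognized else match.name.casefold()
        regions.add((key, admin.strip() if sep else None))
    return frozenset(regions)


def read_home_ranges(path: Path | str) -> list[HomeRangeEntry]:
    """Read the species home-range gazetteer.

    TSV columns: ``species``, ``native``, ``expanded``, optional ``feral``.
    Region lists are ``|``-separated countries, with an optional
    ``/admin-region`` qualifier per entry. Country names are normalized via
    the packaged alias table before storage. A bare country may sit on both
    sides only when at least one side carries admin qualifiers.
    """
    path = Path(path)
    entries: list[HomeRangeEntry] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"species", "native", "expanded"} <= set(
            reader.fieldnames
        ):
            raise SchemaError(
                f"{path}: gazetteer requires columns species, native, expanded"
            )
        for row in reader:
            species = row["species"].strip()
            native = _parse_region_list(row["native"], path, species)
            expanded = _parse_region_list(row["expanded"], path, species)
            if not native:
                raise SchemaError(f"{path}: {species}: empty native region set")
            feral = (row.get("feral") or "").strip().casefold() in {"true", "1", "yes"}
            try:
                entry = HomeRangeEntry(species, native, expanded, feral)
            except ValidationError as exc:
                raise IntegrityError(f"{path}: {exc}") from None
            bare_both = {
                c for c, a in native if a is None
            } & {c for c, a in expanded if a is None}
            qualified = {c for c, a in native | expanded if a is not None}
            illegal = bare_both - qualified
            if illegal:
                raise IntegrityError(
                    f"{path}: {species}: bare country on both sides without "
                    f"admin qualifiers: {sorted(illegal)}"
                )
            entries.append(entry)
    return entries


def _format_region_list(regions: frozenset[Region]) -> str:
    parts = []
    for country, admin in sorted(regions, key=lambda r: (r[0], r[1] or "")):
        parts.append(country if admin is None else f"{country}/{admin}")
    return "|".join(parts)


def write_home_ranges(entries: list[HomeRangeEntry], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["species", "native", "expanded", "feral"])
        for entry in entries:
            writer.writerow(
                [
                    entry.species,
                    _format_region_list(entry.native_regions),
                    _format_region_list(entry.expanded_regions),
                    "true" if entry.feral else "false",
                ]
            )


# --------------------------------------------------------------------------
# Overrides
# --------------------------------------------------------------------------

def read_overrides(path: Path | str) -> list[OverrideEntry]:
    """Read the curated override table (accession, field, value, evidence)."""
    path = Path(path)
    entries: list[OverrideEntry] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "field", "value", "evidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(f"{path}: override table requires {sorted(required)}")
        for row in reader:
            entries.append(
                OverrideEntry(
                    accession=row["accession"].strip(),
                    field=row["field"].strip(),
                    value=row["value"].strip(),
                    evidence=row["evidence"].strip(),
                )
            )
    return entries


def write_overrides(entries: list[OverrideEntry], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "field", "value", "evidence"])
        for entry in entries:
            writer.writerow([entry.accession, entry.field, entry.value, entry.evidence])


# --------------------------------------------------------------------------
# Income table
# --------------------------------------------------------------------------

def read_income_table(path: Path | str, threshold: float = 12055.0) -> IncomeTable:
    """Read country GNI per capita (columns: country_code, gni_usd)."""
    path = Path(path)
    gni: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"country_code", "gni_usd"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(f"{path}: income table requires {sorted(required)}")
        for row in reader:
            try:
                gni[row["country_code"].strip()] = float(row["gni_usd"])
            except ValueError:
                raise ValidationError(
                    f"{path}: bad GNI value {row['gni_usd']!r} "
                    f"for {row['country_code']!r}"
                ) from None
    return IncomeTable(gni=gni, threshold=threshold)


def write_income_table(table: IncomeTable, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["country_code", "gni_usd"])
        for country, value in sorted(table.gni.items()):
            writer.writerow([country, f"{value:g}"])
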