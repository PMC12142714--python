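# Methods

This note documents the models and conventions behind `invaudit`: what each
pipeline stage computes, the parameters that matter, what the synthetic
cohorts do and do not emulate, and the design choices made where repository
practice is ambiguous.

## Scope and data model

The unit of analysis is one genome-assembly submission
(`AssemblyRecord`): assembly-level fields (accession, species, taxonomic
order, assembly level contig/scaffold/chromosome, submission date,
submitter institute and country, reference-genome flag, SRA linkage) plus a
verbatim map of sample attributes in the INSDC/BioSample style. Attribute
keys are normalized to lower-case snake_case exactly once at ingest; values
are never altered beyond stripping surrounding whitespace, so the audit is
a pure function of what the submitter wrote. Three cohort views are
summarized: the full assembly cohort, the reference subset (the
repository-designated representative per species), and the field-collected
subset.

Canonical on-disk form is a fixed-column TSV plus a line-delimited JSON
attribute sidecar; an equivalent combined JSONL dialect is accepted. The
writer is byte-stable and the reader/writer pair round-trips canonical
files identically, which the suite checks. Live repository fetching is
deliberately outside the tested surface.

## Granularity parsing

**Temporal.** `collection_date` is parsed to the finest precision the
string actually carries: `YYYY`, `YYYY-MM`, `YYYY-MM-DD` (a trailing time
part is discarded) and the INSDC `Mon-YYYY` / `DD-Mon-YYYY` spellings. A
range `A/B` resolves to the granularity and value of its earliest bound —
the conservative choice for invasion timelines, where the earliest possible
collection matters. The INSDC null placeholders ("missing", "not
collected", "not applicable", "restricted access", …; packaged in
`data/insdc_null_tokens.txt`) behave exactly like an absent attribute;
"restricted access" is treated as missing because the datum is unusable
for reuse even if it exists somewhere. Any other unparseable token degrades
to `none` with a parse warning — never a hard failure, so one malformed
record cannot stop a cohort audit.

A deliberate build-over-buy choice: generic date parsers complete partial
dates to a full timestamp, destroying precisely the precision signal this
audit measures, so the partial-date grammar is implemented here.

**Spatial.** A valid `lat_lon` always yields `coordinates`. Two dialects
are accepted — hemisphere form `30.61 N 96.34 W` and a signed decimal pair
`30.61, -96.34` — with range validation (|lat| ≤ 90, |lon| ≤ 180);
degrees-minutes-seconds is rejected to a warning (an extension point, not a
silent guess). Otherwise `geo_loc_name` is split at the first colon per the
INSDC convention: a non-empty remainder ⇒ `region_city`; a recognizable
bare country ⇒ `country`; anything else ⇒ `none` plus a warning. Country
spellings are normalized through a packaged alias table
(`data/country_aliases.tsv`: ~115 countries, common aliases, and
self-resolving codes); unmatched names are carried verbatim and flagged,
never dropped. No geocoding of place names is performed.

## Origin classification

Origin is decided by keyword matching over the origin-bearing attributes
(`isolation_source`, `strain`, `isolate`, `sample_name`). The lexicon is a
packaged, editable TSV (`data/origin_vocab.tsv`) so the rubric stays
auditable; keywords match case-insensitively on word boundaries ("lab"
does not fire inside "label"). When matches span several categories the
record takes the highest-precedence class with a conflict flag:
`commercial > laboratory > managed_colony > field`. Rationale: a strain,
colony or supplier token indicates captive propagation regardless of
founder provenance, and captive genomes are the ones unsuitable for
native/expanded comparisons. No match at all ⇒ `unknown` (conflicting
records are classified-and-flagged, not unknown). The classifier is total:
it never raises.

## Completeness and rescue

A record is complete iff origin is known, location resolves to at least
country, and the collection date to at least year. Unknown-origin records
can be rescued by a curated override table; every entry needs a non-empty
citation and a legal field/value pair, and overrides are conservative:
entries targeting records already resolved from attributes, or accessions
absent from the cohort, are skipped with a warning (attributes outrank
literature). The rescue report counts reclassifications to field, to
captive classes, and the remaining unknowns; completeness is recomputed
after an origin override. Range overrides follow the same conservatism and
apply only where the computed status is `undetermined`.

## Range analysis

Field-collected records are matched against a per-species home-range
gazetteer of (country, optional admin-region) pairs. A country on exactly
one side decides directly; a country on both sides (the same-country
split, e.g. a species native to Texas with an invasive Californian
population) requires an exact admin-region match, and a record without
admin resolution stays `undetermined`, as do records with no spatial data,
species missing from the gazetteer, and species flagged feral. Admin
matching is exact string comparison after case folding — desk-scale by
design; polygon containment is out of scope. Calling the classifier on a
non-field record is a contract violation; cohort-level classification
marks such records `not_applicable` instead. Dual-range detection — at
least one native and one expanded field-collected assembly per species —
is checked in tests against a brute-force per-species scan.

## Cohort statistics

Every partition (origin, assembly level, granularities, completeness,
range, income group, SRA linkage, presence flags) is emitted as counts plus
percentages rounded half-away-from-zero at the caller's precision (default
one decimal); exhaustive partitions are checked to conserve the cohort
size. The per-year series splits submissions into field-collected versus
"other" (laboratory ∪ commercial ∪ managed colony ∪ unknown) by submission
year, zero-filling gap years, alongside a completeness count. Income
grouping is `high_income` iff GNI per capita strictly exceeds the
threshold (default USD 12,055, recorded in provenance); the submitter
country is grouped for full cohorts and the collection country for the
field subset, matching how the two questions differ (who funds sequencing
vs where samples come from). "Granular location" is operationalized as
spatial ≥ region_city and "GPS coordinates" strictly as
spatial = coordinates; reports label both explicitly.

## Synthetic cohorts

Real audit cohorts derive from repository snapshots that cannot be rebuilt
offline, so the test surface runs on generated cohorts with planted ground
truth. The generator emulates the INSDC dialects the parsers accept: ISO
dates at the planted precision, `Country: region` strings, both lat_lon
spellings, unambiguous origin keyword phrases, and null tokens or absent
keys for planted-missing fields.

Two properties make it a measurement instrument rather than a noise
source. First, **exact allocation**: every mixture is converted to integer
counts by largest remainder, so planted marginals are realized exactly and
the recovered partition is seed-invariant; seeds only permute which record
receives which category. Second, **exact recovery**: only unambiguous
template strings are emitted (unless `adversarial=True`, which adds
conflicting keyword phrases and date ranges with truth rows flagged), so
the pipeline must recover planted origin, granularity, presence and range
truth on 100 % of records — verified across twenty seeded configurations
up to n = 10⁴.

Defaults are the audited study's conditions: n = 199 submissions over
2010–2022; origins 64 field / 39 laboratory / 17 commercial / 3 managed
colony / 76 unknown (the captive split between laboratory and commercial
is not separately reported anywhere downstream and was fixed arbitrarily;
the 3 managed-colony records fill the gap the published partition leaves);
spatial 45 none / 20 country / 89 region / 45 coordinates; temporal 69
none / 40 year / 30 month / 60 day; tissue and developmental-stage
presence 134/199, sex 100/199; SRA linkage 64 %. The field-subset
configuration plants 76 all-field records with 27 coordinate-level, 38
region, 8 country, 3 unlocated and 25 undated records. The species pool is
twenty real invasive terrestrial arthropods with coarse country-level home
ranges chosen to be disjoint within each species, so planted range truth
is always recoverable; dual-range species are planted by construction
(each receives one native and one expanded field record; all other species
are confined to a single side so the planted dual set is exact, not a
lower bound). The reference flag defaults to "earliest submission per
species", mirroring how repositories designate one representative
assembly; an explicit `reference_fraction` switches to exact-fraction
allocation.

What the generator does **not** emulate: correlated missingness (real
submitters who omit location also tend to omit dates), free-text noise
beyond the packaged dialects, geocodable locality strings without a
country, sub-country gazetteer resolution in bulk, or realistic per-species
assembly-count skew. Passing tests therefore demonstrate the pipeline's
correctness on well-formed and null-token records and its bookkeeping
arithmetic — not parsing recall on arbitrary real-world free text.

## Numerical and degenerate-input conventions

* Percentages: `Decimal` arithmetic, half-away-from-zero; zero denominators
  raise rather than return a sentinel.
* Ordering: granularity enums are integer-ordered; partial dates compare by
  earliest-possible-instant (missing month/day count as January/1st).
* Ties in largest-remainder allocation break toward the earlier category in
  mixture order; allocation is deterministic.
* Empty cohorts are a schema error for the audit entry point; individual
  parsers accept absent values and return the bottom granularity.
* Submission years are validated against a configurable window (default
  1990–current year).
* Determinism: audits of a fixed cohort are byte-stable; the only
  non-deterministic output field is the provenance timestamp.

## Problem sizes

The suite and the drivers run cohorts of 60–400 records plus one
10⁴-record recovery check; these sizes give exact, deterministic targets
(allocation is count-based, so nothing is gained statistically by larger
n). The whole suite completes in a few seconds on one CPU.

## Known limitations

* Country recognition is bounded by the packaged alias table; names
  outside it downgrade a bare-country location to `none` (flagged).
* The origin lexicon is keyword-based; prose like "collected near the lab"
  will misfire toward `laboratory` — the conflict flag and warnings TSV
  exist precisely to surface such records for manual review.
* Range classification is categorical (country/admin string match); no
  spatial containment, so coordinate-only records without a country string
  cannot be range-classified.
* Literature rescue is modeled as an input table; the laborious search
  that produces it is out of scope.
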