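"""The stewardship rubric: granularity parsing, origin, rescue, completeness."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import invaudit as iv
from invaudit.rubric import (
    ORIGIN_PRECEDENCE,
    OriginVocabulary,
    null_tokens,
    parse_collection_date,
    parse_location,
)

T = iv.TemporalGranularity
S = iv.SpatialGranularity
O = iv.OriginClass


# --------------------------------------------------------------------------
# collection_date
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,granularity,date",
    [
        ("2019-03-15", T.DAY, (2019, 3, 15)),
        ("2018", T.YEAR, (2018, None, None)),
        ("2018-07", T.MONTH, (2018, 7, None)),
        ("15-Mar-2019", T.DAY, (2019, 3, 15)),
        ("Mar-2019", T.MONTH, (2019, 3, None)),
        ("2019-03-15T10:31:02Z", T.DAY, (2019, 3, 15)),
        ("2016/2017", T.YEAR, (2016, None, None)),
        ("2017-05/2016-11", T.MONTH, (2016, 11, None)),  # earliest bound wins
    ],
)
def test_collection_date_precision(raw, granularity, date):
    parsed = parse_collection_date(raw)
    assert parsed.granularity == granularity
    assert (
        parsed.date.year,
        parsed.date.month,
        parsed.date.day,
    ) == date


@pytest.mark.parametrize("token", ["missing", "not collected", "Not Applicable",
                                   "restricted access", "", None])
def test_null_tokens_yield_no_temporal_data(token):
    assert parse_collection_date(token).granularity is T.NONE


def test_unparseable_date_warns_but_never_fails():
    parsed = parse_collection_date("summer of 2019?")
    assert parsed.granularity is T.NONE
    assert parsed.warnings


@given(
    y1=st.integers(1990, 2023), m1=st.integers(1, 12),
    y2=st.integers(1990, 2023), m2=st.integers(1, 12),
)
def test_range_rule_matches_bruteforce_min_of_bounds(y1, m1, y2, m2):
    """A date range resolves to whichever bound a naive parser finds earliest."""
    a, b = f"{y1}-{m1:02d}", f"{y2}-{m2:02d}"
    expected = min(
        [parse_collection_date(a).date, parse_collection_date(b).date],
        key=iv.PartialDate.sort_key,
    )
    assert parse_collection_date(f"{a}/{b}").date == expected


# --------------------------------------------------------------------------
# location
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "geo,lat_lon,granularity",
    [
        ("United Kingdom: Wytham Great Wood", None, S.REGION_CITY),
        ("USA", None, S.COUNTRY),
        (None, "30.61 N 96.34 W", S.COORDINATES),
        ("missing", None, S.NONE),
        (None, None, S.NONE),
        ("Atlantis", None, S.NONE),  # unrecognized bare name
        ("Atlantis: Underwater City", None, S.REGION_CITY),
    ],
)
def test_spatial_granularity_levels(geo, lat_lon, granularity):
    assert parse_location(geo, lat_lon).granularity is granularity


def test_hemisphere_sign_convention():
    parsed = parse_location(None, "30.61 N 96.34 W")
    assert parsed.latitude == pytest.approx(30.61)
    assert parsed.longitude == pytest.approx(-96.34)
    signed = parse_location(None, "-41.27, 173.28")
    assert signed.latitude == pytest.approx(-41.27)
    assert signed.longitude == pytest.approx(173.28)


def test_country_extracted_alongside_region():
    parsed = parse_location("United Kingdom: Wytham Great Wood", None)
    assert parsed.country_code == "GB"
    assert parsed.region == "Wytham Great Wood"


@pytest.mark.parametrize(
    "bad", ["12 deg 21 min N", "91.0 N 10.0 E", "200, 10", "here"]
)
def test_malformed_lat_lon_falls_back_with_warning(bad):
    parsed = parse_location("New Zealand", bad)
    assert parsed.granularity is S.COUNTRY
    assert any("lat_lon" in w for w in parsed.warnings)


@given(st.sampled_from(sorted(null_tokens())))
def test_null_token_idempotence_spatial_and_temporal(token):
    """Every INSDC null token behaves exactly like an absent attribute."""
    assert parse_location(token, None).granularity is S.NONE
    assert parse_location(None, token).granularity is S.NONE
    assert parse_collection_date(token).granularity is T.NONE


# --------------------------------------------------------------------------
# origin classification
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "attrs,expected,conflict",
    [
        ({"isolation_source": "wild caught, pheromone trap"}, O.FIELD, False),
        ({"strain": "inbred lab colony G21"}, O.LABORATORY, True),
        ({"isolation_source": "purchased from commercial supplier"}, O.COMMERCIAL, False),
        ({"isolation_source": "managed apiary"}, O.MANAGED_COLONY, False),
        ({"isolation_source": "missing", "strain": "not collected"}, O.UNKNOWN, False),
        ({}, O.UNKNOWN, False),
        ({"isolation_source": "field-collected founders, lab colony F12"}, O.LABORATORY, True),
    ],
)
def test_origin_keyword_rules(attrs, expected, conflict):
    origin, flag = iv.classify_origin(iv.SampleAttributes(attrs))
    assert origin is expected
    assert flag is conflict


def test_precedence_matches_bruteforce_enumeration():
    """Multi-category matches resolve to the highest-precedence category."""
    vocab = OriginVocabulary.default()
    probes = {
        O.FIELD: "wild",
        O.LABORATORY: "inbred",
        O.COMMERCIAL: "purchased",
        O.MANAGED_COLONY: "apiary",
    }
    import itertools

    for r in (1, 2, 3, 4):
        for combo in itertools.combinations(probes, r):
            text = ", ".join(probes[c] for c in combo)
            origin, flag = iv.classify_origin(
                iv.SampleAttributes({"isolation_source": text}), vocab
            )
            # independent oracle: naive scan of every keyword, then precedence
            matched = {
                cat
                for cat, words in vocab.keywords.items()
                if any(w in text.split(", ") for w in words)
            }
            expected = next(c for c in ORIGIN_PRECEDENCE if c in matched)
            assert origin is expected
            assert flag is (len(combo) > 1)


def test_keywords_match_on_word_boundaries():
    # "lab" must not fire inside "label"; "laboratory" is its own keyword
    origin, _ = iv.classify_origin(
        iv.SampleAttributes({"isolation_source": "labelled voucher, wild caught"})
    )
    assert origin is O.FIELD


# --------------------------------------------------------------------------
# completeness and composition
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "origin,spatial,temporal,expected",
    [
        (O.FIELD, S.COUNTRY, T.YEAR, True),
        (O.LABORATORY, S.COORDINATES, T.DAY, True),
        (O.UNKNOWN, S.COORDINATES, T.DAY, False),
        (O.LABORATORY, S.NONE, T.YEAR, False),
        (O.FIELD, S.COUNTRY, T.NONE, False),
    ],
)
def test_completeness_rubric(origin, spatial, temporal, expected):
    assert iv.assess_completeness(origin, spatial, temporal) is expected


def test_assess_record_composes_all_axes(table1):
    by_acc = {r.accession: r for r in table1.records}
    a = iv.assess_record(by_acc["GCA_905475345.1"])
    assert a.origin is O.FIELD
    assert a.spatial is S.COORDINATES  # lat_lon provided
    assert a.spatial_country_code == "GB"
    assert a.spatial_region == "Wytham Great Wood"
    assert a.complete

    bare = iv.AssemblyRecord(
        accession="GCA_0.1", species="X y", taxonomic_order="Diptera",
        assembly_level=iv.AssemblyLevel.CONTIG,
        submission_date=iv.PartialDate(2020),
        submitter_institute="", submitter_country="",
        is_reference=False, sra_linked=False,
    )
    b = iv.assess_record(bare)
    assert (b.origin, b.spatial, b.temporal, b.complete) == (
        O.UNKNOWN, S.NONE, T.NONE, False
    )
    assert not (b.has_tissue or b.has_dev_stage or b.has_sex)


@given(st.data())
def test_enrichment_never_lowers_granularity_or_completeness(data):
    """Adding information (coordinates, day precision) is monotone."""
    geo = data.draw(st.sampled_from([None, "missing", "New Zealand",
                                     "New Zealand: Pelorus"]))
    base = parse_location(geo, None)
    enriched = parse_location(geo, "41.27 S 173.28 E")
    assert enriched.granularity >= base.granularity

    year = data.draw(st.integers(1990, 2022))
    assert (
        parse_collection_date(f"{year}-06-01").granularity
        >= parse_collection_date(str(year)).granularity
    )

    origin = data.draw(st.sampled_from(list(O)))
    if iv.assess_completeness(origin, base.granularity,
                              parse_collection_date(str(year)).granularity):
        assert iv.assess_completeness(
            origin, enriched.granularity,
            parse_collection_date(f"{year}-06-01").granularity,
        )


# --------------------------------------------------------------------------
# literature rescue
# --------------------------------------------------------------------------

def _unknown_record(i):
    return iv.AssemblyRecord(
        accession=f"GCA_{i:04d}.1", species="X y", taxonomic_order="Diptera",
        assembly_level=iv.AssemblyLevel.SCAFFOLD,
        submission_date=iv.PartialDate(2018),
        submitter_institute="", submitter_country="",
        is_reference=False, sra_linked=False,
    )


def test_rescue_closes_the_unknown_gap_to_47():
    """76 unknowns minus 12 field and 17 captive rescues leaves 47."""
    records = [_unknown_record(i) for i in range(76)]
    assessments = [iv.assess_record(r) for r in records]
    overrides = [
        iv.OverrideEntry(records[i].accession, "origin", "field", "lit")
        for i in range(12)
    ] + [
        iv.OverrideEntry(records[12 + i].accession, "origin", "laboratory", "lit")
        for i in range(17)
    ]
    updated, report = iv.apply_overrides(records, assessments, overrides)
    assert report.reclassified_to_field == 12
    assert report.reclassified_to_nonfield == 17
    assert report.remaining_unknown == 47
    assert sum(1 for a in updated if a.origin is O.UNKNOWN) == 47
    assert all(
        a.origin_source == "override"
        for a in updated
        if a.origin is not O.UNKNOWN
    )


def test_rescue_is_conservative_and_monotone(default_cohort):
    """Overrides never touch attribute-resolved records or grow the unknowns."""
    _, records, _ = default_cohort
    assessments = [iv.assess_record(r) for r in records]
    unknown_before = sum(1 for a in assessments if a.origin is O.UNKNOWN)
    resolved = next(
        r for r, a in zip(records, assessments) if a.origin is not O.UNKNOWN
    )
    overrides = [
        iv.OverrideEntry(resolved.accession, "origin", "laboratory", "lit"),
        iv.OverrideEntry("GCA_not_in_cohort.1", "origin", "field", "lit"),
    ]
    updated, report = iv.apply_overrides(records, assessments, overrides)
    assert updated == assessments  # both entries skipped
    assert len(report.skipped) == 2
    assert report.remaining_unknown == unknown_before

    empty, report2 = iv.apply_overrides(records, assessments, [])
    assert empty == assessments
    assert not report2.skipped
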