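"""Harmonization rules: table reading, IDA conversion, the high-income
vitamin A assumption, regional stunting imputation, and the
development-based exclusion partition."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hiddenhunger import (
    ConversionPolicy,
    CountryRecord,
    PrevalenceEstimate,
    Provenance,
    WHORegion,
    apply_exclusions,
    assume_vad_free,
    convert_anemia_to_ida,
    harmonize,
    ida_estimate,
    impute_stunting,
    read_country_table,
)
from hiddenhunger.harmonize import REASON_HDI, REASON_LEI, REASON_NO_DATA, REASON_NO_SCORE
from hiddenhunger.records import AgeGroup


def prev(v, prov=Provenance.NATIONAL_SURVEY):
    if v is None:
        return PrevalenceEstimate(None, AgeGroup.PRESCHOOL, Provenance.MISSING)
    return PrevalenceEstimate(v, AgeGroup.PRESCHOOL, prov)


def country(iso3="AAA", region=WHORegion.AFR, **kw):
    kw.setdefault("population_2009", 1e6)
    return CountryRecord(iso3=iso3, name=iso3.title(), who_region=region, **kw)


# --- table reading ---------------------------------------------------------

HEADER = ("iso3,name,who_region,ssa_member,hdi_2007,lei_2007,gdp_2005,"
          "population_2009,under5_population,malaria_endemic,"
          "stunting,stunting_prov,anemia,anemia_prov,vad,vad_prov,id,id_prov\n")


def test_read_country_table_roundtrips_values_and_missingness(tmp_path):
    rows = [
        "ner,Niger,AFR,true,0.34,,700,15000000,2900000,true,"
        "47,national_survey,72,who_regression,67,national_survey,35,national_survey\n",
        "CUB,Cuba,AMR,false,0.86,,4000,11200000,650000,false,"
        "7,national_survey,,,3,national_survey,,\n",
        "HUN,Hungary,EUR,false,0.88,,18000,10000000,480000,false,"
        "2,national_survey,11,national_survey,1,national_survey,,\n",
    ]
    path = tmp_path / "t.csv"
    path.write_text(HEADER + "".join(rows))
    recs = read_country_table(path)
    assert [r.iso3 for r in recs] == ["NER", "CUB", "HUN"]  # normalized upper
    assert recs[0].anemia.provenance is Provenance.WHO_REGRESSION
    assert recs[0].malaria_endemic and not recs[1].malaria_endemic
    # empty anemia cell -> missing with missing provenance
    assert recs[1].anemia.is_missing
    assert recs[1].anemia.provenance is Provenance.MISSING
    assert recs[2].gdp_2005 == 18000


def test_read_country_table_duplicate_iso3_is_hard_error(tmp_path):
    row = "NER,Niger,AFR,true,0.34,,700,15000000,,true,47,,72,,67,,35,\n"
    path = tmp_path / "dup.csv"
    path.write_text(HEADER + row + row)
    with pytest.raises(ValueError, match="NER"):
        read_country_table(path)


def test_read_country_table_missing_mandatory_column_is_hard_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("iso3,name\nNER,Niger\n")
    with pytest.raises(ValueError, match="who_region"):
        read_country_table(path)


def test_read_country_table_unparseable_numeric_becomes_missing(tmp_path, caplog):
    path = tmp_path / "warn.csv"
    path.write_text(HEADER + "NER,Niger,AFR,true,abc,,700,15000000,,true,47,,72,,67,,,\n")
    with caplog.at_level("WARNING"):
        recs = read_country_table(path)
    assert recs[0].hdi_2007 is None
    assert any("hdi_2007" in m for m in caplog.messages)


def test_tab_dialect_accepted(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(HEADER.replace(",", "\t")
                    + "NER\tNiger\tAFR\ttrue\t0.34\t\t700\t15000000\t\ttrue\t47\t\t72\t\t67\t\t35\t\n")
    assert read_country_table(path)[0].stunting.value == 47


# --- anemia -> IDA ---------------------------------------------------------

@pytest.mark.parametrize(
    "anemia,malaria,expected",
    [(100.0, False, 60.0), (100.0, True, 50.0), (0.0, False, 0.0), (0.0, True, 0.0)],
)
def test_ida_conversion_constants(anemia, malaria, expected, policy):
    assert convert_anemia_to_ida(anemia, malaria, policy) == expected


@given(a=st.floats(0, 100), k=st.floats(0, 1), malaria=st.booleans())
def test_ida_conversion_is_linear(a, k, malaria):
    lhs = convert_anemia_to_ida(a, malaria) * k
    rhs = convert_anemia_to_ida(a * k, malaria)
    assert math.isclose(lhs, rhs, rel_tol=1e-12, abs_tol=1e-12)


def test_missing_anemia_gives_missing_ida_and_provenance_inherits(policy):
    r = country(anemia=prev(None))
    assert ida_estimate(r, policy).is_missing
    r2 = country(anemia=prev(40.0, Provenance.WHO_REGRESSION))
    est = ida_estimate(r2, policy)
    assert est.value == 24.0 and est.provenance is Provenance.WHO_REGRESSION


# --- vitamin A assumption --------------------------------------------------

def test_vad_assumed_zero_above_gdp_threshold(policy):
    r = assume_vad_free(country(gdp_2005=20_000.0, vad=prev(None)), policy)
    assert r.vad.value == 0.0 and r.vad.provenance is Provenance.ASSUMED_ZERO


@pytest.mark.parametrize("gdp,vad_in", [(20_000.0, 5.0), (10_000.0, None), (None, None)])
def test_vad_assumption_never_overwrites_or_fires_below_threshold(gdp, vad_in, policy):
    r = assume_vad_free(country(gdp_2005=gdp, vad=prev(vad_in)), policy)
    if vad_in is not None:
        assert r.vad.value == vad_in and r.vad.provenance is Provenance.NATIONAL_SURVEY
    else:
        assert r.vad.is_missing


def test_gdp_boundary_is_closed(policy):
    r = assume_vad_free(country(gdp_2005=15_000.0, vad=prev(None)), policy)
    assert r.vad.provenance is Provenance.ASSUMED_ZERO


# --- stunting imputation ---------------------------------------------------

def test_imputed_stunting_is_population_weighted_regional_mean():
    recs = [
        country("DNA", stunting=prev(30.0), population_2009=10e6),
        country("DNB", stunting=prev(10.0), population_2009=30e6),
        country("GAP", stunting=prev(None), population_2009=5e6),
    ]
    out = {r.iso3: r for r in impute_stunting(recs)}
    assert out["GAP"].stunting.value == pytest.approx(15.0)  # (30*10+10*30)/40
    assert out["GAP"].stunting.provenance is Provenance.REGIONAL_IMPUTATION
    # donors untouched
    assert out["DNA"].stunting.provenance is Provenance.NATIONAL_SURVEY


@pytest.mark.parametrize("donor_values", [[22.0], [40.0, 40.0, 40.0]])
def test_single_donor_and_constant_donors(donor_values):
    recs = [
        country(f"D{i:02d}", stunting=prev(v), population_2009=(i + 1) * 1e6)
        for i, v in enumerate(donor_values)
    ] + [country("GAP", stunting=prev(None))]
    out = {r.iso3: r for r in impute_stunting(recs)}
    assert out["GAP"].stunting.value == pytest.approx(donor_values[0])


def test_region_without_donors_stays_missing(caplog):
    recs = [country("LON", region=WHORegion.SEAR, stunting=prev(None))]
    with caplog.at_level("WARNING"):
        out = impute_stunting(recs)
    assert out[0].stunting.is_missing


@given(
    data=st.lists(
        st.tuples(st.floats(0, 100), st.floats(1e4, 1e9)), min_size=1, max_size=12
    )
)
def test_imputed_value_within_donor_range(data):
    recs = [
        country(f"D{i:02d}", stunting=prev(v), population_2009=p)
        for i, (v, p) in enumerate(data)
    ] + [country("GAP", stunting=prev(None), population_2009=1e6)]
    out = {r.iso3: r for r in impute_stunting(recs)}
    values = [v for v, _ in data]
    got = out["GAP"].stunting.value
    assert min(values) - 1e-9 <= got <= max(values) + 1e-9


def test_imputation_is_single_pass_imputed_values_never_donate():
    # two regions: AFR has a donor; SEAR has only a missing value, so a
    # freshly imputed AFR value must not leak across (and a second
    # missing AFR value must see only the original donor)
    recs = [
        country("DON", stunting=prev(20.0), population_2009=1e6),
        country("GPA", stunting=prev(None), population_2009=9e9),
        country("GPB", stunting=prev(None), population_2009=1e6),
    ]
    out = {r.iso3: r for r in impute_stunting(recs)}
    assert out["GPA"].stunting.value == pytest.approx(20.0)
    assert out["GPB"].stunting.value == pytest.approx(20.0)  # unaffected by GPA's huge population


# --- exclusions ------------------------------------------------------------

def test_exclusion_reasons_and_partition(policy):
    recs = [
        country("HIH", hdi_2007=0.95, anemia=prev(5.0)),
        country("LEI", lei_2007=0.92, anemia=prev(5.0)),
        country("NOS", anemia=prev(5.0)),
        country("NOD", hdi_2007=0.5, stunting=prev(30.0)),
        country("INC", hdi_2007=0.85, anemia=prev(40.0),
                vad=prev(None)),  # vad missing but anemia present -> included
    ]
    included, excluded = apply_exclusions(recs, policy)
    reasons = {r.iso3: reason for r, reason in excluded}
    assert reasons == {
        "HIH": REASON_HDI, "LEI": REASON_LEI, "NOS": REASON_NO_SCORE, "NOD": REASON_NO_DATA,
    }
    assert [r.iso3 for r in included] == ["INC"]
    # partition: disjoint and exhaustive
    assert len(included) + len(excluded) == len(recs)
    assert {r.iso3 for r in included}.isdisjoint(reasons)


def test_hdi_boundary_exactly_09_is_excluded(policy):
    _, excluded = apply_exclusions([country("EDG", hdi_2007=0.9, anemia=prev(5.0))], policy)
    assert excluded and excluded[0][1] == REASON_HDI


def test_hdi_takes_precedence_over_lei(policy):
    # present HDI below threshold wins even if LEI is above it
    included, _ = apply_exclusions(
        [country("PRE", hdi_2007=0.85, lei_2007=0.95, anemia=prev(5.0))], policy
    )
    assert included


# --- full harmonization on the worked set ----------------------------------

def test_worked_set_harmonization(worked):
    countries, _ = worked
    included, excluded = harmonize(countries)
    assert {r.iso3 for r in included} == {"WKA", "WKB", "WKC", "WKD", "WKH", "WKI", "WKJ"}
    reasons = {r.iso3: reason for r, reason in excluded}
    assert reasons == {"WKE": REASON_HDI, "WKF": REASON_LEI, "WKG": REASON_NO_DATA}
    by = {r.iso3: r for r in included}
    # GDP 20,000 with no retinol data -> assumed free of VAD
    assert by["WKH"].vad.value == 0.0
    assert by["WKH"].vad.provenance is Provenance.ASSUMED_ZERO
    # regional imputation: (40*10M + 60*30M) / 40M = 55
    assert by["WKI"].stunting.value == pytest.approx(55.0)
    assert by["WKI"].stunting.provenance is Provenance.REGIONAL_IMPUTATION


def test_provenance_conservation_through_harmonize(worked):
    countries, _ = worked

    def tally(recs):
        t = {}
        for r in recs:
            for f in ("stunting", "anemia", "vad", "id"):
                t[getattr(r, f).provenance] = t.get(getattr(r, f).provenance, 0) + 1
        return t

    before = tally(countries)
    included, excluded = harmonize(countries)
    after = tally(included + [r for r, _ in excluded])
    # every estimate still carries exactly one tag; totals reconcile
    assert sum(before.values()) == sum(after.values()) == 4 * len(countries)
    # the only permitted tag transitions are missing -> assumed_zero/imputed
    gained = (
        after.get(Provenance.ASSUMED_ZERO, 0) - before.get(Provenance.ASSUMED_ZERO, 0)
        + after.get(Provenance.REGIONAL_IMPUTATION, 0) - before.get(Provenance.REGIONAL_IMPUTATION, 0)
    )
    lost = before.get(Provenance.MISSING, 0) - after.get(Provenance.MISSING, 0)
    assert gained == lost
    for p in (Provenance.NATIONAL_SURVEY, Provenance.WHO_REGRESSION):
        assert before.get(p, 0) == after.get(p, 0)
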