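"""Domain types, registry, CSV I/O and validation."""

import math

import pandas as pd
import pytest

from tubewell_risk.core_data import (
    Dataset,
    GuidelineRule,
    LoadError,
    export_geojson,
    load_samples,
    validate_dataset,
    write_samples,
)

from conftest import build_dataset


# (authority, parameter) -> (lower, upper, exceed_mode): the shipped registry.
EXPECTED_REGISTRY = {
    ("WHO", "ph"): (6.5, 8.5, "outside_range"),
    ("USEPA", "ph"): (6.5, 8.5, "outside_range"),
    ("BDWS", "ph"): (6.5, 8.5, "outside_range"),
    ("WHO", "ec"): (None, 250, "above_upper"),
    ("WHO", "tds"): (600, 1000, "above_upper"),
    ("USEPA", "tds"): (None, 500, "above_upper"),
    ("BDWS", "tds"): (None, 1000, "above_upper"),
    ("WHO", "fe"): (None, 0.3, "above_upper"),
    ("USEPA", "fe"): (None, 0.3, "above_upper"),
    ("BDWS", "fe"): (0.3, 1.0, "above_upper"),
    ("WHO", "as"): (None, 0.01, "above_upper"),
    ("USEPA", "as"): (None, 0.01, "above_upper"),
    ("BDWS", "as"): (None, 0.05, "above_upper"),
}


def test_registry_matches_published_standards(registry):
    """The shipped registry reproduces the standards table cell for cell."""
    got = {(r.authority, r.parameter): (r.lower, r.upper, r.exceed_mode)
           for r in registry}
    assert got == EXPECTED_REGISTRY


def test_guideline_rule_rejects_inverted_bounds():
    with pytest.raises(ValueError):
        GuidelineRule("WHO", "fe", lower=2.0, upper=1.0, exceed_mode="above_upper")
    with pytest.raises(ValueError):
        GuidelineRule("WHO", "fe", lower=None, upper=None, exceed_mode="above_upper")


def test_round_trip_preserves_dataset(tmp_path):
    """read -> write -> read yields field-identical records in order."""
    d = build_dataset(
        sample_id=["A", "B", "C"],
        union=["Bagoan", "Dariapur", "Monakhali"],
        fe=[0.0, 1.23, 4.99],
        **{"as": [0.0, 0.075, 0.175]},
    )
    p = tmp_path / "wells.csv"
    write_samples(d, p)
    d2 = load_samples(p)
    assert list(d2.df["sample_id"]) == ["A", "B", "C"]
    pd.testing.assert_frame_equal(d.df, d2.df)
    # second round trip is byte-stable
    p2 = tmp_path / "wells2.csv"
    write_samples(d2, p2)
    assert p.read_text() == p2.read_text()


def test_load_rejects_out_of_range_iron(tmp_path):
    """A reading beyond the colorimeter full scale cannot be a real record."""
    p = tmp_path / "bad.csv"
    p.write_text(
        "sample_id,union,depth,ph,ec,tds,fe,as\n"
        "ok,Bagoan,300,7,900,460,1.0,0.01\n"
        "hot,Bagoan,300,7,900,460,7.1,0.01\n")
    d = load_samples(p)
    assert list(d.df["sample_id"]) == ["ok"]
    assert len(d.rejected) == 1
    assert "fe" in d.rejected[0] and "row 3" in d.rejected[0]


def test_load_flags_extended_scale_arsenic(tmp_path):
    """As in (0.5, 5] is kept but flagged as an extended-scale reading."""
    p = tmp_path / "ext.csv"
    p.write_text("sample_id,union,depth,ph,ec,tds,fe,as\n"
                 "x,Bagoan,300,7,900,460,1.0,0.8\n")
    d = load_samples(p)
    assert len(d) == 1
    assert len(d.flags) == 1 and "extended" in d.flags[0]


def test_union_alias_canonicalization(tmp_path):
    """Variant spellings map onto the four canonical unions."""
    p = tmp_path / "alias.csv"
    p.write_text("sample_id,union,depth,ph,ec,tds,fe,as\n"
                 "a,Baguan,300,7,900,460,1.0,0.01\n"
                 "b,Moahajanpur,300,7,900,460,1.0,0.01\n")
    d = load_samples(p)
    assert list(d.df["union"]) == ["Bagoan", "Mohajanpur"]
    with pytest.raises(LoadError, match="unknown union"):
        q = tmp_path / "bad_union.csv"
        q.write_text("sample_id,union,depth,ph,ec,tds,fe,as\n"
                     "a,Atlantis,300,7,900,460,1.0,0.01\n")
        load_samples(q)


def test_load_errors_name_row_and_column(tmp_path):
    p = tmp_path / "nonnum.csv"
    p.write_text("sample_id,union,depth,ph,ec,tds,fe,as\n"
                 "a,Bagoan,300,7,900,460,abc,0.01\n")
    with pytest.raises(LoadError, match="row 2.*'fe'"):
        load_samples(p)
    with pytest.raises(LoadError, match="no such file"):
        load_samples(tmp_path / "missing.csv")


def test_missing_optional_fields_become_nan_not_zero(tmp_path):
    p = tmp_path / "gaps.csv"
    p.write_text("sample_id,union,depth,ph,ec,tds,fe,as,temperature\n"
                 "a,Bagoan,300,7,900,460,1.0,0.01,\n")
    d = load_samples(p)
    assert math.isnan(d.df["temperature"].iat[0])
    assert math.isnan(d.df["salinity"].iat[0])


def test_validate_dataset_reports():
    empty = build_dataset(n=1)
    empty = Dataset(df=empty.df.iloc[:0], provenance="t")
    rep = validate_dataset(empty)
    assert rep.empty and rep.ok

    dup = build_dataset(sample_id=["X", "X"], ph=[7.0, 15.0])
    rep = validate_dataset(dup)
    msgs = [i.message for i in rep.issues]
    assert any("duplicate id" in m for m in msgs)
    assert any("ph 15.0 out of [0, 14]" in m for m in msgs)
    # pure function: no mutation
    assert list(dup.df["ph"]) == [7.0, 15.0]


def test_geojson_export_point_features(tmp_path):
    import json
    d = build_dataset(sample_id=["A", "B"], longitude=[88.6, float("nan")])
    out = tmp_path / "pts.geojson"
    export_geojson(d.df, out)
    payload = json.loads(out.read_text())
    assert payload["type"] == "FeatureCollection"
    assert len(payload["features"]) == 1  # NaN-coordinate row skipped
    feat = payload["features"][0]
    assert feat["geometry"]["coordinates"] == [88.6, 23.7]
    assert feat["properties"]["sample_id"] == "A"
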