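"""Instrument config, response CSV round-trips, exclusions, tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from saqirt.instrument import (
    ExclusionReport,
    ResponseMatrix,
    filter_complete,
    load_instrument,
    read_responses,
    saqc_instrument,
    summarize_sample,
    write_responses,
)

TWO_DOMAIN_CFG = {
    "domains": [
        {"id": "A", "items": ["A1", "A2"]},
        {"id": "B", "items": ["B1"]},
    ],
    "n_categories": 5,
}


def small_matrix():
    data = pd.DataFrame(
        {
            "A1": pd.array([1, 2, None, 4, 5, 3], dtype="Int64"),
            "A2": pd.array([5, 4, 3, 2, 1, 2], dtype="Int64"),
            "B1": pd.array([3, 3, 2, None, 1, 5], dtype="Int64"),
        }
    )
    group = pd.Series(["g1", "g2", "g1", "g1", None, "g2"], dtype="string", name="group")
    meta = pd.DataFrame({"gender": ["f", "f", "m", "f", "f", None]})
    return ResponseMatrix(data=data, group=group, metadata=meta)


class TestInstrumentSpec:
    def test_bundled_saqc_layout(self):
        spec = saqc_instrument()
        assert spec.domain_ids == ("TC", "SC", "JS", "PM", "WC")
        assert [len(spec.items_for(d)) for d in spec.domain_ids] == [5, 6, 5, 10, 4]
        assert spec.n_items == 30
        assert all(spec.n_categories[i] == 5 for i in spec.item_ids)

    def test_minimal_single_item_binary(self):
        spec = load_instrument(
            {"domains": [{"id": "D", "items": ["x"]}], "n_categories": 2}
        )
        assert spec.item_ids == ("x",)
        assert spec.n_categories["x"] == 2

    def test_duplicate_item_rejected(self):
        cfg = {
            "domains": [
                {"id": "A", "items": ["TC1"]},
                {"id": "B", "items": ["TC1"]},
            ]
        }
        with pytest.raises(ValueError, match="more than one domain"):
            load_instrument(cfg)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError, match="n_categories"):
            load_instrument({"domains": [{"id": "D", "items": ["x"]}], "n_categories": 1})

    def test_yaml_and_json_files(self, tmp_path):
        import json

        import yaml

        jp = tmp_path / "spec.json"
        jp.write_text(json.dumps(TWO_DOMAIN_CFG))
        yp = tmp_path / "spec.yaml"
        yp.write_text(yaml.safe_dump(TWO_DOMAIN_CFG))
        assert load_instrument(jp).item_ids == load_instrument(yp).item_ids == ("A1", "A2", "B1")


class TestReadWriteResponses:
    def test_roundtrip_identity(self, tmp_path):
        spec = load_instrument(TWO_DOMAIN_CFG)
        matrix = small_matrix()
        path = tmp_path / "resp.csv"
        write_responses(matrix, path)
        back = read_responses(path, spec)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), matrix.data.reset_index(drop=True)
        )
        assert back.group.isna().tolist() == matrix.group.isna().tolist()
        assert back.group.dropna().tolist() == matrix.group.dropna().tolist()
        assert back.metadata["gender"].fillna("NA").tolist() == matrix.metadata[
            "gender"
        ].fillna("NA").tolist()

    @given(
        codes=st.lists(
            st.lists(st.one_of(st.none(), st.integers(1, 5)), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    def test_roundtrip_property(self, codes, tmp_path_factory):
        spec = load_instrument(TWO_DOMAIN_CFG)
        data = pd.DataFrame(
            [[pd.NA if v is None else v for v in row] for row in codes],
            columns=["A1", "A2", "B1"],
            dtype="Int64",
        )
        matrix = ResponseMatrix(data=data)
        path = tmp_path_factory.mktemp("rt") / "r.csv"
        write_responses(matrix, path)
        back = read_responses(path, spec)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), matrix.data.reset_index(drop=True)
        )

    def test_out_of_range_cell_named(self, tmp_path):
        spec = load_instrument(TWO_DOMAIN_CFG)
        path = tmp_path / "bad.csv"
        path.write_text("A1,A2,B1\n1,2,3\n6,2,3\n")
        with pytest.raises(ValueError, match="A1.*outside 1..5"):
            read_responses(path, spec)

    def test_missing_item_column(self, tmp_path):
        spec = load_instrument(TWO_DOMAIN_CFG)
        path = tmp_path / "short.csv"
        path.write_text("A1,A2\n1,2\n")
        with pytest.raises(ValueError, match="B1"):
            read_responses(path, spec)


class TestFilterComplete:
    def test_constructed_toy(self):
        spec = load_instrument(TWO_DOMAIN_CFG)
        kept, report = filter_complete(small_matrix(), spec, require_group=True)
        # rows 2 and 3 miss an item; row 4 misses only the group label
        assert report == ExclusionReport(6, 2, 1, 3)
        assert kept.n_respondents == 3
        assert not np.isnan(kept.codes()).any()

    def test_both_missing_counted_once_under_item(self):
        spec = load_instrument(TWO_DOMAIN_CFG)
        data = pd.DataFrame(
            {"A1": pd.array([None, 1], dtype="Int64"),
             "A2": pd.array([1, 1], dtype="Int64"),
             "B1": pd.array([1, 1], dtype="Int64")}
        )
        group = pd.Series([None, "g1"], dtype="string")
        _, report = filter_complete(ResponseMatrix(data=data, group=group), spec)
        assert report.n_excluded_missing_item == 1
        assert report.n_excluded_missing_group == 0

    def test_identity_when_complete(self):
        spec = load_instrument(TWO_DOMAIN_CFG)
        m = small_matrix()
        complete = ResponseMatrix(
            data=m.data.iloc[[0, 1, 5]].copy(),
            group=m.group.iloc[[0, 1, 5]].copy(),
            metadata=m.metadata.iloc[[0, 1, 5]].copy(),
        )
        kept, report = filter_complete(complete, spec)
        assert report.n_analyzed == report.n_collected == 3
        assert report.n_excluded_missing_item == report.n_excluded_missing_group == 0
        pd.testing.assert_frame_equal(kept.data, complete.data)

    def test_idempotent(self):
        spec = load_instrument(TWO_DOMAIN_CFG)
        once, _ = filter_complete(small_matrix(), spec)
        twice, report2 = filter_complete(once, spec)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report2.n_excluded_missing_item == 0
        assert report2.n_excluded_missing_group == 0

    def test_require_group_without_groups_raises(self):
        spec = load_instrument(TWO_DOMAIN_CFG)
        m = ResponseMatrix(data=small_matrix().data)
        with pytest.raises(ValueError, match="group"):
            filter_complete(m, spec, require_group=True)
        kept, report = filter_complete(m, spec, require_group=False)
        assert report.n_excluded_missing_group == 0

    def test_report_must_balance(self):
        with pytest.raises(ValueError):
            ExclusionReport(10, 2, 2, 7)
        with pytest.raises(ValueError):
            ExclusionReport(10, -1, 0, 11)


class TestSummarizeSample:
    def test_counts_and_percentages(self):
        table = summarize_sample(small_matrix(), ["gender", "group"])
        g = table[table.field == "gender"].set_index("category")
        assert g.loc["f", "n"] == 4
        assert g.loc["f", "pct"] == pytest.approx(66.7)
        assert g.loc["Missing", "n"] == 1
        for fieldname in ("gender", "group"):
            sub = table[table.field == fieldname]
            # each pct is rounded to 1 dp, so the sum can be off by the
            # accumulated rounding of up to half a unit in the last place
            assert sub.pct.sum() == pytest.approx(100.0, abs=0.1 + 1e-9)
            assert sub.n.sum() == 6

    def test_single_category_is_100(self):
        data = pd.DataFrame({"A1": pd.array([1, 2], dtype="Int64")})
        meta = pd.DataFrame({"job": ["nurse", "nurse"]})
        table = summarize_sample(ResponseMatrix(data=data, metadata=meta), ["job"])
        assert table.pct.tolist() == [100.0]

    def test_unknown_field(self):
        with pytest.raises(KeyError):
            summarize_sample(small_matrix(), ["no_such_column"])
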