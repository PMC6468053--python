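"""Record parsing, per-season deduplication, and matrix construction."""

import datetime as dt
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indivnet import (
    DietRecord,
    IncidenceMatrix,
    Season,
    build_incidence,
    dedupe_one_per_season,
    read_diet_records,
)
from indivnet.diet import DietRecordError
from indivnet.incidence import IncidenceError


def write_tsv(tmp_path, body):
    path = tmp_path / "records.tsv"
    path.write_text(textwrap.dedent(body))
    return path


class TestReadRecords:
    def test_header_excluded_from_record_count(self, tmp_path):
        rows = ["individual\tsite\tseason\titem\tdate"]
        for k in range(7):
            rows.append(f"ind{k % 3}\tFAL\tcool_dry\titem{k}\t2009-06-0{k + 1}")
        path = write_tsv(tmp_path, "\n".join(rows))
        assert len(read_diet_records(path)) == 7

    def test_empty_file_is_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(DietRecordError, match="no records"):
            read_diet_records(path)

    def test_season_alias_mapping(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "individual\tsite\tseason\titem\na\tFAL\twet\tseeds\n",
        )
        (rec,) = read_diet_records(path, season_aliases={"wet": "warm_wet"})
        assert rec.season is Season.WARM_WET

    def test_unknown_season_is_fatal_with_line_number(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "individual\tsite\tseason\titem\na\tFAL\tmonsoon\tseeds\n",
        )
        with pytest.raises(DietRecordError, match="line 2.*monsoon"):
            read_diet_records(path)

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = write_tsv(tmp_path, "individual\tsite\titem\na\tFAL\tseeds\n")
        with pytest.raises(DietRecordError, match="season"):
            read_diet_records(path)


class TestDedupe:
    def rec(self, ind, season, item, day):
        return DietRecord(ind, "FAL", season, item, capture_date=dt.date(2009, 6, day))

    def test_earliest_date_wins_within_season(self):
        records = [
            self.rec("A", Season.WARM_WET, "x", 10),
            self.rec("A", Season.WARM_WET, "y", 10),
            self.rec("A", Season.WARM_WET, "z", 3),
        ]
        kept = dedupe_one_per_season(records)
        assert [r.item for r in kept] == ["z"]

    def test_one_sample_per_season_keeps_both_seasons(self):
        records = [self.rec("A", Season.WARM_WET, "x", 1), self.rec("A", Season.COOL_DRY, "y", 1)]
        assert len(dedupe_one_per_season(records)) == 2

    def test_missing_dates_fall_back_to_input_order(self):
        first = DietRecord("A", "FAL", Season.WARM_WET, "x")
        second = DietRecord("A", "FAL", Season.WARM_WET, "y")
        # undated records of one individual-season form one indistinct event
        assert {r.item for r in dedupe_one_per_season([first, second])} == {"x", "y"}
        # but a dated event always beats undated ones
        dated = self.rec("A", Season.WARM_WET, "z", 20)
        assert [r.item for r in dedupe_one_per_season([first, second, dated])] == ["z"]

    def test_union_rule_pools_all_events(self):
        records = [self.rec("A", Season.WARM_WET, "x", 1), self.rec("A", Season.WARM_WET, "y", 9)]
        assert {r.item for r in dedupe_one_per_season(records, rule="union")} == {"x", "y"}

    def test_idempotent(self, study_records):
        once = dedupe_one_per_season(study_records)
        assert dedupe_one_per_season(once) == once


class TestBuildIncidence:
    def test_direct_construction(self):
        records = [
            DietRecord("A", "s", Season.COOL_DRY, "x"),
            DietRecord("A", "s", Season.COOL_DRY, "y"),
            DietRecord("B", "s", Season.COOL_DRY, "y"),
        ]
        m = build_incidence(records, "s", Season.COOL_DRY)
        assert m.shape == (2, 2) and m.n_links == 3

    def test_minimal_one_by_one(self):
        m = build_incidence([DietRecord("A", "s", Season.COOL_DRY, "x")], "s", Season.COOL_DRY)
        assert m.shape == (1, 1) and m.values[0, 0] == 1

    def test_occurrence_not_count(self):
        records = [DietRecord("A", "s", Season.COOL_DRY, "x")] * 3
        m = build_incidence(records, "s", Season.COOL_DRY)
        assert m.n_links == 1

    def test_no_matching_records_names_site_and_season(self):
        records = [DietRecord("A", "s", Season.COOL_DRY, "x")]
        with pytest.raises(DietRecordError, match="elsewhere.*warm_wet|'elsewhere'"):
            build_incidence(records, "elsewhere", Season.WARM_WET)

    def test_no_empty_rows_or_columns_and_link_bound(self, study_records):
        deduped = dedupe_one_per_season(study_records)
        m = build_incidence(deduped, "FAL", Season.COOL_DRY)
        assert (m.values.sum(axis=1) > 0).all() and (m.values.sum(axis=0) > 0).all()
        pairs = {(r.individual_id, r.item) for r in deduped
                 if r.site == "FAL" and r.season is Season.COOL_DRY}
        assert m.n_links <= len(pairs)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = (rng.random((5, 4)) < 0.6).astype(np.int8)
        arr[arr.sum(1) == 0, 0] = 1
        m = IncidenceMatrix(tuple("abcde"), ("w", "x", "y", "z"), arr)
        m.to_csv(tmp_path / "m.csv")
        assert IncidenceMatrix.from_csv(tmp_path / "m.csv") == m

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_round_trip_property(self, data, tmp_path_factory):
        n_rows = data.draw(st.integers(1, 8))
        n_cols = data.draw(st.integers(1, 8))
        bits = data.draw(
            st.lists(st.integers(0, 1), min_size=n_rows * n_cols, max_size=n_rows * n_cols)
        )
        arr = np.array(bits, dtype=np.int8).reshape(n_rows, n_cols)
        m = IncidenceMatrix(
            tuple(f"i{k}" for k in range(n_rows)),
            tuple(f"c{k}" for k in range(n_cols)),
            arr,
        )
        path = tmp_path_factory.mktemp("rt") / "m.csv"
        m.to_csv(path)
        assert IncidenceMatrix.from_csv(path) == m

    def test_non_binary_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("individual,x,y\na,1,0\nb,2,1\n")
        with pytest.raises(IncidenceError, match="'b'.*'x'"):
            IncidenceMatrix.from_csv(path)

    def test_duplicated_column_label_is_fatal(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("individual,x,x\na,1,0\nb,0,1\n")
        with pytest.raises(IncidenceError, match="dup"):
            IncidenceMatrix.from_csv(path)
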