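import io
import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import effortseason as es
from effortseason import ingest
from effortseason.grids import GridSpec


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadVesselTable:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("vessel_id,gear_class,length_m\nV1,trawlers,35\n")
        df = ingest.read_vessel_table(p)
        assert df.loc[0, "vessel_id"] == "V1"
        assert df.loc[0, "gear_class"] == "trawlers"
        assert df.loc[0, "length_m"] == 35.0

    def test_unknown_gear_maps_to_other(self, caplog):
        df = ingest.read_vessel_table(pd.read_csv(_csv(
            "vessel_id,gear_class,length_m\nV1,dredge,20")))
        assert df.loc[0, "gear_class"] == "other"

    def test_missing_mandatory_column_errors(self):
        with pytest.raises(ValueError, match="vessel_id"):
            ingest.read_vessel_table(pd.read_csv(_csv(
                "id,gear_class,length_m\nV1,trawlers,20")))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ingest.read_vessel_table(
                pd.DataFrame(columns=["vessel_id", "gear_class", "length_m"]))


class TestReadFishingRecords:
    def test_retains_fishing_drops_nonfishing(self):
        df = ingest.read_fishing_records(pd.read_csv(_csv(
            "vessel_id,date,lat,lon,is_fishing\n"
            "V1,2015-03-02,10.2,-150.7,1\n"
            "V1,2015-03-02,10.2,-150.7,0")))
        assert len(df) == 1

    def test_lon_180_wraps(self):
        df = ingest.read_fishing_records(pd.read_csv(_csv(
            "vessel_id,date,lat,lon,is_fishing\nV1,2015-03-02,0.0,180.0,1")))
        assert df.loc[0, "lon"] == -180.0
        col, _ = GridSpec(1.0).cell_index(df.loc[0, "lon"], 0.0)
        assert col == 0

    def test_bad_records_counted_and_threshold(self):
        good = "V1,2015-01-01,0.0,0.0,1\n"
        bad = "V1,not-a-date,0.0,0.0,1\nV1,2015-01-01,95.0,0.0,1\n"
        df = ingest.read_fishing_records(pd.read_csv(_csv(
            "vessel_id,date,lat,lon,is_fishing\n" + good * 3 + bad)))
        assert df.attrs["n_rejected"] == 2
        with pytest.raises(ValueError, match="rejected"):
            ingest.read_fishing_records(pd.read_csv(_csv(
                "vessel_id,date,lat,lon,is_fishing\n" + good + bad)))


class TestContinuityFilter:
    def _records(self, spec):
        rows = [{"vessel_id": v, "date": pd.Timestamp(f"{y}-06-01"),
                 "lat": 0.5, "lon": 0.5} for v, ys in spec.items() for y in ys]
        return pd.DataFrame(rows)

    def test_keeps_only_vessels_active_every_year(self):
        recs = self._records({"A": [2015, 2016, 2017], "B": [2015, 2017]})
        kept, summary = ingest.filter_continuous_vessels(recs)
        assert set(kept["vessel_id"]) == {"A"}
        assert summary["n_vessels_dropped"] == 1

    def test_no_continuous_vessels_warns_not_errors(self, caplog):
        kept, summary = ingest.filter_continuous_vessels(
            self._records({"B": [2015]}))
        assert kept.empty
        assert summary["n_vessels_kept"] == 0


class TestPurseSplit:
    @pytest.mark.parametrize("length,dist,expected", [
        (45.0, 60.0, "purse_high_seas"),
        (30.0, 60.0, "purse_coastal"),
        (45.0, 20.0, "purse_coastal"),
        (np.nan, 60.0, "purse_coastal"),  # missing length -> conservative
    ])
    def test_length_and_distance_rule(self, length, dist, expected):
        vessels = pd.DataFrame({
            "vessel_id": ["P1"], "gear_class": ["purse_seines"],
            "length_m": [length], "mean_shore_distance_nm": [dist]})
        out = es.split_purse_seiners(vessels)
        assert out.loc[0, "gear_class"] == expected

    def test_other_gears_unchanged(self):
        vessels = pd.DataFrame({
            "vessel_id": ["T1"], "gear_class": ["trawlers"],
            "length_m": [50.0], "mean_shore_distance_nm": [100.0]})
        out = es.split_purse_seiners(vessels)
        assert out.loc[0, "gear_class"] == "trawlers"


def _mk_records(rows):
    return pd.DataFrame(
        [{"vessel_id": v, "date": pd.Timestamp(d), "lat": lat, "lon": lon,
          "gear_class": "trawlers"} for v, d, lat, lon in rows])


class TestRasterizeDaily:
    def test_vessel_counts_once_per_cell_day(self):
        recs = _mk_records([("V1", "2015-01-01", 10.2, 20.2)] * 5)
        daily = es.rasterize_daily(recs, GridSpec(1.0))
        assert daily["count"].tolist() == [1]

    def test_two_vessels_same_cell(self):
        recs = _mk_records([("V1", "2015-01-01", 10.2, 20.2),
                            ("V2", "2015-01-01", 10.3, 20.3)])
        daily = es.rasterize_daily(recs, GridSpec(1.0))
        assert daily["count"].tolist() == [2]

    def test_one_vessel_two_cells_counts_in_each(self):
        recs = _mk_records([("V1", "2015-01-01", 10.2, 20.2),
                            ("V1", "2015-01-01", 10.2, 21.2)])
        daily = es.rasterize_daily(recs, GridSpec(1.0))
        assert sorted(daily["count"]) == [1, 1]

    def test_matches_bruteforce_dedup_oracle(self):
        rng = np.random.default_rng(0)
        n = 400
        recs = pd.DataFrame({
            "vessel_id": rng.choice(["A", "B", "C"], n),
            "date": pd.to_datetime("2015-01-01")
            + pd.to_timedelta(rng.integers(0, 5, n), unit="D"),
            "lat": rng.uniform(0, 3, n),
            "lon": rng.uniform(0, 3, n),
            "gear_class": "trawlers",
        })
        daily = es.rasterize_daily(recs, GridSpec(1.0))
        # oracle: distinct (vessel, date, cell) triples, counted per cell
        triples = {(v, d.normalize(), int(lat), int(lon))
                   for v, d, lat, lon in zip(recs.vessel_id, recs.date,
                                             recs.lat, recs.lon)}
        assert daily["count"].sum() == len(triples)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        recs = _mk_records([("V1", "2015-01-02", 1.1, 2.2),
                            ("V2", "2015-01-03", 1.4, 2.6)])
        a = es.rasterize_daily(recs, GridSpec(1.0))
        b = es.rasterize_daily(recs, GridSpec(1.0))
        pd.testing.assert_frame_equal(a, b)


class TestMonthlyAggregate:
    def _daily(self, dates, count=1):
        return pd.DataFrame({"gear": "trawlers", "date": pd.to_datetime(dates),
                             "col": 200, "row": 100, "count": count})

    def test_january_division(self):
        days = pd.date_range("2015-01-01", "2015-01-31")
        eff = es.monthly_aggregate(self._daily(days, 2), GridSpec(1.0))
        assert eff.values.max() == pytest.approx(2.0)  # 62 vessel-days / 31

    def test_leap_february(self):
        days = pd.date_range("2016-02-01", "2016-02-29")
        eff = es.monthly_aggregate(self._daily(days, 2), GridSpec(1.0))
        assert eff.values.max() == pytest.approx(2.0)  # 58 / 29
        assert eff["days_in_month"].values[0] == 29

    def test_partial_trailing_month_excluded(self, caplog):
        days = pd.date_range("2015-01-01", "2015-02-10")
        eff = es.monthly_aggregate(self._daily(days), GridSpec(1.0))
        assert eff.sizes["month"] == 1

    def test_conservation(self, poisson_data, poisson_effort):
        grid = GridSpec(1.0)
        recs = poisson_data.records.copy()
        col, row = grid.cell_index(recs["lon"].to_numpy(),
                                   recs["lat"].to_numpy())
        n = len(recs.assign(c=col, r=row, d=recs["date"].dt.normalize())
                .drop_duplicates(["vessel_id", "d", "c", "r"]))
        assert es.total_vessel_days(poisson_effort) == pytest.approx(n, abs=1e-6)

    def test_coarser_resolution_has_fewer_or_equal_vessel_days(self, poisson_data):
        # merging cells can only merge duplicates, never create them
        totals = {}
        for res in (0.5, 1.0, 4.0):
            grid = GridSpec(res)
            daily = es.rasterize_daily(
                poisson_data.records.assign(gear_class="all"), grid)
            totals[res] = es.total_vessel_days(
                es.monthly_aggregate(daily, grid))
        assert totals[0.5] >= totals[1.0] >= totals[4.0]


class TestMask:
    def _effort(self):
        from conftest import make_effort
        vals = np.arange(2 * 2 * 3 * 3, dtype=float).reshape(2, 2, 3, 3) + 1
        return make_effort(vals, gears=("trawlers", "other"),
                           lat=np.array([10.5, 11.5, 12.5]),
                           lon=np.array([20.5, 21.5, 22.5]))

    def test_partition_sums_to_original(self):
        eff = self._effort()
        mask = ingest.CellMask.from_polygon(GridSpec(1.0), box(20, 10, 22, 12))
        removed = es.apply_mask(eff, mask, "remove")
        kept = es.apply_mask(eff, mask, "keep")
        assert np.allclose(removed.values + kept.values, eff.values)

    def test_polygon_membership_by_cell_center(self):
        mask = ingest.CellMask.from_polygon(GridSpec(1.0), box(20, 10, 22, 12))
        assert mask.cells == {(200, 100), (200, 101), (201, 100), (201, 101)}

    def test_grid_mismatch_errors(self):
        eff = self._effort()
        mask = ingest.CellMask.from_polygon(GridSpec(4.0), box(20, 8, 24, 12))
        with pytest.raises(ValueError, match="resolution"):
            es.apply_mask(eff, mask, "remove")

    def test_bad_mode_errors(self):
        eff = self._effort()
        mask = ingest.CellMask(GridSpec(1.0), frozenset())
        with pytest.raises(ValueError, match="mode"):
            es.apply_mask(eff, mask, "drop")

    def test_geojson_round_trip(self, tmp_path):
        sc = es.Scenario()
        mask, gj = es.generate_eez_mask(sc)
        import json
        p = tmp_path / "m.geojson"
        p.write_text(json.dumps(gj))
        back = ingest.CellMask.from_geojson(p, GridSpec(1.0))
        assert back.cells == mask.cells


class TestRoundTrips:
    def test_netcdf(self, tmp_path, poisson_effort):
        p = tmp_path / "eff.nc"
        ingest.effort_to_netcdf(poisson_effort, p)
        back = ingest.effort_from_netcdf(p)
        back = back.sel(gear=poisson_effort["gear"].values)
        assert np.allclose(back.values, poisson_effort.values)

    def test_csv_totals(self, tmp_path, poisson_effort):
        p = tmp_path / "eff.csv"
        ingest.effort_to_csv(poisson_effort, p)
        df = pd.read_csv(p)
        assert df["effort_per_day"].sum() == pytest.approx(
            float(poisson_effort.sum()), rel=1e-9)
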