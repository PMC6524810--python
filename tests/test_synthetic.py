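import json

import numpy as np
import pandas as pd
import pytest

import effortseason as es
from effortseason import ingest
from effortseason.synthetic import (
    ScenarioFields,
    _deterministic_counts,
    generate_distance_fields,
)
from conftest import small_scenario


class TestScenarioValidation:
    def test_shares_must_sum_to_100(self):
        with pytest.raises(ValueError, match="shares"):
            es.Scenario(gears=[es.GearSpec("trawlers", 60.0),
                               es.GearSpec("other", 30.0)])

    def test_amplitude_bounds(self):
        with pytest.raises(ValueError, match="amplitude"):
            es.GearSpec("trawlers", 100.0, amplitude=1.5)

    def test_yaml_round_trip(self, tmp_path):
        sc = small_scenario(seed=9)
        p = tmp_path / "scenario.yaml"
        sc.to_yaml(p)
        back = es.Scenario.from_yaml(p)
        assert back.to_dict() == sc.to_dict()


class TestDeterminism:
    def test_identical_seed_identical_records(self):
        a = es.generate_parametric(small_scenario(seed=5))
        b = es.generate_parametric(small_scenario(seed=5))
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.vessels, b.vessels)

    def test_different_seed_different_records(self):
        a = es.generate_parametric(small_scenario(seed=5))
        b = es.generate_parametric(small_scenario(seed=6))
        assert not a.records.equals(b.records)


class TestConstructionIdentities:
    def test_zero_amplitude_no_modulation_constant_series(self):
        sc = small_scenario(noise="none", moratorium=None, holidays={},
                            gears=[es.GearSpec("trawlers", 100.0, "basin",
                                               amplitude=0.0, n_vessels=100)])
        f = ScenarioFields(sc)
        s = f.expected_monthly_series(sc.gears[0])
        assert np.allclose(s.values, s.values[0])

    def test_holiday_deficit_exact_on_expectation(self):
        # December at deficit h: monthly mean = baseline * (1 - h/31)
        sc = small_scenario(noise="none", moratorium=None,
                            holidays={12: 4.0},
                            gears=[es.GearSpec("trawlers", 100.0, "basin",
                                               amplitude=0.0, n_vessels=100)])
        f = ScenarioFields(sc)
        s = f.expected_monthly_series(sc.gears[0])
        dec = s[[p.month == 12 for p in s.index]].mean()
        base = s[[p.month in range(3, 12) for p in s.index]].mean()
        assert dec == pytest.approx(base * (1 - 4.0 / 31.0), rel=1e-12)

    def test_moratorium_window_suppresses_member_cells_only(self):
        sc = small_scenario(noise="none")
        f = ScenarioFields(sc)
        lam = f.daily_intensity(sc.gears[0])
        member = f.member.reshape(-1)
        july = np.asarray(f.dates.strftime("%Y-%m") == "2015-07")
        january = np.asarray(f.dates.strftime("%Y-%m") == "2015-01")
        inside_ratio = lam[july][:, member].sum() / lam[january][:, member].sum()
        outside_ratio = (lam[july][:, ~member].sum()
                         / lam[january][:, ~member].sum())
        assert inside_ratio < 0.15          # suppressed by factor 0.1
        assert 0.8 < outside_ratio < 1.3    # unaffected outside

    def test_deterministic_counts_match_monthly_expectation(self):
        sc = small_scenario(noise="none")
        f = ScenarioFields(sc)
        lam = f.daily_intensity(sc.gears[0])
        counts = _deterministic_counts(lam, f.dates)
        per = f.dates.to_period("M")
        for m in per.unique()[:6]:
            sel = np.asarray(per == m)
            assert abs(counts[sel].sum() - lam[sel].sum()) < 1.0

    def test_poisson_expectation_fidelity(self):
        # realized monthly totals match the expectation within 4 sigma
        sc = small_scenario(noise="poisson", seed=2)
        data = es.generate_parametric(sc)
        truth = data.truth["gears"]["trawlers"]
        expected = truth["expected_vessel_days"]
        realized = truth["realized_vessel_days"]
        assert abs(realized - expected) < 4 * np.sqrt(expected)


class TestVesselAssignment:
    def test_continuity_guaranteed_for_pool_vessels(self):
        data = es.generate_parametric(small_scenario(seed=3))
        kept, summary = es.filter_continuous_vessels(data.records)
        assert summary["n_vessels_dropped"] == 0

    def test_dropout_vessels_removed_by_filter(self):
        gears = [es.GearSpec("trawlers", 100.0, "basin", amplitude=0.2,
                             n_vessels=60, n_dropout_vessels=5)]
        sc = small_scenario(gears=gears, moratorium=None, seed=4)
        data = es.generate_parametric(sc)
        kept, summary = es.filter_continuous_vessels(data.records)
        dropped = set(data.records["vessel_id"]) - set(kept["vessel_id"])
        expected = set(data.truth["gears"]["trawlers"]["dropout_vessels"])
        assert dropped == expected & set(data.records["vessel_id"])

    def test_no_duplicate_vessel_in_cell_day(self):
        data = es.generate_parametric(small_scenario(seed=7))
        recs = data.records
        grid = es.GridSpec(1.0)
        col, row = grid.cell_index(recs["lon"].to_numpy(),
                                   recs["lat"].to_numpy())
        key = recs.assign(c=col, r=row)
        dups = key.duplicated(["vessel_id", "date", "c", "r"]).sum()
        assert dups == 0

    def test_infeasible_pool_errors(self):
        gears = [es.GearSpec("trawlers", 100.0, "coastal", 50.0,
                             amplitude=0.0, n_vessels=2)]
        sc = small_scenario(gears=gears, mean_total_effort=500.0,
                            moratorium=None, seed=0)
        with pytest.raises(ValueError, match="pool"):
            es.generate_parametric(sc)


class TestDistanceFields:
    def test_port_node_zero(self):
        sc = es.Scenario(lon_min=100, lon_max=112, lat_min=0, lat_max=12,
                         ports=[(106.0, 6.0)])
        port, _ = generate_distance_fields(sc)
        assert float(port.sel(lon=106.0, lat=6.0, method="nearest")) < 1.0

    def test_two_ports_pointwise_minimum(self):
        kw = dict(lon_min=100, lon_max=112, lat_min=0, lat_max=12)
        both, _ = generate_distance_fields(es.Scenario(
            ports=[(102.0, 2.0), (110.0, 10.0)], **kw))
        a, _ = generate_distance_fields(es.Scenario(ports=[(102.0, 2.0)], **kw))
        b, _ = generate_distance_fields(es.Scenario(ports=[(110.0, 10.0)], **kw))
        assert np.allclose(both.values,
                           np.fmin(a.values, b.values), equal_nan=True)

    def test_land_nodes_invalid(self):
        sc = es.Scenario(lon_min=100, lon_max=112, lat_min=0, lat_max=12)
        port, shore = generate_distance_fields(sc)
        west = port.sel(lon=slice(None, 99.9))
        assert np.isnan(west.values).all()
        # shore distance grows eastward from the coastline
        row = shore.sel(lat=6.0, method="nearest").sel(lon=slice(100, 112))
        assert (np.diff(row.values[np.isfinite(row.values)]) > 0).all()

    def test_no_ports_errors(self):
        sc = es.Scenario(lon_min=100, lon_max=112, lat_min=0, lat_max=12,
                         ports=[])
        with pytest.raises(ValueError, match="port"):
            generate_distance_fields(sc)


class TestEezMask:
    def test_rectangle_covers_expected_cells(self):
        sc = small_scenario()
        mask, gj = es.generate_eez_mask(sc)
        # region 100-112E x 12-24N at 1 deg: 12 x 12 cells
        assert len(mask.cells) == 144
        assert gj["geometry"]["type"] == "Polygon"

    def test_degenerate_polygon_errors(self):
        m = es.Moratorium(region=[(0, 0), (0, 0), (0, 0)], windows=[])
        sc = small_scenario()
        sc.moratorium = m
        with pytest.raises(ValueError, match="degenerate"):
            es.generate_eez_mask(sc)


class TestBioeconomic:
    def test_zero_growth_constant_effort(self):
        # p q B = c and R = 0: effort never moves
        p = es.BioeconomicParams(kappa_e=1e-4, price=2.0, cost=1000.0,
                                 q=0.01, B=50000.0, R=0.0, E0=3.0)
        traj = es.simulate_effort(p, n_days=30, dt=1.0)
        assert np.allclose(traj, 3.0)

    def test_exponential_growth_matches_closed_form(self):
        # kappa_e (p q B - c) = r = 0.05 / day, R = 0
        p = es.BioeconomicParams(kappa_e=1e-4, price=2.0, cost=500.0,
                                 q=0.01, B=50000.0, R=0.0, E0=1.0)
        for dt in (0.1, 0.05):
            traj = es.simulate_effort(p, n_days=20, dt=dt)
            err = abs(traj[-1, 0] - np.exp(0.05 * 20))
            assert err < 2.0 * 0.05 * 20 * np.exp(1.0) * dt  # O(dt)
        e1 = abs(es.simulate_effort(p, 20, 0.1)[-1, 0] - np.exp(1.0))
        e2 = abs(es.simulate_effort(p, 20, 0.05)[-1, 0] - np.exp(1.0))
        assert e1 / e2 == pytest.approx(2.0, rel=0.1)

    def test_linear_decline_clips_at_zero(self):
        p = es.BioeconomicParams(kappa_e=1e-4, price=2.0, cost=1000.0,
                                 q=0.01, B=50000.0, R=0.1, E0=1.0)
        traj = es.simulate_effort(p, n_days=15, dt=1.0)[:, 0]
        assert traj[5] == pytest.approx(0.5, abs=1e-12)
        assert traj[10] == pytest.approx(0.0, abs=1e-12)
        # once at (numerical) zero with no profit, effort stays there
        assert (traj[11:] == 0.0).all()

    def test_nonfinite_parameters_error(self):
        p = es.BioeconomicParams(E0=np.nan)
        with pytest.raises(ValueError):
            es.simulate_effort(p, n_days=5)

    def test_closure_window_suppresses_effort(self):
        # strong regulatory removal during a closure window drives
        # in-region effort below 10% of its pre-closure mean
        def removal(t):
            return 2.0 if 100 <= t < 200 else 0.0

        p = es.BioeconomicParams(kappa_e=1e-4, price=2.0, cost=1000.0,
                                 q=0.01, B=50000.0, R=removal, E0=5.0)
        traj = es.simulate_effort(p, n_days=300, dt=1.0)[:, 0]
        pre = traj[:100].mean()
        during = traj[110:200].mean()
        assert during < 0.1 * pre

    def test_record_emission(self):
        sc = es.Scenario(lon_min=100, lon_max=106, lat_min=0, lat_max=6,
                         gears=[es.GearSpec("trawlers", 100.0, "basin",
                                            n_vessels=200)],
                         moratorium=None, seed=8)
        p = es.BioeconomicParams(kappa_e=1e-4, price=2.0, cost=1000.0,
                                 q=0.01, B=50000.0, R=0.0, E0=5e-4)
        records, truth = es.generate_bioeconomic(p, sc, n_days=60)
        assert len(records) > 0
        assert set(records.columns) >= {"vessel_id", "date", "lat", "lon"}
        assert truth["n_records"] == len(records)


class TestFileRoundTrip:
    def test_written_files_feed_the_readers(self, tmp_path):
        data = es.generate_parametric(small_scenario(seed=1,
                                                     mean_total_effort=50.0))
        paths = data.write(tmp_path)
        records = ingest.read_fishing_records(paths["records"])
        vessels = ingest.read_vessel_table(paths["vessels"])
        assert len(records) == len(data.records)
        assert set(vessels["vessel_id"]) == set(data.vessels["vessel_id"])
        with open(paths["truth"]) as fh:
            truth = json.load(fh)
        assert truth["n_records"] == len(records)
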