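import numpy as np
import pandas as pd
import pytest
import shapely

from windrift import context_annotation as ca
from windrift import synthetic_data as sd
from windrift.context_annotation import Biome, BiomeMap


def ndvi_map():
    """NDVI raster over lon/lat [0, 10] with one land and one forest polygon,
    plus a small island below the sea-crossing size threshold."""
    lons = np.linspace(0, 10, 21)
    lats = np.linspace(0, 10, 21)
    ndvi = np.tile(np.linspace(0.0, 0.5, 21), (21, 1))  # increases eastward
    land = shapely.Polygon([(0, 0), (8, 0), (8, 10), (0, 10)])
    island = shapely.Polygon([(9, 9), (9.2, 9), (9.2, 9.2), (9, 9.2)])  # tiny
    forest = shapely.Polygon([(1, 6), (4, 6), (4, 9), (1, 9)])
    return BiomeMap(lons=lons, lats=lats, ndvi=ndvi, land=[land, island], forest=[forest])


class TestAnnotateFixBiome:
    def test_ocean_point_is_sea(self):
        m = ndvi_map()
        assert m.lookup(9.5, 2.0)[0] == Biome.SEA.value

    def test_small_island_counts_as_sea(self):
        m = ndvi_map()
        assert m.lookup(9.1, 9.1)[0] == Biome.SEA.value

    @pytest.mark.parametrize("ndvi_val,expected", [(0.24, "desert"), (0.26, "other")])
    def test_ndvi_threshold(self, ndvi_val, expected):
        lons = lats = np.linspace(0, 10, 11)
        land = shapely.Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        m = BiomeMap(lons=lons, lats=lats, ndvi=np.full((11, 11), ndvi_val), land=[land])
        assert m.lookup(2.0, 2.0)[0] == expected

    def test_forest_polygon_overrides_ndvi(self):
        m = ndvi_map()
        # inside forest polygon but with NDVI < 0.25 at that longitude
        assert m.lookup(2.0, 7.0)[0] == Biome.HUMID_FOREST.value

    def test_outside_extent_rejected(self):
        m = ndvi_map()
        with pytest.raises(ValueError, match="extent"):
            m.lookup(50.0, 2.0)

    def test_category_raster_lookup(self):
        bm = sd.make_biome_bands()
        assert bm.lookup(0.0, 20.0)[0] == Biome.DESERT.value
        assert bm.lookup(0.0, 0.0)[0] == Biome.HUMID_FOREST.value
        assert bm.lookup(45.0, -20.0)[0] == Biome.SEA.value

    def test_every_fix_gets_exactly_one_category(self):
        m = ndvi_map()
        rng = np.random.default_rng(5)
        cats = m.lookup(rng.uniform(0, 10, 500), rng.uniform(0, 10, 500))
        assert set(cats) <= {b.value for b in Biome}


class TestModalDailyBiome:
    def test_majority(self):
        assert ca.modal_daily_biome(["desert"] * 10 + ["other"] * 2) == "desert"

    def test_tie_broken_by_priority(self):
        assert ca.modal_daily_biome(["desert"] * 6 + ["other"] * 6) == "desert"
        assert ca.modal_daily_biome(["sea"] * 3 + ["humid_forest"] * 3) == "sea"

    def test_single_fix(self):
        assert ca.modal_daily_biome(["sea"]) == "sea"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ca.modal_daily_biome([])


class TestLongestDesertRun:
    def mk(self, pattern, dlat=1.0):
        t0 = pd.Timestamp("2019-10-20 06:00")
        return pd.DataFrame(
            {
                "bird_id": "B1",
                "t": [t0 + pd.Timedelta(hours=h) for h in range(len(pattern))],
                "lon": 0.0,
                "lat": np.arange(len(pattern)) * dlat,
                "biome": ["desert" if c == "D" else "other" for c in pattern],
            }
        )

    def test_longest_run_selected(self):
        best = ca.longest_desert_run(self.mk("ODDDODD"))
        assert best["start_index"] == 1 and best["end_index"] == 3
        assert best["length_km"] == pytest.approx(2 * 111.195, rel=1e-3)

    def test_all_desert_covers_whole_trip(self):
        best = ca.longest_desert_run(self.mk("DDDD"))
        assert best["start_index"] == 0 and best["end_index"] == 3

    def test_no_desert_returns_none(self):
        assert ca.longest_desert_run(self.mk("OOO")) is None

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pattern = "".join(rng.choice(list("DO"), 60))
        fx = self.mk(pattern)
        best = ca.longest_desert_run(fx)
        # brute force over all contiguous desert runs, same distance metric
        from windrift.geodesy import gc_distance_deg

        runs = []
        i = 0
        while i < len(pattern):
            if pattern[i] == "D":
                j = i
                while j + 1 < len(pattern) and pattern[j + 1] == "D":
                    j += 1
                km = float(
                    gc_distance_deg(
                        fx["lon"].to_numpy()[i:j], fx["lat"].to_numpy()[i:j],
                        fx["lon"].to_numpy()[i + 1 : j + 1], fx["lat"].to_numpy()[i + 1 : j + 1],
                    ).sum()
                )
                runs.append((i, j, km))
                i = j + 1
            else:
                i += 1
        exp = max(runs, key=lambda r: r[2])
        assert (best["start_index"], best["end_index"]) == (exp[0], exp[1])
        assert best["length_km"] == pytest.approx(exp[2])

    def test_tie_goes_to_earliest(self):
        best = ca.longest_desert_run(self.mk("DDODD"))
        assert best["start_index"] == 0


class TestDekads:
    def test_calendar_convention(self):
        d = ca.dekad_of(pd.to_datetime(["2019-01-01", "2019-01-10", "2019-01-11",
                                        "2019-01-21", "2019-01-31", "2019-02-01",
                                        "2019-12-31"]))
        assert list(d) == [1, 1, 2, 3, 3, 4, 36]


def qualifying_inputs(season="autumn", bearing_deg=90.0, lat=10.0):
    """One travel day moving at the given bearing inside the Sahel box."""
    t0 = pd.Timestamp("2019-10-22 06:00")
    from windrift.geodesy import destination_deg

    lons, lats = [0.0], [lat]
    for _ in range(8):
        lo, la = destination_deg(lons[-1], lats[-1], bearing_deg, 50.0)
        lons.append(float(lo))
        lats.append(float(la))
    fixes = pd.DataFrame(
        {
            "bird_id": "B1",
            "t": [t0 + pd.Timedelta(hours=h) for h in range(len(lons))],
            "lon": lons,
            "lat": lats,
        }
    )
    days = pd.DataFrame(
        {"bird_id": ["B1"], "date": [t0.normalize()], "day_class": ["travel"]}
    )
    return days, fixes


class TestSahelFilter:
    def test_autumn_eastward_day_kept(self):
        days, fixes = qualifying_inputs(bearing_deg=90.0)
        out = ca.filter_sahel_days(days, fixes, "autumn")
        assert len(out) == 1

    def test_autumn_off_sector_dropped(self):
        days, fixes = qualifying_inputs(bearing_deg=60.0)
        assert ca.filter_sahel_days(days, fixes, "autumn").empty

    def test_spring_westward_day_kept_via_signed_bearing(self):
        days, fixes = qualifying_inputs(bearing_deg=270.0)
        out = ca.filter_sahel_days(days, fixes, "spring")
        assert len(out) == 1

    def test_day_outside_box_dropped(self):
        days, fixes = qualifying_inputs(lat=30.0)
        assert ca.filter_sahel_days(days, fixes, "autumn").empty

    def test_stopover_day_dropped(self):
        days, fixes = qualifying_inputs()
        days["day_class"] = "stopover"
        assert ca.filter_sahel_days(days, fixes, "autumn").empty


class TestMatchItf:
    def itf_table(self):
        rows = []
        for dk in range(28, 32):
            for b in ca.ITF_LON_BINS:
                rows.append({"year": 2019, "dekad": dk, "lon_bin": int(b), "lat_itf": 12.0})
        return pd.DataFrame(rows)

    def test_one_day_one_bin(self):
        days, fixes = qualifying_inputs()
        q = ca.filter_sahel_days(days, fixes, "autumn")
        blocks, dropped = ca.match_itf(q, fixes, self.itf_table())
        assert dropped == 0
        assert len(blocks) >= 1
        b0 = blocks.iloc[0]
        in_bin = fixes[(fixes["lon"] - b0["lon_bin"]).abs() <= 2.5]
        assert b0["mean_lat_bird"] == pytest.approx(in_bin["lat"].mean())

    def test_same_block_days_averaged_together(self):
        days1, fixes1 = qualifying_inputs()
        days2, fixes2 = qualifying_inputs()
        fixes2["t"] += pd.Timedelta(days=1)
        days2["date"] += pd.Timedelta(days=1)
        days = pd.concat([days1, days2], ignore_index=True)
        fixes = pd.concat([fixes1, fixes2], ignore_index=True)
        q = ca.filter_sahel_days(days, fixes, "autumn")
        blocks, _ = ca.match_itf(q, fixes, self.itf_table())
        # both days are in the same dekad: group-by collapses them
        assert blocks.groupby(["bird_id", "year", "dekad", "lon_bin"]).size().max() == 1

    def test_missing_itf_record_dropped_and_counted(self):
        days, fixes = qualifying_inputs()
        q = ca.filter_sahel_days(days, fixes, "autumn")
        blocks_all, _ = ca.match_itf(q, fixes, self.itf_table())
        empty_itf = self.itf_table().iloc[:0]
        blocks, dropped = ca.match_itf(q, fixes, empty_itf)
        assert blocks.empty and dropped == len(blocks_all)

    def test_block_count_invariant_to_day_order(self):
        days1, fixes1 = qualifying_inputs()
        days2, fixes2 = qualifying_inputs(bearing_deg=80.0)
        fixes2["t"] += pd.Timedelta(days=12)
        days2["date"] += pd.Timedelta(days=12)
        days = pd.concat([days2, days1], ignore_index=True)
        fixes = pd.concat([fixes2, fixes1], ignore_index=True).sort_values("t")
        q = ca.filter_sahel_days(days, fixes, "autumn")
        b1, _ = ca.match_itf(q, fixes, self.itf_table())
        q2 = q.iloc[::-1]
        b2, _ = ca.match_itf(q2, fixes, self.itf_table())
        assert len(b1) == len(b2)


class TestItfSlopeRecovery:
    def test_tracks_hugging_itf_recover_unit_slope(self):
        """Birds generated to follow the ITF line with 0.5-degree latitude
        noise: regressing block latitude on ITF latitude gives slope ~1."""
        # ITF line kept inside the 5-15 N Sahel box so the box filter does
        # not truncate the latitude distribution
        scen = sd.WindScenario(itf_lat0=9.0, itf_amp=2.0)
        itf = sd.make_itf_table(scen, years=[2019], noise_sd=0.0)
        rng = np.random.default_rng(21)
        rows_f, rows_d = [], []
        for b in range(10):
            t = pd.Timestamp("2019-10-01 06:00") + pd.Timedelta(days=int(rng.integers(0, 9)))
            lon = -10.0
            while lon < 35.0:
                date = t.normalize()
                lat_day = float(
                    np.atleast_1d(scen.itf_lat(lon, np.datetime64(t)))[0]
                ) + rng.normal(0, 0.5)
                for h in range(9):
                    rows_f.append(
                        {"bird_id": f"B{b}", "t": t + pd.Timedelta(hours=h),
                         "lon": lon + h * 0.4, "lat": lat_day}
                    )
                rows_d.append({"bird_id": f"B{b}", "date": date, "day_class": "travel"})
                lon += 3.5
                t += pd.Timedelta(days=1)
        fixes = pd.DataFrame(rows_f)
        days = pd.DataFrame(rows_d)
        q = ca.filter_sahel_days(days, fixes, "autumn")
        blocks, _ = ca.match_itf(q, fixes, itf)
        assert len(blocks) >= 100
        slope = np.polyfit(blocks["lat_itf"], blocks["mean_lat_bird"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
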