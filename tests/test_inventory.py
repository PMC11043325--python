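"""Inventory loading, cleaning rules, area approximation, spatial join."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from resfish.inventory import (SchemaError, approximate_missing_area,
                               assign_ecoregion, clean_inventory,
                               load_ecoregions, load_inventory,
                               normalize_name)
from resfish.simulate import ecoregion_polygons, write_ecoregions_geojson
from resfish.config import SimulationConfig


def _write(tmp_path, text, name="inv.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = ("reservoir_id,name,state,latitude,longitude,year_completed,"
          "storage_volume_m3,max_discharge_m3s,surface_area_ha,natural_lake\n")


class TestLoad:
    def test_well_formed(self, tmp_path):
        p = _write(tmp_path, HEADER
                   + "R1,Alpha,TX,31,-99,1950,1e6,10,50,False\n"
                   + "R2,Beta,OK,35,-97,1960,2e6,20,80,False\n"
                   + "R3,Gamma,AR,34,-92,1970,3e6,30,90,False\n")
        df, warn = load_inventory(p)
        assert len(df) == 3 and warn == {}

    def test_unparseable_numeric_coerced_with_warning(self, tmp_path):
        p = _write(tmp_path, HEADER + "R1,Alpha,TX,31,-99,1950,n/a,10,50,False\n")
        df, warn = load_inventory(p)
        assert np.isnan(df.loc[0, "storage_volume_m3"])
        assert warn == {"storage_volume_m3": 1}

    def test_round_trip(self, tmp_path):
        from resfish.simulate import simulate_inventory
        inv = simulate_inventory(SimulationConfig(seed=1, n_reservoirs=40))
        pub = inv[[c for c in inv.columns if not c.startswith("_")]]
        p = tmp_path / "roundtrip.csv"
        pub.to_csv(p, index=False)
        back, _ = load_inventory(p)
        pd.testing.assert_frame_equal(
            back[pub.columns].reset_index(drop=True), pub.reset_index(drop=True),
            check_dtype=False)

    def test_missing_file_and_missing_id(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_inventory(tmp_path / "nope.csv")
        p = _write(tmp_path, "name,state\nX,TX\n")
        with pytest.raises(SchemaError):
            load_inventory(p)


def _toy_six_rows():
    return pd.DataFrame({
        "reservoir_id": ["R1", "R2", "R3", "R4", "R5", "R6"],
        "name": ["Alpha Lake", "ALPHA  LAKE", "Beta", "Lake Superior",
                 "Delta", "Echo"],
        "state": ["TX", "TX", "OK", "MI", "AR", "MO"],
        "latitude": [31.0] * 6, "longitude": [-99.0] * 6,
        "year_completed": [1950] * 6,
        "storage_volume_m3": [1e6, 5e5, 2e6, 1e12, 3e6, 4e6],
        "max_discharge_m3s": [10.0] * 6,
        "surface_area_ha": [50.0, 50.0, 80.0, 8e6, 90.0, 20.0],
        "natural_lake": [False, False, False, False, False, False],
    })


class TestClean:
    def test_toy_dedup_and_natural_lake(self):
        cleaned, report = clean_inventory(_toy_six_rows())
        assert len(cleaned) == 4
        assert report["duplicates"] == 1
        assert report["natural_lakes"] == 1
        # the surviving Alpha record is the max-volume dam
        alpha = cleaned[cleaned["name"].str.contains("lpha", case=False)]
        assert len(alpha) == 1
        assert alpha["storage_volume_m3"].iloc[0] == 1e6

    def test_empty_input(self):
        cleaned, report = clean_inventory(_toy_six_rows().iloc[:0])
        assert len(cleaned) == 0
        assert report["rows_out"] == 0
        assert report["duplicates"] == report["natural_lakes"] == 0

    def test_idempotent(self):
        once, _ = clean_inventory(_toy_six_rows())
        twice, rep = clean_inventory(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep["duplicates"] == rep["natural_lakes"] == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_count_identity(self, seed):
        """|output| + removals = |input| on randomized tables."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        df = pd.DataFrame({
            "reservoir_id": [f"R{i}" for i in range(n)],
            "name": rng.choice(["Alpha", "Beta", "Gamma", "Lake Superior"], n),
            "state": rng.choice(["TX", "OK"], n),
            "latitude": 31.0, "longitude": -99.0, "year_completed": 1950,
            "storage_volume_m3": np.where(rng.random(n) < 0.2, np.nan,
                                          rng.uniform(1e5, 1e7, n)),
            "max_discharge_m3s": 10.0,
            "surface_area_ha": np.where(rng.random(n) < 0.3, np.nan,
                                        rng.uniform(10, 100, n)),
            "natural_lake": rng.random(n) < 0.1,
        })
        cleaned, rep = clean_inventory(df)
        assert len(cleaned) + rep["duplicates"] + rep["natural_lakes"] \
            + rep["no_area_basis"] == len(df)
        assert cleaned["surface_area_ha"].notna().sum() \
            + cleaned["storage_volume_m3"].notna().sum() >= len(cleaned)


class TestAreaApproximation:
    def _frame(self, volumes, areas):
        return pd.DataFrame({"reservoir_id": [f"R{i}" for i in range(len(volumes))],
                             "storage_volume_m3": volumes,
                             "surface_area_ha": areas})

    def test_no_missing_is_identity(self):
        df = self._frame([1e5, 2e5], [10.0, 20.0])
        out, info = approximate_missing_area(df)
        assert info["n_approximated"] == 0
        pd.testing.assert_series_equal(out["surface_area_ha"],
                                       df["surface_area_ha"])

    def test_noiseless_power_law_recovered(self):
        v = np.geomspace(1e4, 1e8, 12)
        a = 0.1 * v**0.8
        df = self._frame(list(v) + [1e6], list(a) + [np.nan])
        out, info = approximate_missing_area(df)
        assert info["method"] == "loglog_ols"
        assert out["surface_area_ha"].iloc[-1] \
            == pytest.approx(0.1 * 10**4.8, rel=1e-6)
        assert out["area_approximated"].iloc[-1]
        # observed areas untouched
        assert np.allclose(out["surface_area_ha"].iloc[:-1], a)

    def test_median_ratio_fallback_under_ten_pairs(self):
        df = self._frame([1e5, 2e5, 4e5, 1e6], [10.0, 30.0, 40.0, np.nan])
        out, info = approximate_missing_area(df)
        assert info["method"] == "median_ratio"
        ratio = np.median([10 / 1e5, 30 / 2e5, 40 / 4e5])
        assert out["surface_area_ha"].iloc[-1] == pytest.approx(ratio * 1e6)

    def test_no_complete_pairs_raises(self):
        df = self._frame([1e5, np.nan], [np.nan, 10.0])
        with pytest.raises(ValueError):
            approximate_missing_area(df)


def _ray_casting(lon, lat, ring):
    """Independent even-odd point-in-polygon oracle."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > lat) != (y2 > lat):
            x_cross = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
            if lon < x_cross:
                inside = not inside
    return inside


class TestEcoregionJoin:
    UNIT = [("E1", Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))]

    def _records(self, lons, lats):
        return pd.DataFrame({"reservoir_id": [f"R{i}" for i in range(len(lons))],
                             "longitude": lons, "latitude": lats})

    def test_point_inside_unit_square(self):
        out, rep = assign_ecoregion(self._records([0.5], [0.5]), self.UNIT)
        assert out["ecoregion_l2"].iloc[0] == "E1"
        assert rep["outside_all_polygons"] == 0

    def test_point_outside_all(self):
        out, rep = assign_ecoregion(self._records([2.0], [2.0]), self.UNIT)
        assert pd.isna(out["ecoregion_l2"].iloc[0])
        assert rep["outside_all_polygons"] == 1

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            assign_ecoregion(self._records([0.5], [0.5]), [])

    def test_agrees_with_ray_casting_oracle(self):
        tiles = {"A": [(0, 0), (1, 0), (1, 1), (0, 1)],
                 "B": [(1, 0), (2, 0), (2, 1), (1, 1)],
                 "C": [(0, 1), (1, 1), (1, 2), (0, 2)],
                 "D": [(1, 1), (2, 1), (2, 2), (1, 2)]}
        layer = [(k, Polygon(r)) for k, r in tiles.items()]
        rng = np.random.default_rng(7)
        # strictly interior points (oracle and join agree away from edges)
        lons = rng.uniform(0.001, 1.999, 100)
        lats = rng.uniform(0.001, 1.999, 100)
        lons = np.where(np.abs(lons - 1) < 1e-3, 0.5, lons)
        lats = np.where(np.abs(lats - 1) < 1e-3, 0.5, lats)
        out, _ = assign_ecoregion(self._records(lons, lats), layer)
        for lon, lat, got in zip(lons, lats, out["ecoregion_l2"]):
            expected = next(k for k, ring in tiles.items()
                            if _ray_casting(lon, lat, ring))
            assert got == expected

    def test_geojson_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=0, n_reservoirs=0, n_ecoregions=4)
        path = tmp_path / "eco.geojson"
        write_ecoregions_geojson(cfg, path)
        layer = load_ecoregions(path)
        assert [label for label, _ in layer] \
            == [label for label, _ in ecoregion_polygons(cfg)]
        for (_, a), (_, b) in zip(layer, ecoregion_polygons(cfg)):
            assert a.equals(b)
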