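"""Prediction grid, kriged attributes, proxy fill, standardized indices."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from cpuestd.environment import EnvField, sample_environment
from cpuestd.gam import ModelSpec, SmoothTerm, fit_gam
from cpuestd.geometry import GeometryConfig, make_study_geometry
from cpuestd.grid import (NM_TO_KM, EARTH_RADIUS_KM, LocalEqualArea,
                          assign_cell_attributes, build_grid,
                          cell_mean_depth, compare_observed_predicted,
                          krige_environment, proxy_fill, standardized_index)
from cpuestd.simulate import simulate_hauls


def _small_geometry(nm_lon, nm_lat, lat0=43.0, lon0=15.0, **kw):
    """Geometry whose bounding box spans a given size in nautical miles."""
    dlat = nm_lat * NM_TO_KM / (np.pi * EARTH_RADIUS_KM / 180.0)
    dlon = nm_lon * NM_TO_KM / (np.pi * EARTH_RADIUS_KM / 180.0
                                * np.cos(np.radians(lat0)))
    cfg = GeometryConfig(lon_min=lon0, lon_max=lon0 + dlon,
                         lat_min=lat0 - dlat / 2, lat_max=lat0 + dlat / 2,
                         pits=(), **kw)
    return make_study_geometry(cfg)


@pytest.fixture(scope="module")
def grid_cells(geometry):
    return build_grid(geometry, cell_size_nm=2.0)


class TestBuildGrid:
    def test_square_4nm_region_gives_exactly_4_cells(self):
        geom = _small_geometry(3.995, 3.995)
        cells = build_grid(geom, cell_size_nm=2.0)
        assert len(cells) == 4

    def test_cell_size_must_be_positive(self, geometry):
        with pytest.raises(ValueError):
            build_grid(geometry, cell_size_nm=0.0)

    def test_nominal_cell_areas_constant(self, grid_cells):
        areas = {c.area_nm2 for c in grid_cells}
        assert areas == {4.0}

    def test_area_conservation_against_spherical_oracle(self, geometry,
                                                        grid_cells):
        """Sum of clipped cell areas equals the spherical area of the
        bounding box (independent closed form), within 1 %."""
        cfg = geometry.config
        oracle_km2 = (EARTH_RADIUS_KM ** 2
                      * np.radians(cfg.lon_max - cfg.lon_min)
                      * (np.sin(np.radians(cfg.lat_max))
                         - np.sin(np.radians(cfg.lat_min))))
        total = sum(c.clipped_area_nm2 for c in grid_cells) * NM_TO_KM ** 2
        assert total == pytest.approx(oracle_km2, rel=0.01)

    def test_each_haul_falls_in_exactly_one_cell(self, geometry, timeline,
                                                 effects, grid_cells):
        env = sample_environment(geometry, "spring", 2016, seed=1)
        hauls = simulate_hauls(geometry, env, timeline, effects, 60,
                               "spring", 2016, seed=2)
        for lon, lat in zip(hauls["lon"], hauls["lat"]):
            hits = sum(c.polygon.covers(Point(lon, lat))
                       for c in grid_cells)
            assert hits == 1

    def test_deterministic_cell_ids(self, geometry, grid_cells):
        again = build_grid(geometry, cell_size_nm=2.0)
        assert [c.cell_id for c in again] == [c.cell_id for c in grid_cells]
        assert np.allclose([c.lon for c in again],
                           [c.lon for c in grid_cells])

    def test_projection_round_trip(self):
        proj = LocalEqualArea(15.0, 43.0)
        lon = np.array([14.8, 15.0, 15.9])
        lat = np.array([42.8, 43.0, 43.5])
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)


class TestCellAttributes:
    def test_constant_depth_surface(self, timeline):
        geom = _small_geometry(8.0, 8.0, base_depth=150.0)
        cells = build_grid(geom, cell_size_nm=2.0)
        informed = assign_cell_attributes(cells, geom, timeline,
                                          "spring", 2016)
        assert np.allclose(informed["depth"], 150.0)

    def test_autumn_domain_subset_of_spring(self, geometry, timeline,
                                            grid_cells):
        spring = assign_cell_attributes(grid_cells, geometry, timeline,
                                        "spring", 2017)
        autumn = assign_cell_attributes(grid_cells, geometry, timeline,
                                        "autumn", 2017)
        s = set(spring.loc[spring["in_domain"], "cell_id"])
        a = set(autumn.loc[autumn["in_domain"], "cell_id"])
        assert a < s
        assert a == set(autumn.loc[autumn["western"], "cell_id"])

    def test_mean_depth_matches_fine_quadrature(self, geometry, grid_cells):
        cell = grid_cells[len(grid_cells) // 2]
        coarse = cell_mean_depth(geometry, cell, n=6)
        fine = cell_mean_depth(geometry, cell, n=40)  # quadrature oracle
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_management_levels_by_year(self, geometry, timeline,
                                       grid_cells):
        before = assign_cell_attributes(grid_cells, geometry, timeline,
                                        "spring", 2014)
        after = assign_cell_attributes(grid_cells, geometry, timeline,
                                       "autumn", 2018)
        assert set(before["fishery"]) == {"Y"}
        assert {"N", "L"} <= set(after["fishery"])


class TestKrigeEnvironment:
    def test_grid_values_near_station_values(self, geometry, grid_cells):
        env = sample_environment(geometry, "spring", 2015, n_stations=30,
                                 seed=3)
        vals = krige_environment(env.stations, grid_cells, "BT", geometry)
        st = env.stations["BT"]
        assert np.isfinite(vals).all()
        # kriged field stays within a sane envelope of the station range
        span = st.max() - st.min()
        assert vals.min() > st.min() - span
        assert vals.max() < st.max() + span


class TestProxyFill:
    @pytest.fixture
    def layers(self, geometry):
        f2013 = sample_environment(geometry, "spring", 2013, seed=5)
        f2019 = sample_environment(geometry, "spring", 2019, seed=6)
        f2012 = sample_environment(geometry, "spring", 2012, seed=7)
        f2012.drop_param("Oxy")
        return {("spring", 2012): f2012, ("spring", 2013): f2013,
                ("spring", 2019): f2019}

    def test_2012_oxygen_borrows_2013(self, layers):
        full = proxy_fill(layers, [("spring", 2012), ("spring", 2013)])
        lon = np.linspace(14.8, 16.0, 7)
        lat = np.linspace(42.8, 43.5, 7)
        assert np.allclose(full[("spring", 2012)].value("Oxy", lon, lat),
                           layers[("spring", 2013)].value("Oxy", lon, lat))
        assert full[("spring", 2012)].proxy_of["Oxy"] == ("spring", 2013)
        # observed parameters untouched
        assert "BT" not in full[("spring", 2012)].proxy_of

    def test_missing_2018_borrows_everything_from_2019(self, layers):
        full = proxy_fill(layers, [("spring", 2018)])
        lon, lat = np.array([15.2]), np.array([43.0])
        for p in ("BT", "Sal", "Oxy"):
            assert np.allclose(full[("spring", 2018)].value(p, lon, lat),
                               layers[("spring", 2019)].value(p, lon, lat))
            assert full[("spring", 2018)].proxy_of[p] == ("spring", 2019)

    def test_complete_input_identity(self, layers):
        full = proxy_fill(layers, [("spring", 2013), ("spring", 2019)])
        assert full[("spring", 2013)] is layers[("spring", 2013)]
        assert full[("spring", 2019)] is layers[("spring", 2019)]

    def test_missing_donor_reported(self, layers):
        with pytest.raises(KeyError, match="autumn.*2016"):
            proxy_fill(layers, [("autumn", 2016)])

    def test_proxy_layers_never_become_donors(self, geometry, layers):
        # 2012's filled Oxy (borrowed from 2013) must not donate onward
        full = proxy_fill(layers, [("spring", 2012)])
        merged = dict(layers)
        merged[("spring", 2011)] = EnvField("spring", 2011, {},
                                            layers[("spring", 2013)]
                                            .stations.copy())
        full2 = proxy_fill(merged, [("spring", 2011)])
        assert full2[("spring", 2011)].proxy_of["Oxy"] == ("spring", 2013)


def _toy_informed_grid(means):
    rows = []
    for i, lvl in enumerate(means):
        rows.append({"cell_id": i, "lon": 15.0 + 0.01 * i, "lat": 43.0,
                     "depth": 150.0, "fishery": lvl, "in_domain": True,
                     "survey": "spring", "year": 2016, "week": 18})
    return pd.DataFrame(rows)


class TestStandardizedIndex:
    def test_constant_model_gives_constant_index(self):
        d = pd.DataFrame({"y": np.full(30, 12.0)})
        fit = fit_gam(ModelSpec("y"), d)
        grid = _toy_informed_grid(["Y", "Y", "Y"])
        idx = standardized_index(fit, grid)
        assert idx["mean"] == pytest.approx(12.0, rel=1e-8)
        assert idx["n_cells"] == 3

    def test_three_cell_toy_mean_is_hand_arithmetic(self):
        rng = np.random.default_rng(9)
        n = 120
        lvl = rng.choice(["Y", "L", "N"], n)
        eta = 2.0 + 0.5 * (lvl == "L") + 0.9 * (lvl == "N")
        d = pd.DataFrame({"y": rng.gamma(50, np.exp(eta) / 50),
                          "fishery": lvl})
        fit = fit_gam(ModelSpec("y", factors=("fishery",)), d)
        grid = _toy_informed_grid(["Y", "L", "N"])
        idx = standardized_index(fit, grid)
        b0 = fit.coef("Intercept")
        by_hand = np.mean([np.exp(b0),
                           np.exp(b0 + fit.coef("fisheryL")),
                           np.exp(b0 + fit.coef("fisheryN"))])
        assert idx["mean"] == pytest.approx(by_hand, rel=1e-10)
        assert idx["se"] == pytest.approx(
            np.sqrt(np.sum(idx["cell_se"] ** 2)) / 3, rel=1e-12)

    def test_ban_level_raises_index_when_offset_positive(self,
                                                         survey_dataset):
        filt = survey_dataset["filtered"]
        fit = fit_gam(ModelSpec("biomass_index",
                                smooths=(SmoothTerm("depth"),),
                                factors=("fishery", "tod")), filt)
        grid_y = _toy_informed_grid(["Y"] * 5)
        grid_n = _toy_informed_grid(["N"] * 5)
        idx_y = standardized_index(fit, grid_y)["mean"]
        idx_n = standardized_index(fit, grid_n)["mean"]
        assert fit.coef("fisheryN") > 0      # planted positive ban effect
        assert idx_n > idx_y

    def test_missing_attribute_names_cell(self):
        d = pd.DataFrame({"y": np.full(30, 5.0),
                          "depth": np.linspace(100, 200, 30)})
        fit = fit_gam(ModelSpec("y", smooths=(SmoothTerm("depth"),)), d)
        grid = _toy_informed_grid(["Y", "Y", "Y"])
        grid.loc[1, "depth"] = np.nan
        with pytest.raises(ValueError, match="depth"):
            standardized_index(fit, grid)


class TestObservedVsPredicted:
    def test_reported_autumn_2015_increment(self):
        assert round(compare_observed_predicted(24.9, 37.33)) == 33

    def test_equal_values_zero(self):
        assert compare_observed_predicted(50.0, 50.0) == 0.0

    def test_spring_2012_increment(self):
        assert compare_observed_predicted(24.6, 71.3) == pytest.approx(
            65.5, abs=0.05)

    def test_observed_denominator_flag(self):
        out = compare_observed_predicted(50.0, 75.0,
                                         denominator="observed")
        assert out == pytest.approx(50.0)
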