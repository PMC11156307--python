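"""Centers of gravity, shift rates, percent changes, rings, fishing grounds."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from fishcast import bioeconomics as be
from fishcast import summaries as sm
from fishcast.grids import cell_area_km2, make_layer


def surface(values, lon, lat):
    return make_layer(np.asarray(values, float), np.asarray(lon, float),
                      np.asarray(lat, float), "abundance")


def law_of_cosines_km(lon1, lat1, lon2, lat2):
    """Independent great-circle oracle (spherical law of cosines)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    return 6371.0 * math.acos(
        min(1.0, math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
    )


class TestCog:
    def test_uniform_field_centroid_at_area_weighted_center(self):
        lon = [0.25, 0.75]
        lat = [60.25, 60.75]
        surf = surface(np.ones((2, 2)), lon, lat)
        cog = sm.center_of_gravity(surf)
        assert cog[0] == pytest.approx(0.5)
        # area weighting pulls the latitude slightly towards the equator
        a = cell_area_km2(np.array(lat), 0.5, 0.5)
        expected_lat = (a[0] * 2 * 60.25 + a[1] * 2 * 60.75) / (2 * a.sum())
        assert cog[1] == pytest.approx(expected_lat)
        assert cog[1] < 60.5

    def test_point_mass_returns_that_cell_center(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 7.0
        surf = surface(vals, [0.0, 1.0, 2.0], [50.0, 51.0, 52.0])
        assert sm.center_of_gravity(surf) == pytest.approx((2.0, 51.0))

    def test_two_cell_weighted_mean(self):
        surf = surface([[1.0, 0.0, 3.0]], [0.0, 1.0, 2.0], [60.0])
        lon, lat = sm.center_of_gravity(surf)
        assert lon == pytest.approx(1.5)
        assert lat == pytest.approx(60.0)

    def test_translation_equivariance_in_longitude(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 5, (4, 5))
        lon = np.arange(5) * 0.5
        lat = 60 + np.arange(4) * 0.5
        a = sm.center_of_gravity(surface(vals, lon, lat))
        # same abundance pattern moved one cell east
        b = sm.center_of_gravity(surface(vals, lon + 0.5, lat))
        assert b[0] == pytest.approx(a[0] + 0.5)
        assert b[1] == pytest.approx(a[1])

    def test_all_zero_surface_rejected(self):
        with pytest.raises(ValueError):
            sm.center_of_gravity(surface(np.zeros((2, 2)), [0, 1], [50, 51]))


class TestShiftRate:
    def test_identical_cogs_give_zero(self):
        assert sm.shift_rate((0.0, 60.0), (0.0, 60.0), 2009.5, 2030.5) == 0.0

    def test_one_degree_latitude_over_2_1_decades(self):
        rate = sm.shift_rate((-170.0, 60.0), (-170.0, 61.0), 2009.5, 2030.5)
        oracle = law_of_cosines_km(-170.0, 60.0, -170.0, 61.0) / 2.1
        assert rate == pytest.approx(oracle, rel=1e-9)
        assert rate == pytest.approx(52.95, abs=0.01)

    def test_inverse_proportionality_to_elapsed_time(self):
        r1 = sm.shift_rate((0.0, 60.0), (1.0, 61.0), 2009.5, 2030.5)
        r2 = sm.shift_rate((0.0, 60.0), (1.0, 61.0), 2009.5, 2051.5)
        assert r2 == pytest.approx(r1 / 2)

    def test_sign_convention_invariance_and_errors(self):
        a = sm.shift_rate((-170.0, 60.0), (-168.0, 62.0), 2009.5, 2030.5)
        b = sm.shift_rate((170.0, 60.0), (168.0, 62.0), 2009.5, 2030.5)
        assert a == pytest.approx(b)
        assert a >= 0
        with pytest.raises(ValueError):
            sm.shift_rate((0, 60), (1, 61), 2030.5, 2009.5)


class TestPercentChange:
    def test_basic_cases(self):
        assert sm.percent_change(10.0, 10.0) == 0.0
        assert sm.percent_change(200.0, 150.0) == pytest.approx(-25.0)

    def test_negative_present_uses_absolute_denominator(self):
        # present -100 -> future -50 is an improvement: +50%
        assert sm.percent_change(-100.0, -50.0) == pytest.approx(50.0)
        assert sm.percent_change(-100.0, -150.0) == pytest.approx(-50.0)

    def test_zero_present_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = sm.percent_change(0.0, 5.0)
        assert math.isnan(out)


class TestRings:
    def test_constant_field_rings_have_identical_means(self):
        lon = np.arange(5) * 0.5
        lat = 58 + np.arange(5) * 0.5
        mcp = surface(np.full((5, 5), 4.2), lon, lat)
        prof = sm.port_buffer_profile(mcp, lon[2], lat[2], 100.0, 4)
        nonempty = prof.dropna(subset=["mean_mcp"])
        assert len(nonempty) >= 2
        np.testing.assert_allclose(nonempty["mean_mcp"], 4.2)

    def test_single_cell_at_150km_lands_in_ring_two(self):
        # ~1.35 degrees of latitude ~ 150 km from the port cell
        lat = np.array([60.0, 61.35])
        lon = np.array([0.0])
        vals = np.array([[0.0], [9.0]])
        prof = sm.port_buffer_profile(surface(vals, lon, lat), 0.0, 60.0, 100.0, 3)
        means = prof.set_index("ring")["mean_mcp"]
        assert means[2] == pytest.approx(9.0 / 1)  # only that cell in ring 2
        assert means[1] == pytest.approx(0.0)

    def test_ring_means_match_exhaustive_enumeration(self):
        """5x5 toy grid vs a cell-by-cell brute-force recomputation."""
        rng = np.random.default_rng(3)
        lon = -170 + np.arange(5) * 1.0
        lat = 57 + np.arange(5) * 1.0
        vals = rng.uniform(0, 10, (5, 5))
        port = (-168.0, 59.0)
        mcp = surface(vals, lon, lat)
        prof = sm.port_buffer_profile(mcp, port[0], port[1], 100.0, 8)

        brute = {k: [] for k in range(1, 9)}
        for i, la in enumerate(lat):
            for j, lo in enumerate(lon):
                d = law_of_cosines_km(port[0], port[1], lo, la)
                k = max(1, math.ceil(d / 100.0))
                if k <= 8:
                    brute[k].append(vals[i, j])
        for k in range(1, 9):
            row = prof.set_index("ring").loc[k]
            if brute[k]:
                assert row["mean_mcp"] == pytest.approx(
                    float(np.mean(brute[k])), rel=1e-9
                )
                assert row["n_cells"] == len(brute[k])
            else:
                assert math.isnan(row["mean_mcp"])

    def test_no_cell_in_range_rejected(self):
        mcp = surface([[1.0]], [0.0], [60.0])
        with pytest.raises(ValueError, match="outermost ring"):
            sm.port_buffer_profile(mcp, 10.0, 80.0, 100.0, 2)


@pytest.fixture()
def toy_grounds():
    """12-cell toy: 3x4 grid, two jurisdictions split at lon 1.5."""
    lon = np.arange(4) * 1.0
    lat = 60 + np.arange(3) * 1.0
    rng = np.random.default_rng(5)
    effort_vals = rng.uniform(0, 500, (3, 4))
    effort_vals[0, 0] = 1500.0
    effort_vals[1, 3] = 2000.0
    effort = surface(effort_vals, lon, lat)
    dens = rng.uniform(1, 10, (3, 4))
    surf = surface(dens, lon, lat)
    lon2d = np.broadcast_to(lon[None, :], (3, 4))
    masks = {
        "west": xr.DataArray(lon2d < 1.5, dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon}),
        "east": xr.DataArray(lon2d >= 1.5, dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon}),
    }
    params = pd.DataFrame(
        [{"species": "sp01", "group": "groundfish", "g": 0.3, "phi": 0.188,
          "u_msy": 0.2, "price": 1000.0, "f_bar": 1.5, "b_bar": 0.5,
          "beta": 1.3}]
    )
    surfaces = {("sp01", "2000-2019", ""): surf}
    return effort, surf, masks, params, surfaces


class TestFishingGrounds:
    def test_threshold_above_max_reports_missing(self, toy_grounds):
        effort, _surf, masks, params, surfaces = toy_grounds
        out = sm.fishing_ground_compare(effort, 1e6, surfaces, masks, params)
        assert out["missing"].all()
        assert out["MCP"].isna().all()

    def test_values_match_manual_bioeconomics_chain(self, toy_grounds):
        """End-to-end oracle on 12 cells: recompute via the equations by hand."""
        effort, surf, masks, params, surfaces = toy_grounds
        out = sm.fishing_ground_compare(effort, 1000.0, surfaces, masks, params)
        p = params.iloc[0]
        for name in ("west", "east"):
            mask = (effort >= 1000.0) & masks[name]
            B = be.integrate_biomass(surf, mask)
            msy_mt = be.msy(B, p.g, p.phi)
            catch = B * p.u_msy
            R = p.price * catch
            c = be.cost_param(p.price, p.f_bar, p.b_bar, msy_mt, p.g, p.beta)
            pi = R - c * p.g**p.beta
            row = out[out["jurisdiction"] == name].iloc[0]
            assert row["MCP"] == pytest.approx(catch, rel=1e-12)
            assert row["MRP"] == pytest.approx(R, rel=1e-12)
            assert row["MPP"] == pytest.approx(pi, rel=1e-12)

    def test_uniform_effort_and_density_ratio_equals_area_ratio(self):
        lon = np.arange(4) * 1.0
        lat = 60 + np.arange(2) * 1.0
        effort = surface(np.full((2, 4), 2000.0), lon, lat)
        dens = surface(np.ones((2, 4)), lon, lat)
        lon2d = np.broadcast_to(lon[None, :], (2, 4))
        masks = {
            "west": xr.DataArray(lon2d < 0.5, dims=("lat", "lon"),
                                 coords={"lat": lat, "lon": lon}),
            "east": xr.DataArray(lon2d >= 0.5, dims=("lat", "lon"),
                                 coords={"lat": lat, "lon": lon}),
        }
        params = pd.DataFrame(
            [{"species": "s", "group": "groundfish", "g": 0.3, "phi": 0.188,
              "u_msy": 0.2, "price": 10.0, "f_bar": 1.5, "b_bar": 0.5,
              "beta": 1.3}]
        )
        out = sm.fishing_ground_compare(
            effort, 1000.0, {("s", "2000-2019", "")
                             : dens}, masks, params
        )
        mcp_w = out[out.jurisdiction == "west"]["MCP"].iloc[0]
        mcp_e = out[out.jurisdiction == "east"]["MCP"].iloc[0]
        from fishcast.grids import area_grid

        area_w = float(area_grid(dens).where(masks["west"]).sum())
        area_e = float(area_grid(dens).where(masks["east"]).sum())
        assert mcp_w / mcp_e == pytest.approx(area_w / area_e, rel=1e-12)


class TestCogTracks:
    def test_tracks_table_contains_rates_vs_present(self):
        lon = np.arange(3) * 1.0
        lat = 60 + np.arange(3) * 1.0
        present = np.zeros((3, 3)); present[0, 1] = 5.0
        future = np.zeros((3, 3)); future[2, 1] = 5.0
        surfaces = {
            ("sp01", "2000-2019", ""): surface(present, lon, lat),
            ("sp01", "2081-2100", "SSP585"): surface(future, lon, lat),
        }
        df = sm.cog_tracks(surfaces)
        row = df[(df.period == "2081-2100")].iloc[0]
        oracle = law_of_cosines_km(1.0, 60.0, 1.0, 62.0) / 8.1
        assert row["shift_rate_km_per_decade"] == pytest.approx(oracle, rel=1e-9)
        present_row = df[df.period == "2000-2019"].iloc[0]
        assert math.isnan(present_row["shift_rate_km_per_decade"])
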