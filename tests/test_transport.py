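"""Backtracking physics, origin classification and ice metrics."""

import numpy as np
import pytest
import xarray as xr

from icesink import synthetic as syn
from icesink import transport as tr


def release(lon=0.0, lat=79.0, seafloor=2650.0, ws=52.0, dates=(200.0,),
            **kw):
    return tr.ReleaseSpec(lon=lon, lat=lat, seafloor_depth=seafloor,
                          sinking_speed=ws, release_dates=list(dates), **kw)


def zonal_displacement_km(traj):
    """Displacement in the integrator's own (equirectangular) metric."""
    dlon = traj.surf_lon - traj.release_lon
    dlat = traj.surf_lat - traj.release_lat
    mx = dlon * np.cos(np.radians(traj.release_lat)) * tr.M_PER_DEG
    my = dlat * tr.M_PER_DEG
    return np.hypot(mx, my) / 1000.0


class TestInterpolation:
    def test_node_identity(self, wide_domain):
        cfg = syn.SyntheticConfig(seed=2, domain=wide_domain)
        field, _ = syn.make_velocity_field(cfg)
        lon, lat = field.lon[3], field.lat[2]
        depth, t = field.depth[1], field.time[4]
        u, v, w = tr.interpolate_field(field, lon, lat, depth, t)
        stored = field.ds["v"].sel(lon=lon, lat=lat, depth=depth,
                                   time=t).item()
        assert v[0] == pytest.approx(stored)

    def test_linearity_at_midpoint(self):
        ds = syn.make_uniform_field(u=1.0).ds
        lon = ds["lon"].values
        ds["u"][:] = np.where(lon >= lon[5], 3.0, 1.0)  # step at node 5
        field = tr.VelocityField(ds)
        mid = 0.5 * (lon[4] + lon[5])
        u, _, _ = tr.interpolate_field(field, mid, 79.0, 100.0, 100.0)
        assert u[0] == pytest.approx(2.0)

    def test_constant_field_everywhere(self, still_ocean):
        pts = [(-20.0, 75.5, 313.0, 17.0), (31.0, 83.0, 2111.0, 301.0)]
        for lon, lat, depth, t in pts:
            u, v, w = tr.interpolate_field(still_ocean, lon, lat, depth, t)
            assert (u[0], v[0], w[0]) == (0.0, 0.0, 0.0)

    def test_outside_hull_is_nan(self, still_ocean):
        u, _, _ = tr.interpolate_field(still_ocean, 500.0, 79.0, 100.0,
                                       100.0)
        assert np.isnan(u[0])


class TestBacktrack:
    def test_zero_flow_travel_time(self, still_ocean):
        traj = tr.backtrack(still_ocean, release(ws=50.0, seafloor=2650.0))
        assert traj.status[0] == "surfaced"
        assert 200.0 - traj.surf_time[0] == pytest.approx(47.0, abs=0.03)
        med, sd = tr.catchment_radius(traj)
        assert med == pytest.approx(0.0, abs=1e-9)

    def test_uniform_flow_closed_form(self, wide_domain):
        field = syn.make_uniform_field(u=0.1, domain=wide_domain)
        traj = tr.backtrack(field, release(ws=52.0, seafloor=2650.0))
        travel = 2350.0 / 52.0
        assert 200.0 - traj.surf_time[0] == pytest.approx(travel, abs=0.03)
        expected_km = 0.1 * 86400.0 * travel / 1000.0
        step_km = 0.1 * 1800.0 / 1000.0
        assert abs(zonal_displacement_km(traj)[0] - expected_km) \
            <= step_km + 1e-9

    def test_halving_step_converges(self, wide_domain):
        field = syn.make_uniform_field(u=0.08, v=0.03, domain=wide_domain)
        disp = []
        for step in (30.0, 15.0):
            traj = tr.backtrack(field, release(ws=40.0, seafloor=2650.0,
                                               time_step_min=step))
            disp.append(zonal_displacement_km(traj)[0])
        assert abs(disp[1] - disp[0]) < 0.01 * disp[0]

    def test_reversibility(self, wide_domain):
        field = syn.make_uniform_field(u=0.05, v=-0.02, domain=wide_domain)
        traj = tr.backtrack(field, release(ws=45.0, seafloor=2650.0))
        lon, lat, depth, t = tr.forward_track(
            field, traj.surf_lon[0], traj.surf_lat[0], traj.surf_time[0],
            45.0, target_depth=traj.release_depth)
        assert lon[0] == pytest.approx(traj.release_lon, abs=0.05)
        assert lat[0] == pytest.approx(traj.release_lat, abs=0.05)

    def test_release_outside_grid_rejected(self, still_ocean):
        with pytest.raises(ValueError):
            tr.backtrack(still_ocean, release(lon=170.0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            release(ws=-5.0)
        with pytest.raises(ValueError):
            release(seafloor=200.0)  # release depth would be negative


class TestOriginClassification:
    def make_ice(self, conc, wide_domain):
        lon, lat, _, _ = wide_domain.axes()
        time = np.arange(0.0, 366.0)
        arr = np.full((time.size, lat.size, lon.size), conc)
        return tr.IceSeries(xr.Dataset(
            {"iceconc": (("time", "lat", "lon"), arr)},
            coords={"time": time, "lat": lat, "lon": lon}))

    @pytest.mark.parametrize("conc, expect_pct, expect_label", [
        (0.8, 100.0, "ice-covered"),
        (0.0, 0.0, "ice-free"),
        (0.15, 100.0, "ice-covered"),   # inclusive threshold convention
        (0.1499, 0.0, "ice-free"),
    ])
    def test_uniform_concentration(self, still_ocean, wide_domain, conc,
                                   expect_pct, expect_label):
        traj = tr.backtrack(still_ocean, release(dates=(150.0, 200.0)))
        origin, pct = tr.classify_origin(traj,
                                         self.make_ice(conc, wide_domain))
        assert pct == expect_pct
        assert set(origin) == {expect_label}

    def test_reorder_invariance(self, still_ocean, wide_domain):
        ice = self.make_ice(0.5, wide_domain)
        t1 = tr.backtrack(still_ocean, release(dates=(150.0, 180.0, 210.0)))
        t2 = tr.backtrack(still_ocean, release(dates=(210.0, 150.0, 180.0)))
        _, p1 = tr.classify_origin(t1, ice)
        _, p2 = tr.classify_origin(t2, ice)
        assert p1 == p2


class TestTrajectoryStatistics:
    def test_median_of_two(self):
        # synthetic ensemble: two surfaced particles at 100 and 300 km north
        deg1 = 100.0 / (tr.M_PER_DEG / 1000.0)
        deg3 = 300.0 / (tr.M_PER_DEG / 1000.0)
        traj = tr.TrajectoryEnsemble(
            release_lon=0.0, release_lat=76.0, release_depth=2000.0,
            release_times=np.array([10.0, 20.0]),
            positions=np.full((2, 3, 4), np.nan),
            surf_lon=np.array([0.0, 0.0]),
            surf_lat=np.array([76.0 + deg1, 76.0 + deg3]),
            surf_time=np.array([40.0, 50.0]),
            status=np.array(["surfaced", "surfaced"], dtype=object))
        med, _ = tr.catchment_radius(traj)
        assert med == pytest.approx(200.0, rel=1e-3)

    def test_uniform_flow_length_equals_radius(self, wide_domain):
        field = syn.make_uniform_field(u=0.1, domain=wide_domain)
        traj = tr.backtrack(field, release(ws=52.0, seafloor=2650.0))
        radius, _ = tr.catchment_radius(traj)
        length, _ = tr.trajectory_length(traj)
        assert length == pytest.approx(radius, rel=0.01)

    def test_eddy_path_longer_than_chord(self, wide_domain):
        cfg = syn.SyntheticConfig(seed=3, domain=wide_domain,
                                  eddy_amplitude=0.25,
                                  current_speed_east=0.02,
                                  current_speed_west=0.02)
        field, _ = syn.make_velocity_field(cfg)
        traj = tr.backtrack(field, release(lon=2.0, lat=79.5, ws=30.0,
                                           seafloor=2650.0))
        assert traj.status[0] == "surfaced"
        length, _ = tr.trajectory_length(traj)
        radius, _ = tr.catchment_radius(traj)
        assert length > radius * 1.05


class TestBinDensity:
    def test_stationary_particle_single_bin(self, still_ocean):
        traj = tr.backtrack(still_ocean, release())
        density, _ = tr.bin_density(traj)
        assert density.max() < 1.0  # particle rises through depth bins
        assert density.sum() == pytest.approx(1.0)

    def test_two_particles_split_weight(self):
        pos = np.full((2, 2, 4), np.nan)
        pos[0, 0] = (0.0, 76.0, 100.0, 10.0)
        pos[1, 0] = (1.0, 77.0, 500.0, 10.0)
        traj = tr.TrajectoryEnsemble(
            release_lon=0.0, release_lat=76.0, release_depth=2000.0,
            release_times=np.array([10.0, 10.0]), positions=pos,
            surf_lon=np.array([np.nan] * 2), surf_lat=np.array([np.nan] * 2),
            surf_time=np.array([np.nan] * 2),
            status=np.array(["max_steps"] * 2, dtype=object))
        density, _ = tr.bin_density(traj)
        assert sorted(density[density > 0].ravel()) == [0.5, 0.5]

    def test_normalisation_random_ensemble(self, wide_domain):
        field = syn.make_uniform_field(u=0.05, v=0.02, domain=wide_domain)
        traj = tr.backtrack(field, release(dates=(150.0, 200.0, 250.0)))
        density, _ = tr.bin_density(traj)
        assert density.sum() == pytest.approx(1.0)


class TestIceMetrics:
    def make_edge_ice(self, edge_lon, lon, lat, days=100):
        time = np.arange(float(days))
        conc = np.where(lon[None, :] < edge_lon, 0.9, 0.0)
        arr = np.broadcast_to(conc[:, None, :],
                              (time.size, lat.size, lon.size)).copy()
        return tr.IceSeries(xr.Dataset(
            {"iceconc": (("time", "lat", "lon"), arr)},
            coords={"time": time, "lat": lat, "lon": lon}))

    def test_count_constant_cover(self, wide_domain):
        lon, lat, _, _ = wide_domain.axes()
        ice = self.make_edge_ice(100.0, lon, lat)  # everywhere icy
        assert tr.count_ice_days(ice, 0.0, 79.0, (0, 99)) == 100

    def test_count_below_threshold(self, wide_domain):
        lon, lat, _, _ = wide_domain.axes()
        time = np.arange(100.0)
        arr = np.full((100, lat.size, lon.size), 0.10)
        ice = tr.IceSeries(xr.Dataset(
            {"iceconc": (("time", "lat", "lon"), arr)},
            coords={"time": time, "lat": lat, "lon": lon}))
        assert tr.count_ice_days(ice, 0.0, 79.0, (0, 99)) == 0

    def test_count_sweeping_edge(self):
        # edge crosses the point mid-window: icy for exactly half the days
        lon = np.arange(-10.0, 10.5, 0.5)
        lat = np.arange(78.0, 80.5, 0.5)
        time = np.arange(100.0)
        edge = -5.0 + 0.1 * time          # passes lon=0 at day 50
        conc = np.where(lon[None, :] < edge[:, None], 0.9, 0.0)
        arr = np.broadcast_to(conc[:, None, :],
                              (100, lat.size, lon.size)).copy()
        ice = tr.IceSeries(xr.Dataset(
            {"iceconc": (("time", "lat", "lon"), arr)},
            coords={"time": time, "lat": lat, "lon": lon}))
        n = tr.count_ice_days(ice, 0.0, 79.0, (0, 99))
        assert 45 <= n <= 55

    def test_distance_zero_inside_edge_cell(self, wide_domain):
        lon, lat, _, _ = wide_domain.axes()
        ice = self.make_edge_ice(0.0, lon, lat)
        # the last icy column before the edge is an edge cell
        edge_lon = lon[lon < 0.0][-1]
        assert tr.distance_to_ice_edge(ice, float(edge_lon), 79.0, 10.0) \
            == 0.0

    def test_meridional_edge_spherical_distance(self):
        lon = np.arange(-5.0, 5.5, 1.0)
        lat = np.arange(78.0, 80.5, 0.5)
        ice = self.make_edge_ice(-0.5, lon, lat)
        # edge cells are at lon=-1; querying from lon=0 at lat=79
        d = tr.distance_to_ice_edge(ice, 0.0, 79.0, 10.0)
        expect = tr.haversine_km(0.0, 79.0, -1.0, 79.0)
        assert d == pytest.approx(expect, rel=1e-6)
        assert expect == pytest.approx(111.19 * np.cos(np.radians(79.0)),
                                       rel=0.01)

    def test_ice_free_field_signals_absence(self, wide_domain):
        lon, lat, _, _ = wide_domain.axes()
        ice = self.make_edge_ice(-999.0, lon, lat)
        with pytest.raises(LookupError):
            tr.distance_to_ice_edge(ice, 0.0, 79.0, 10.0)
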