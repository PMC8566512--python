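"""Lagrangian backtracking of sinking aggregates and sea-ice metrics.

Aggregates collected at depth are traced back to their surface origin by
reversing the flow field: the particle is treated as rising from the
sampling depth with the sinking speed w_s added to the modelled vertical
velocity, while being displaced with the reversed horizontal velocity.
Integration is explicit Euler with a 30-minute default step; bi-hourly
positions are stored.  Surface origins are classified as ice-covered
when the sea-ice concentration at the surfacing position and date is at
least 15% (inclusive).

Depth is positive downward (m); the vertical velocity w in the field is
positive upward (m/s); time is in days on the field's own time axis.
Great-circle distances use the haversine formula on a sphere of radius
6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0
M_PER_DEG = np.pi * EARTH_RADIUS_KM * 1000.0 / 180.0  # meters per degree lat
SECONDS_PER_DAY = 86400.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) \
        * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


class VelocityField:
    """Gridded time-dependent 3-D velocity on a regular lon/lat/depth/time
    grid, wrapping an :class:`xarray.Dataset` with variables u, v, w."""

    def __init__(self, ds: xr.Dataset):
        for name in ("u", "v", "w"):
            if name not in ds:
                raise ValueError(f"velocity dataset must contain '{name}'")
        for axis in ("time", "depth", "lat", "lon"):
            coord = np.asarray(ds[axis].values, dtype=float)
            if coord.size > 1 and not np.all(np.diff(coord) > 0):
                raise ValueError(f"grid axis '{axis}' must be strictly "
                                 "increasing")
        if not all(np.isfinite(ds[v].values).all() for v in ("u", "v", "w")):
            raise ValueError("velocity values must be finite")
        self.ds = ds
        self._interp = {}

    @property
    def time(self):
        return np.asarray(self.ds["time"].values, dtype=float)

    @property
    def depth(self):
        return np.asarray(self.ds["depth"].values, dtype=float)

    @property
    def lat(self):
        return np.asarray(self.ds["lat"].values, dtype=float)

    @property
    def lon(self):
        return np.asarray(self.ds["lon"].values, dtype=float)

    def _interpolator(self, var: str) -> RegularGridInterpolator:
        if var not in self._interp:
            self._interp[var] = RegularGridInterpolator(
                (self.time, self.depth, self.lat, self.lon),
                self.ds[var].transpose("time", "depth", "lat",
                                       "lon").values.astype(float),
                method="linear", bounds_error=False, fill_value=np.nan)
        return self._interp[var]

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        return cls(xr.open_dataset(path).load())


class IceSeries:
    """Sea-ice concentration (fraction, 0-1) on a lon/lat/time grid."""

    def __init__(self, ds: xr.Dataset):
        if "iceconc" not in ds:
            raise ValueError("ice dataset must contain 'iceconc'")
        conc = ds["iceconc"].values
        if np.nanmin(conc) < 0 or np.nanmax(conc) > 1:
            raise ValueError("ice concentration must lie in [0, 1]")
        self.ds = ds

    @property
    def time(self):
        return np.asarray(self.ds["time"].values, dtype=float)

    @property
    def lat(self):
        return np.asarray(self.ds["lat"].values, dtype=float)

    @property
    def lon(self):
        return np.asarray(self.ds["lon"].values, dtype=float)

    def concentration_at(self, lon, lat, time) -> np.ndarray:
        """Concentration at the nearest grid cell and nearest time slice."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        time = np.atleast_1d(np.asarray(time, dtype=float))
        it = np.abs(self.time[None, :] - time[:, None]).argmin(axis=1)
        iy = np.abs(self.lat[None, :] - lat[:, None]).argmin(axis=1)
        ix = np.abs(self.lon[None, :] - lon[:, None]).argmin(axis=1)
        conc = self.ds["iceconc"].transpose("time", "lat", "lon").values
        return conc[it, iy, ix]

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "IceSeries":
        return cls(xr.open_dataset(path).load())


@dataclass
class ReleaseSpec:
    """Where, when and how particles are (back-)released.

    Particles start ``release_offset`` m above the seafloor (default
    300 m) at the station position, once per release date, and rise with
    sinking speed ``sinking_speed`` (m/d) added to the modelled vertical
    velocity.
    """

    lon: float
    lat: float
    seafloor_depth: float
    sinking_speed: float                       # m/d
    release_dates: Sequence[float] = ()        # days on the field time axis
    release_offset: float = 300.0
    time_step_min: float = 30.0
    store_interval_h: float = 2.0
    surfacing_window: tuple[float, float] | None = None
    max_days: float = 400.0

    def __post_init__(self) -> None:
        if self.sinking_speed <= 0:
            raise ValueError("sinking speed must be positive")
        if self.time_step_min <= 0:
            raise ValueError("time step must be positive")
        if self.release_depth <= 0:
            raise ValueError("release depth (seafloor - offset) must be "
                             "positive")

    @property
    def release_depth(self) -> float:
        return self.seafloor_depth - self.release_offset


@dataclass
class TrajectoryEnsemble:
    """Backtracked paths of one release experiment.

    ``positions`` is (n_particles, n_stored, 4) of (lon, lat, depth,
    time) at the storage interval, NaN-padded after termination.
    Surfacing fields are NaN for particles that did not surface inside
    the surfacing window.
    """

    release_lon: float
    release_lat: float
    release_depth: float
    release_times: np.ndarray
    positions: np.ndarray
    surf_lon: np.ndarray
    surf_lat: np.ndarray
    surf_time: np.ndarray
    status: np.ndarray                       # "surfaced"|"exited"|"max_steps"
    origin: np.ndarray | None = None         # filled by classify_origin

    @property
    def n_particles(self) -> int:
        return self.release_times.size

    @property
    def surfaced(self) -> np.ndarray:
        """Mask of particles with a valid surfacing record."""
        return np.isfinite(self.surf_time)

    def to_dataframe(self) -> pd.DataFrame:
        """One-row-per-particle summary (CSV-friendly)."""
        df = pd.DataFrame({
            "release_time": self.release_times,
            "status": self.status,
            "surf_lon": self.surf_lon,
            "surf_lat": self.surf_lat,
            "surf_time": self.surf_time,
        })
        if self.origin is not None:
            df["origin"] = self.origin
        return df


def interpolate_field(field: VelocityField, lon, lat, depth, time):
    """Trilinear-in-space, linear-in-time interpolation of (u, v, w).

    Queries outside the grid hull return NaN, which the integrator
    treats as an out-of-domain signal.
    """
    pts = np.column_stack([np.atleast_1d(np.asarray(a, dtype=float))
                           for a in (time, depth, lat, lon)])
    return tuple(field._interpolator(v)(pts) for v in ("u", "v", "w"))


def _integrate(field: VelocityField, lon0, lat0, depth0, t0,
               sinking_speed_m_d: float, time_step_min: float,
               store_interval_h: float, max_days: float,
               direction: int = -1):
    """Euler integration of the (reversed) flow for a batch of particles.

    ``direction=-1`` integrates backward in time (rising particles);
    ``direction=+1`` forward (sinking), used for reversibility checks.
    Returns per-particle stored positions and termination info.
    """
    n = np.atleast_1d(np.asarray(t0, dtype=float)).size
    lon = np.full(n, lon0, dtype=float) if np.isscalar(lon0) \
        else np.asarray(lon0, dtype=float).copy()
    lat = np.full(n, lat0, dtype=float) if np.isscalar(lat0) \
        else np.asarray(lat0, dtype=float).copy()
    depth = np.full(n, depth0, dtype=float) if np.isscalar(depth0) \
        else np.asarray(depth0, dtype=float).copy()
    t = np.atleast_1d(np.asarray(t0, dtype=float)).copy()

    dt_s = time_step_min * 60.0
    dt_d = dt_s / SECONDS_PER_DAY
    w_s = sinking_speed_m_d / SECONDS_PER_DAY          # m/s
    steps_per_store = max(1, int(round(store_interval_h * 3600.0 / dt_s)))
    max_steps = int(np.ceil(max_days * SECONDS_PER_DAY / dt_s))
    n_store = max_steps // steps_per_store + 2
    top_depth = field.depth[0]

    positions = np.full((n, n_store, 4), np.nan)
    positions[:, 0] = np.column_stack([lon, lat, depth, t])
    store_idx = np.ones(n, dtype=int)

    status = np.full(n, "max_steps", dtype=object)
    end_lon = np.full(n, np.nan)
    end_lat = np.full(n, np.nan)
    end_time = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)

    for step in range(1, max_steps + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        u, v, w = interpolate_field(field, lon[idx], lat[idx],
                                    depth[idx], t[idx])
        bad = ~(np.isfinite(u) & np.isfinite(v) & np.isfinite(w))
        if bad.any():
            status[idx[bad]] = "exited"
            active[idx[bad]] = False
            idx = idx[~bad]
            u, v, w = u[~bad], v[~bad], w[~bad]
        if idx.size == 0:
            continue
        sgn = float(direction)
        lon[idx] += sgn * u * dt_s / (M_PER_DEG * np.cos(np.radians(lat[idx])))
        lat[idx] += sgn * v * dt_s / M_PER_DEG
        # depth positive down, w positive up: sinking forward in time,
        # rising when integrated backward
        depth[idx] += sgn * (w_s - w) * dt_s
        t[idx] += sgn * dt_d

        if step % steps_per_store == 0:
            positions[idx, store_idx[idx]] = np.column_stack(
                [lon[idx], lat[idx], depth[idx], t[idx]])
            store_idx[idx] += 1

        if direction < 0:
            done = active & (depth <= top_depth)
            if done.any():
                j = np.flatnonzero(done)
                status[j] = "surfaced"
                end_lon[j], end_lat[j], end_time[j] = lon[j], lat[j], t[j]
                active[j] = False
        # leaving the field's time span terminates the particle
        out_t = active & ((t < field.time[0]) | (t > field.time[-1]))
        if out_t.any():
            j = np.flatnonzero(out_t)
            status[j] = "exited"
            active[j] = False

    return positions, status, end_lon, end_lat, end_time, lon, lat, depth


def backtrack(field: VelocityField, release: ReleaseSpec) -> TrajectoryEnsemble:
    """Backtrack particles from the release depth to the surface.

    Each step moves the particle by -(u, v) * dt horizontally and
    upward by (w_s - w_model) * dt (depth positive down) while time runs
    backward.  Integration stops at the top model level (surfaced), when
    the particle leaves the spatial or temporal domain (exited), or
    after ``max_days`` (max_steps).  A surfacing record is kept only for
    particles that surface inside the surfacing window.
    """
    if not (field.lon[0] <= release.lon <= field.lon[-1]
            and field.lat[0] <= release.lat <= field.lat[-1]
            and field.depth[0] <= release.release_depth <= field.depth[-1]):
        raise ValueError("release position outside the velocity grid")
    t0 = np.asarray(release.release_dates, dtype=float)
    if t0.size == 0:
        raise ValueError("no release dates given")
    if t0.min() < field.time[0] or t0.max() > field.time[-1]:
        raise ValueError("release dates outside the field time span")

    positions, status, s_lon, s_lat, s_time, *_ = _integrate(
        field, release.lon, release.lat, release.release_depth, t0,
        release.sinking_speed, release.time_step_min,
        release.store_interval_h, release.max_days, direction=-1)

    if release.surfacing_window is not None:
        lo, hi = release.surfacing_window
        outside = (status == "surfaced") & ~((s_time >= lo) & (s_time <= hi))
        s_lon[outside] = np.nan
        s_lat[outside] = np.nan
        s_time[outside] = np.nan

    return TrajectoryEnsemble(
        release_lon=release.lon, release_lat=release.lat,
        release_depth=release.release_depth, release_times=t0,
        positions=positions, surf_lon=s_lon, surf_lat=s_lat,
        surf_time=s_time, status=status)


def forward_track(field: VelocityField, lon0, lat0, t0,
                  sinking_speed_m_d: float, target_depth: float,
                  time_step_min: float = 30.0, max_days: float = 400.0):
    """Forward-integrate a sinking particle from the surface until it
    reaches ``target_depth``; returns (lon, lat, depth, time) arrays of
    final states.  Used to check reversibility of the backtracking."""
    n = np.atleast_1d(np.asarray(t0, dtype=float)).size
    lon = np.full(n, lon0, dtype=float)
    lat = np.full(n, lat0, dtype=float)
    depth = np.full(n, field.depth[0], dtype=float)
    t = np.atleast_1d(np.asarray(t0, dtype=float)).astype(float).copy()
    dt_s = time_step_min * 60.0
    w_s = sinking_speed_m_d / SECONDS_PER_DAY
    max_steps = int(np.ceil(max_days * SECONDS_PER_DAY / dt_s))
    for _ in range(max_steps):
        active = depth < target_depth
        if not active.any():
            break
        u, v, w = interpolate_field(field, lon[active], lat[active],
                                    depth[active], t[active])
        lon[active] += u * dt_s / (M_PER_DEG
                                   * np.cos(np.radians(lat[active])))
        lat[active] += v * dt_s / M_PER_DEG
        depth[active] += (w_s - w) * dt_s
        t[active] += dt_s / SECONDS_PER_DAY
    return lon, lat, depth, t


@dataclass
class IceParams:
    """Ice-covered classification rule: concentration >= threshold."""

    threshold: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def classify_origin(traj: TrajectoryEnsemble, ice: IceSeries,
                    params: IceParams | None = None):
    """Label each surfaced particle ice-covered/ice-free by the sea-ice
    concentration at its surfacing position and date (inclusive 15%
    threshold); return the labels and the percentage of surfaced
    particles of ice-covered origin."""
    if params is None:
        params = IceParams()
    mask = traj.surfaced
    if not mask.any():
        raise ValueError("no surfaced particles to classify")
    origin = np.full(traj.n_particles, "none", dtype=object)
    conc = ice.concentration_at(traj.surf_lon[mask], traj.surf_lat[mask],
                                traj.surf_time[mask])
    origin[mask] = np.where(conc >= params.threshold, "ice-covered",
                            "ice-free")
    traj.origin = origin
    pct = 100.0 * float((origin[mask] == "ice-covered").sum()) / mask.sum()
    return origin, pct


def catchment_radius(traj: TrajectoryEnsemble) -> tuple[float, float]:
    """Median and sd (km) of the great-circle distance between the
    release position and the surfacing position, over surfaced
    particles."""
    mask = traj.surfaced
    if not mask.any():
        raise ValueError("no surfaced particles")
    r = haversine_km(traj.release_lon, traj.release_lat,
                     traj.surf_lon[mask], traj.surf_lat[mask])
    return float(np.median(r)), float(np.std(r))


def trajectory_length(traj: TrajectoryEnsemble) -> tuple[float, float]:
    """Median and sd (km) of the horizontal path length summed over
    consecutive stored positions, over surfaced particles."""
    mask = traj.surfaced
    if not mask.any():
        raise ValueError("no surfaced particles")
    lengths = []
    for i in np.flatnonzero(mask):
        p = traj.positions[i]
        p = p[np.isfinite(p[:, 0])]
        if p.shape[0] < 2:
            lengths.append(0.0)
            continue
        seg = haversine_km(p[:-1, 0], p[:-1, 1], p[1:, 0], p[1:, 1])
        lengths.append(float(seg.sum()))
    lengths = np.asarray(lengths)
    return float(np.median(lengths)), float(np.std(lengths))


@dataclass
class BinSpec:
    """Grid used for particle-density binning."""

    depth_bin_m: float = 25.0
    horizontal_bin_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.depth_bin_m <= 0 or self.horizontal_bin_deg <= 0:
            raise ValueError("bin sizes must be positive")


def bin_density(traj: TrajectoryEnsemble, bins: BinSpec | None = None):
    """Fraction of particles per (depth, lat, lon) bin.

    Each particle distributes unit weight uniformly over its stored
    positions, so the array sums to 1 and a stationary particle puts
    all its weight in one bin.

    Returns ``(density, (depth_edges, lat_edges, lon_edges))``.
    """
    if bins is None:
        bins = BinSpec()
    pts = []
    weights = []
    for i in range(traj.n_particles):
        p = traj.positions[i]
        p = p[np.isfinite(p[:, 0])]
        if p.shape[0] == 0:
            continue
        pts.append(p)
        weights.append(np.full(p.shape[0], 1.0 / p.shape[0]))
    if not pts:
        raise ValueError("no stored positions to bin")
    pts = np.vstack(pts)
    weights = np.concatenate(weights) / len(weights)

    def edges(vals, width):
        lo = np.floor(vals.min() / width) * width
        hi = np.ceil(vals.max() / width) * width + width
        return np.arange(lo, hi + width / 2, width)

    e_depth = edges(pts[:, 2], bins.depth_bin_m)
    e_lat = edges(pts[:, 1], bins.horizontal_bin_deg)
    e_lon = edges(pts[:, 0], bins.horizontal_bin_deg)
    density, _ = np.histogramdd(pts[:, [2, 1, 0]],
                                bins=(e_depth, e_lat, e_lon),
                                weights=weights)
    return density, (e_depth, e_lat, e_lon)


def count_ice_days(ice: IceSeries, lon: float, lat: float,
                   window: tuple[float, float],
                   threshold: float = 0.15) -> int:
    """Number of time slices inside ``window`` with concentration at the
    nearest grid cell at or above the threshold."""
    if not (ice.lon[0] <= lon <= ice.lon[-1]
            and ice.lat[0] <= lat <= ice.lat[-1]):
        raise ValueError("point outside the ice grid")
    tmask = (ice.time >= window[0]) & (ice.time <= window[1])
    iy = int(np.abs(ice.lat - lat).argmin())
    ix = int(np.abs(ice.lon - lon).argmin())
    conc = ice.ds["iceconc"].transpose("time", "lat", "lon").values[
        tmask, iy, ix]
    return int((conc >= threshold).sum())


def distance_to_ice_edge(ice: IceSeries, lon: float, lat: float,
                         date: float, threshold: float = 0.15) -> float:
    """Great-circle distance (km) from a point to the sea-ice edge.

    The edge is the set of cells at or above the threshold that have a
    4-neighbour below it.  Returns 0 when the point's own cell is an
    edge cell.  Raises ``LookupError`` when no cell reaches the
    threshold (fully ice-free field).
    """
    it = int(np.abs(ice.time - date).argmin())
    conc = ice.ds["iceconc"].transpose("time", "lat", "lon").values[it]
    icy = conc >= threshold
    if not icy.any():
        raise LookupError("no ice anywhere at this date: edge undefined")
    # 4-neighbour erosion: edge cells are icy cells touching open water
    open_nb = np.zeros_like(icy)
    open_nb[:-1, :] |= ~icy[1:, :]
    open_nb[1:, :] |= ~icy[:-1, :]
    open_nb[:, :-1] |= ~icy[:, 1:]
    open_nb[:, 1:] |= ~icy[:, :-1]
    edge = icy & open_nb
    if not edge.any():
        # ice everywhere: treat the whole boundary of the grid as edge
        edge = icy.copy()
        edge[1:-1, 1:-1] = False
    iy = int(np.abs(ice.lat - lat).argmin())
    ix = int(np.abs(ice.lon - lon).argmin())
    if edge[iy, ix]:
        return 0.0
    yy, xx = np.nonzero(edge)
    d = haversine_km(lon, lat, ice.lon[xx], ice.lat[yy])
    return float(d.min())
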