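"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the study setting: two adjacent regions of a
polar strait — an ice-covered western side with a southward current and
a seasonally ice-free eastern side with a northward current — an
exponential decline of POC flux with distance to the ice edge,
free-living (FL) source communities layered by depth whose
particle-associated (PA) counterparts are known mixtures of those
sources plus an unknown component, planted depth-enriched ASVs with
specified log2 fold changes, and sediment communities seeded with a
known fraction of the PA-enriched pool.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .asv import AsvTable
from .particle_flux import AggregateRecord
from .transport import VelocityField, IceSeries

LAYERS = ("surface", "epi", "meso", "bathy")


@dataclass
class DomainConfig:
    """Grid extents of the synthetic ocean (degrees, m, days)."""

    lon_min: float = -10.0
    lon_max: float = 10.0
    lon_step: float = 0.5
    lat_min: float = 76.0
    lat_max: float = 82.0
    lat_step: float = 0.25
    depth_max: float = 2500.0
    depth_step: float = 125.0
    t_min: float = 0.0
    t_max: float = 365.0
    t_step: float = 5.0

    def axes(self):
        lon = np.arange(self.lon_min, self.lon_max + 1e-9, self.lon_step)
        lat = np.arange(self.lat_min, self.lat_max + 1e-9, self.lat_step)
        depth = np.arange(0.0, self.depth_max + 1e-9, self.depth_step)
        time = np.arange(self.t_min, self.t_max + 1e-9, self.t_step)
        for name, ax in (("lon", lon), ("lat", lat), ("depth", depth),
                         ("time", time)):
            if ax.size < 2 or not np.all(np.diff(ax) > 0):
                raise ValueError(f"domain axis '{name}' must be strictly "
                                 "monotonic with at least 2 points")
        return lon, lat, depth, time


@dataclass
class FluxModelConfig:
    """Generating exponential flux-distance model (with log-noise)."""

    a: float = 13.6              # mg m^-2 d^-1 at the ice edge
    b: float = -0.015            # 1/km
    noise_sigma_log: float = 0.3

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("flux at zero distance must be positive")


def default_mixing_matrix() -> pd.DataFrame:
    """Ground-truth mixing of FL sources into PA sinks per layer.

    Upper-layer particles derive overwhelmingly from surface and
    epipelagic FL communities; deep particles keep a surface imprint but
    carry a large unknown component (growth of taxa rare in any FL
    source)."""
    gamma = pd.DataFrame(
        [[0.80, 0.05, 0.00, 0.00, 0.15],
         [0.45, 0.40, 0.00, 0.00, 0.15],
         [0.15, 0.10, 0.02, 0.00, 0.73],
         [0.12, 0.08, 0.02, 0.08, 0.70]],
        index=list(LAYERS), columns=list(LAYERS) + ["Unknown"])
    return gamma


@dataclass
class CommunityConfig:
    """Amplicon community generator settings.

    Baseline profiles follow a lognormal abundance spectrum (heavy tail,
    as amplicon data show) with a per-layer lognormal tilt; samples are
    Dirichlet-perturbed around their profile and read counts drawn
    multinomially.  Read depths span 5000-30000 so rarefaction to 5000
    is always feasible.
    """

    n_asvs: int = 600
    reads_min: int = 5000
    reads_max: int = 30000
    dirichlet_concentration: float = 5000.0
    layer_tilt_sigma: float = 2.0
    region_tilt_sigma: float = 0.3
    stations: dict = field(default_factory=lambda: {
        "ice-covered": ["EG1", "EG4", "N4"],
        "ice-free": ["HG1", "HG4", "S3"],
    })
    mixing_matrix: pd.DataFrame = field(default_factory=default_mixing_matrix)
    n_planted: int = 24
    planted_lfc: float = 1.5     # log2 fold change between adjacent layers
    planted_base_abundance: float = 2.5e-4
    sediment_seed_fraction: float = 0.15
    n_sediment_per_region: int = 3

    def __post_init__(self) -> None:
        rows = self.mixing_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("mixing matrix rows must each sum to 1")
        if not np.isfinite(self.planted_lfc):
            raise ValueError("planted log2 fold change must be finite")


@dataclass
class AggregateConfig:
    """Region contrasts for marine-snow aggregates.

    Ice-covered aggregates (diatom) are larger and faster-sinking than
    ice-free (Phaeocystis) ones; defaults mirror the flow-chamber
    contrast of the study region (mean ESD 0.9 vs 0.6 mm, sinking
    velocity ~53 vs ~30 m/d, n = 36 vs 24).
    """

    esd_mean_mm: dict = field(default_factory=lambda: {
        "ice-covered": 0.9, "ice-free": 0.6})
    esd_sigma_log: float = 0.45
    velocity_mean_m_d: dict = field(default_factory=lambda: {
        "ice-covered": 52.8, "ice-free": 29.5})
    velocity_sigma_log: float = 0.15
    velocity_size_exponent: float = 0.8
    n_per_region: dict = field(default_factory=lambda: {
        "ice-covered": 36, "ice-free": 24})
    axis_sigma_log: float = 0.2
    taxon: dict = field(default_factory=lambda: {
        "ice-covered": "diatoms", "ice-free": "Phaeocystis"})

    def __post_init__(self) -> None:
        if min(self.esd_mean_mm.values()) <= 0 \
                or min(self.velocity_mean_m_d.values()) <= 0:
            raise ValueError("region means must be positive")


@dataclass
class SyntheticConfig:
    """Master configuration; a fixed seed makes all outputs identical."""

    seed: int = 7
    domain: DomainConfig = field(default_factory=DomainConfig)
    current_speed_east: float = 0.10    # m/s, northward (eastern side)
    current_speed_west: float = 0.10    # m/s, southward (western side)
    ice_edge_lon0: float = -1.0         # degrees
    ice_edge_drift: float = 0.0         # degrees/day (eastward positive)
    ice_ramp_deg: float = 1.5
    eddy_amplitude: float = 0.0         # m/s solid-body perturbation
    flux_model: FluxModelConfig = field(default_factory=FluxModelConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    aggregates: AggregateConfig = field(default_factory=AggregateConfig)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ------------------------------------------------------------------ fields

def make_velocity_field(cfg: SyntheticConfig) -> tuple[VelocityField,
                                                       IceSeries]:
    """Analytic two-jet velocity field plus a sea-ice series.

    Meridional flow is northward over the eastern half of the domain
    and southward over the western half (tanh shear across the centre),
    with an optional solid-body eddy perturbation.  Incompressibility is
    not enforced: the field only drives particle advection.  Ice
    concentration is >= 0.8 west of a (possibly drifting) edge longitude
    and 0 east of it, with a smooth ramp of width ``ice_ramp_deg``.
    """
    lon, lat, depth, time = cfg.domain.axes()
    mid = 0.5 * (lon[0] + lon[-1]) + 1e-6   # keep grid points off the centre
    shear_width = 1.0
    shape = np.abs(np.tanh((lon - mid) / shear_width))
    v_profile = np.where(lon >= mid, cfg.current_speed_east * shape,
                         -cfg.current_speed_west * shape)

    nt, nz, ny, nx = time.size, depth.size, lat.size, lon.size
    v = np.broadcast_to(v_profile, (nt, nz, ny, nx)).copy()
    u = np.zeros((nt, nz, ny, nx))
    w = np.zeros((nt, nz, ny, nx))

    if cfg.eddy_amplitude != 0.0:
        lon_c, lat_c, r_deg = mid, 0.5 * (lat[0] + lat[-1]), 2.0
        dx = (lon[None, :] - lon_c) / r_deg
        dy = (lat[:, None] - lat_c) / r_deg
        r = np.sqrt(dx ** 2 + dy ** 2)
        damp = np.exp(-r ** 2)
        u_eddy = -cfg.eddy_amplitude * dy * damp
        v_eddy = cfg.eddy_amplitude * dx * damp
        u += u_eddy[None, None, :, :]
        v += v_eddy[None, None, :, :]

    vel = xr.Dataset(
        {"u": (("time", "depth", "lat", "lon"), u),
         "v": (("time", "depth", "lat", "lon"), v),
         "w": (("time", "depth", "lat", "lon"), w)},
        coords={"time": time, "depth": depth, "lat": lat, "lon": lon},
        attrs={"units": "m s-1", "depth_positive": "down",
               "w_positive": "up"})

    ice_time = np.arange(cfg.domain.t_min, cfg.domain.t_max + 0.5, 1.0)
    edge = cfg.ice_edge_lon0 + cfg.ice_edge_drift * ice_time
    x = (edge[:, None] - lon[None, :]) / cfg.ice_ramp_deg
    s = np.clip(x, 0.0, 1.0)
    conc2d = 0.9 * s * s * (3.0 - 2.0 * s)          # smoothstep ramp
    conc = np.broadcast_to(conc2d[:, None, :],
                           (ice_time.size, lat.size, lon.size)).copy()
    ice = xr.Dataset(
        {"iceconc": (("time", "lat", "lon"), conc)},
        coords={"time": ice_time, "lat": lat, "lon": lon},
        attrs={"units": "fraction"})
    return VelocityField(vel), IceSeries(ice)


def make_uniform_field(u: float = 0.0, v: float = 0.0, w: float = 0.0,
                       domain: DomainConfig | None = None) -> VelocityField:
    """Spatially and temporally uniform velocity field (test geometry)."""
    dom = domain or DomainConfig()
    lon, lat, depth, time = dom.axes()
    shape = (time.size, depth.size, lat.size, lon.size)
    ds = xr.Dataset(
        {"u": (("time", "depth", "lat", "lon"), np.full(shape, float(u))),
         "v": (("time", "depth", "lat", "lon"), np.full(shape, float(v))),
         "w": (("time", "depth", "lat", "lon"), np.full(shape, float(w)))},
        coords={"time": time, "depth": depth, "lat": lat, "lon": lon})
    return VelocityField(ds)


# ------------------------------------------------------------------- flux

def make_flux_series(cfg: SyntheticConfig, n: int,
                     seed: int | None = None) -> pd.DataFrame:
    """(distance, POC flux) pairs from the exponential generating model.

    Distances are uniform on [0, 90] km; fluxes are
    ``a * exp(b * x) * exp(eps)`` with eps ~ N(0, noise_sigma_log^2),
    hence strictly positive with E[log flux] linear in distance.
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    fm = cfg.flux_model
    rng = np.random.default_rng(seed) if seed is not None else cfg.rng(11)
    x = rng.uniform(0.0, 90.0, size=n)
    eps = rng.normal(0.0, fm.noise_sigma_log, size=n) \
        if fm.noise_sigma_log > 0 else np.zeros(n)
    flux = fm.a * np.exp(fm.b * x) * np.exp(eps)
    return pd.DataFrame({"distance_km": x, "poc_flux": flux})


# -------------------------------------------------------------- community

@dataclass
class CommunityGroundTruth:
    """What the community generator actually planted."""

    mixing_matrix: pd.DataFrame          # PA layer x (FL sources + Unknown)
    planted_asvs: pd.DataFrame           # asv id, lfc, base abundance
    sediment_seed_fraction: float
    layer_profiles: pd.DataFrame         # ASV x layer FL profiles
    pa_profiles: pd.DataFrame            # ASV x layer PA sink profiles

    def write_json(self, path) -> None:
        payload = {
            "mixing_matrix": self.mixing_matrix.round(6).to_dict(),
            "planted_asvs": self.planted_asvs.to_dict(orient="list"),
            "sediment_seed_fraction": self.sediment_seed_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _lognormal_profile(rng: np.random.Generator, n: int,
                       sigma: float = 1.0) -> np.ndarray:
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return x / x.sum()


def make_community_suite(cfg: SyntheticConfig) -> tuple[AsvTable,
                                                        CommunityGroundTruth]:
    """FL + PA + sediment samples with known mixing and planted effects.

    FL source profiles per layer share a common lognormal abundance
    backbone with a per-layer lognormal tilt.  Each PA sink profile is
    the configured mixture of the FL sources plus an Unknown profile;
    the planted ASVs are then overridden to relative abundance
    ``base * 2^(lfc * layer_index)`` (non-planted mass rescaled), so the
    expected relative-abundance ratio between consecutive layers equals
    exactly ``2^lfc``.  Sediment samples draw a fraction rho of reads
    from the planted pool and the rest from a disjoint background.
    Every sample is a multinomial draw over a Dirichlet-perturbed
    profile.
    """
    cc = cfg.community
    T = cc.n_asvs
    rng = cfg.rng(21)
    asv_ids = [f"asv{i:04d}" for i in range(T)]

    backbone = rng.lognormal(0.0, 1.0, size=T)
    fl_profiles = {}
    for layer in LAYERS:
        tilt = rng.lognormal(0.0, cc.layer_tilt_sigma, size=T)
        p = backbone * tilt
        fl_profiles[layer] = p / p.sum()
    unknown_raw = backbone * rng.lognormal(0.0, cc.layer_tilt_sigma, size=T)
    unknown_profile = unknown_raw / unknown_raw.sum()

    # planted depth-enriched ASVs, disjoint from the sediment background
    planted_idx = rng.choice(T, size=cc.n_planted, replace=False)
    planted = pd.DataFrame({
        "asv": [asv_ids[i] for i in planted_idx],
        "lfc": cc.planted_lfc,
        "base_abundance": cc.planted_base_abundance,
    })

    gamma = cc.mixing_matrix
    pa_profiles = {}
    for li, layer in enumerate(LAYERS):
        mix = np.zeros(T)
        for src in LAYERS:
            mix += gamma.loc[layer, src] * fl_profiles[src]
        mix += gamma.loc[layer, "Unknown"] * unknown_profile
        target = cc.planted_base_abundance * 2.0 ** (cc.planted_lfc * li)
        planted_mass = target * cc.n_planted
        if planted_mass >= 0.5:
            raise ValueError("planted abundances too large; reduce lfc, "
                             "count or base abundance")
        prof = mix.copy()
        prof[planted_idx] = 0.0
        prof *= (1.0 - planted_mass) / prof.sum()
        prof[planted_idx] = target
        pa_profiles[layer] = prof

    # sediment: rho from the planted pool (weighted as in the deepest PA
    # layer), 1-rho from a background disjoint from the planted set
    background = backbone * rng.lognormal(0.0, cc.layer_tilt_sigma, size=T)
    background[planted_idx] = 0.0
    background /= background.sum()
    rho = cc.sediment_seed_fraction if cc.n_planted > 0 else 0.0
    if cc.n_planted > 0:
        pool = np.zeros(T)
        pool[planted_idx] = pa_profiles["bathy"][planted_idx]
        pool /= pool.sum()
        sediment_profile = rho * pool + (1.0 - rho) * background
    else:
        sediment_profile = background

    def draw_sample(profile: np.ndarray) -> np.ndarray:
        n_reads = int(rng.integers(cc.reads_min, cc.reads_max + 1))
        alpha = cc.dirichlet_concentration * np.clip(profile, 1e-12, None)
        p = rng.dirichlet(alpha)
        return rng.multinomial(n_reads, p)

    rows, meta = [], []
    for region, stations in cc.stations.items():
        region_tilt = rng.lognormal(0.0, cc.region_tilt_sigma, size=T)
        for station in stations:
            for layer in LAYERS:
                for fraction, profiles in (("FL", fl_profiles),
                                           ("PA", pa_profiles)):
                    prof = profiles[layer].copy()
                    if layer in ("surface", "epi"):
                        prof = prof * region_tilt
                        prof /= prof.sum()
                    rows.append(draw_sample(prof))
                    meta.append((f"{station}_{layer}_{fraction}", fraction,
                                 layer, region, station))
        for k in range(cc.n_sediment_per_region):
            station = stations[k % len(stations)]
            rows.append(draw_sample(sediment_profile))
            meta.append((f"{station}_sediment_{k}", "sediment", "sediment",
                         region, station))

    counts = pd.DataFrame(np.asarray(rows, dtype=int),
                          index=[m[0] for m in meta], columns=asv_ids)
    counts.index.name = "sample"
    metadata = pd.DataFrame(
        [m[1:] for m in meta], index=counts.index,
        columns=["fraction", "layer", "region", "station"])
    n_families = max(8, T // 25)
    taxonomy = pd.DataFrame({
        "family": [f"family{i % n_families:02d}" for i in range(T)],
    }, index=pd.Index(asv_ids, name="asv"))

    table = AsvTable(counts, metadata, taxonomy)
    truth = CommunityGroundTruth(
        mixing_matrix=gamma.copy(), planted_asvs=planted,
        sediment_seed_fraction=rho,
        layer_profiles=pd.DataFrame(fl_profiles, index=asv_ids),
        pa_profiles=pd.DataFrame(pa_profiles, index=asv_ids))
    return table, truth


def make_two_group_table(n_per_group: int = 6, depth: int = 10000,
                         n_asvs: int = 300, n_planted: int = 10,
                         lfc: float = 0.0,
                         dirichlet_concentration: float = 5000.0,
                         seed: int = 0) -> tuple[AsvTable, list[str]]:
    """Two-layer table for differential-abundance calibration and power.

    Group B's planted ASVs have expected relative abundance ``2^lfc``
    times group A's (baseline drawn from the mid-abundance range so the
    effect is observable at the given depth); ``lfc=0`` gives a null
    table.  Returns the table and the planted ASV ids.
    """
    rng = np.random.default_rng(seed)
    asv_ids = [f"asv{i:04d}" for i in range(n_asvs)]
    profile = _lognormal_profile(rng, n_asvs, sigma=1.2)
    order = np.argsort(profile)
    mid = order[n_asvs // 2: n_asvs // 2 + 3 * n_planted]
    planted_idx = rng.choice(mid, size=n_planted, replace=False)

    profile_b = profile.copy()
    profile_b[planted_idx] *= 2.0 ** lfc
    profile_b /= profile_b.sum()

    rows, meta = [], []
    for g, prof in (("A", profile), ("B", profile_b)):
        layer = "epi" if g == "A" else "meso"
        for j in range(n_per_group):
            alpha = dirichlet_concentration * np.clip(prof, 1e-12, None)
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(depth, p))
            meta.append((f"{g}{j}", "PA", layer, "ice-free", f"st{g}"))
    counts = pd.DataFrame(np.asarray(rows, dtype=int),
                          index=[m[0] for m in meta], columns=asv_ids)
    counts.index.name = "sample"
    metadata = pd.DataFrame([m[1:] for m in meta], index=counts.index,
                            columns=["fraction", "layer", "region",
                                     "station"])
    return AsvTable(counts, metadata), [asv_ids[i] for i in planted_idx]


# ------------------------------------------------------------- aggregates

def make_aggregates(cfg: SyntheticConfig) -> list[AggregateRecord]:
    """Aggregate records for both regions.

    ESDs are lognormal around the region mean; the three axes are the
    ESD times lognormal shape factors constrained so their geometric
    mean is exactly the drawn ESD.  Sinking velocity scales with size
    (power law) around the region mean.
    """
    ac = cfg.aggregates
    rng = cfg.rng(31)
    records: list[AggregateRecord] = []
    for region in sorted(ac.n_per_region):
        n = ac.n_per_region[region]
        mu_esd = ac.esd_mean_mm[region]
        mu_v = ac.velocity_mean_m_d[region]
        esd = mu_esd * rng.lognormal(-ac.esd_sigma_log ** 2 / 2,
                                     ac.esd_sigma_log, size=n)
        r1 = rng.lognormal(0.0, ac.axis_sigma_log, size=n)
        r2 = rng.lognormal(0.0, ac.axis_sigma_log, size=n)
        x = esd * r1
        y = esd * r2
        z = esd / (r1 * r2)
        v = mu_v * (esd / mu_esd) ** ac.velocity_size_exponent \
            * rng.lognormal(-ac.velocity_sigma_log ** 2 / 2,
                            ac.velocity_sigma_log, size=n)
        for i in range(n):
            records.append(AggregateRecord(
                x=float(x[i]), y=float(y[i]), z=float(z[i]),
                taxon=ac.taxon[region], region=region,
                sinking_velocity=float(v[i])))
    return records


def make_gel_image(esd_mm, pixel_size_um: float = 12.0,
                   shape: tuple[int, int] = (1024, 1024),
                   background: int = 20, foreground: int = 220,
                   noise: float = 3.0, seed: int = 0) -> np.ndarray:
    """Render particles as bright disks on a dark gel background.

    Each particle becomes a disk whose pixel diameter corresponds to its
    ESD at the given pixel size, laid out on a non-overlapping grid.
    Returns an 8-bit grayscale image; an empty ESD list gives a blank
    (background-only) image.
    """
    rng = np.random.default_rng(seed)
    esd_mm = np.asarray(esd_mm, dtype=float)
    if esd_mm.size == 0:
        img = np.clip(background + rng.normal(0.0, noise, size=shape),
                      0, 255)
        return img.astype(np.uint8)
    radii_px = esd_mm * 1000.0 / pixel_size_um / 2.0
    max_r = int(np.ceil(radii_px.max()))
    pitch = max(2 * max_r + 16, 16)
    per_row = max(1, shape[1] // pitch - 1)
    n_rows = int(np.ceil(esd_mm.size / per_row))
    height = max(shape[0], pitch * (n_rows + 1))   # grow to fit if needed
    img = np.clip(background + rng.normal(0.0, noise,
                                          size=(height, shape[1])), 0, 255)
    yy, xx = np.mgrid[0:height, 0:shape[1]]
    for k, r in enumerate(radii_px):
        cy = pitch // 2 + pitch * (k // per_row) + max_r
        cx = pitch // 2 + pitch * (k % per_row) + max_r
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[disk] = foreground
    return img.astype(np.uint8)


def config_to_dict(cfg: SyntheticConfig) -> dict:
    """JSON-safe dump of the configuration (mixing matrix flattened)."""
    d = asdict(cfg)
    d["community"]["mixing_matrix"] = \
        cfg.community.mixing_matrix.round(6).to_dict()
    return d
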