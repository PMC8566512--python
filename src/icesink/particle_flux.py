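"""Biogeochemistry of sinking aggregates and sediment-trap collections.

Covers the measurement chain from individual marine-snow aggregates to
regional export fluxes: ellipsoid geometry and equivalent spherical
diameter (ESD), flow-chamber sinking velocities, moored/drifting trap
fluxes (POC, PON, particle number and volume), molar C:N ratios, the
exponential POC-flux-vs-ice-distance model, Martin-curve power-law
attenuation, nutrient drawdown across the seasonal pycnocline, and gel
trap image particle sizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Atomic masses (g/mol) used for molar C:N
ATOMIC_MASS_C = 12.011
ATOMIC_MASS_N = 14.007

#: Inner diameter (m) of a drifting-trap collection cylinder.
DRIFTING_TRAP_DIAMETER_M = 0.104
#: Cross-section area (m^2) of a drifting-trap cylinder.
DRIFTING_TRAP_AREA_M2 = np.pi * (DRIFTING_TRAP_DIAMETER_M / 2) ** 2
#: Collection area (m^2) of the long-term moored trap.
MOORED_TRAP_AREA_M2 = 0.5


@dataclass
class AggregateRecord:
    """A single aggregate measured in the vertical flow chamber.

    Axes are the three principal axes of the ellipsoid approximation, in
    mm.  ``sinking_velocity`` (m/d) is optional: gel-trap particles have
    sizes only.
    """

    x: float
    y: float
    z: float
    taxon: str = ""
    region: str = ""
    sinking_velocity: float | None = None

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) <= 0:
            raise ValueError(f"aggregate axes must be positive, got "
                             f"({self.x}, {self.y}, {self.z})")

    @property
    def volume(self) -> float:
        """Ellipsoid volume in mm^3."""
        return esd_from_axes(self.x, self.y, self.z)[0]

    @property
    def esd(self) -> float:
        """Equivalent spherical diameter in mm."""
        return esd_from_axes(self.x, self.y, self.z)[1]


@dataclass
class TrapSample:
    """One sediment-trap collection (moored, drifting or gel cylinder)."""

    kind: str                 # "moored" | "drifting" | "gel"
    area_m2: float
    duration_d: float
    poc_mg: float = 0.0
    pon_mg: float = 0.0
    particles: list[AggregateRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0 or self.duration_d <= 0:
            raise ValueError("trap area and duration must be positive")
        if self.poc_mg < 0 or self.pon_mg < 0:
            raise ValueError("trap masses must be non-negative")


@dataclass
class FluxModel:
    """Exponential flux-distance model ``flux = a * exp(b * x)``.

    ``a`` is the flux at zero distance to the ice edge (mg m^-2 d^-1),
    ``b`` the decay coefficient (1/km, negative when flux declines away
    from the ice), ``r2`` the coefficient of determination on the
    original flux scale.
    """

    a: float
    b: float
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("flux at zero distance must be positive")


@dataclass
class GelImageMeta:
    """Calibration of a gel-trap particle photograph.

    ``min_dynamic_range`` guards against thresholding pure sensor noise:
    images whose gray-level range falls below it are treated as blank
    (gel photographs of particles are close to bimodal).
    """

    pixel_size_um: float = 12.0
    threshold_method: str = "otsu"
    min_esd_mm: float = 0.1
    min_dynamic_range: float = 50.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class AttenuationParams:
    """Martin-curve parameters: ``F(z) = F(z0) * (z/z0)^(-b)``."""

    b_att: float = 0.858
    reference_depth_m: float = 100.0

    def __post_init__(self) -> None:
        if self.reference_depth_m <= 0:
            raise ValueError("reference depth must be positive")


def esd_from_axes(x: float, y: float, z: float) -> tuple[float, float]:
    """Ellipsoid volume (mm^3) and equivalent spherical diameter (mm).

    V = (pi/6) x y z; the ESD, the diameter of the equal-volume sphere,
    reduces to the geometric mean of the three axes.
    """
    if min(x, y, z) <= 0:
        raise ValueError("axes must be positive")
    volume = np.pi / 6.0 * x * y * z
    esd = float((x * y * z) ** (1.0 / 3.0))
    return float(volume), esd


def sinking_velocity_from_flow(flows_ml_min: Sequence[float],
                               chamber_area_cm2: float) -> float:
    """Sinking velocity (m/d) from repeated volumetric flow measurements.

    The aggregate is balanced in an upward flow; its sinking velocity is
    the mean volumetric flow rate divided by the chamber cross-section.

    Parameters
    ----------
    flows_ml_min : flow-rate measurements in mL/min.
    chamber_area_cm2 : chamber cross-section in cm^2.
    """
    flows = np.asarray(flows_ml_min, dtype=float)
    if flows.size == 0:
        raise ValueError("at least one flow measurement is required")
    if chamber_area_cm2 <= 0:
        raise ValueError("chamber area must be positive")
    # mL/min over cm^2 -> cm/min -> m/d
    cm_per_min = flows.mean() / chamber_area_cm2
    return float(cm_per_min * 60.0 * 24.0 / 100.0)


def flux_from_trap(sample: TrapSample) -> dict[str, float]:
    """Per-area per-day fluxes from one trap collection.

    Returns POC and PON fluxes (mg m^-2 d^-1), particle number flux
    (# m^-2 d^-1) and particle volume flux (mm^3 m^-2 d^-1); number and
    volume fluxes are zero when the sample carries no particle records.
    """
    denom = sample.area_m2 * sample.duration_d
    volumes = [p.volume for p in sample.particles]
    return {
        "poc_flux": sample.poc_mg / denom,
        "pon_flux": sample.pon_mg / denom,
        "number_flux": len(sample.particles) / denom,
        "volume_flux": float(np.sum(volumes)) / denom if volumes else 0.0,
    }


def molar_cn(poc: float, pon: float) -> float:
    """Molar C:N ratio from POC and PON in the same mass units."""
    if pon <= 0:
        raise ValueError("PON must be positive")
    return (poc / ATOMIC_MASS_C) / (pon / ATOMIC_MASS_N)


def fit_ice_distance_model(distance_km: Sequence[float],
                           flux: Sequence[float]) -> FluxModel:
    """Fit ``flux = a * exp(b * distance)`` by least squares on log flux.

    The exponential is linearised (``ln flux = ln a + b x``) and fitted
    by ordinary least squares; R^2 is then computed on the original flux
    scale, ``1 - SS_res/SS_tot``.
    """
    x = np.asarray(distance_km, dtype=float)
    y = np.asarray(flux, dtype=float)
    if x.size != y.size:
        raise ValueError("distance and flux must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit the model")
    if np.any(y <= 0):
        raise ValueError("fluxes must be strictly positive")
    b, ln_a = np.polyfit(x, np.log(y), 1)
    a = float(np.exp(ln_a))
    pred = a * np.exp(b * x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FluxModel(a=a, b=float(b), r2=r2)


def predict_flux(model: FluxModel, distance_km: float | np.ndarray):
    """Flux predicted by the exponential ice-distance model."""
    x = np.asarray(distance_km, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    out = model.a * np.exp(model.b * x)
    return float(out) if out.ndim == 0 else out


def attenuate_flux(flux_z0: float, z0: float, z: float,
                   params: AttenuationParams | None = None) -> float:
    """Power-law (Martin curve) flux attenuation from depth z0 to z."""
    if params is None:
        params = AttenuationParams()
    if z0 <= 0 or z <= 0:
        raise ValueError("depths must be positive")
    return float(flux_z0 * (z / z0) ** (-params.b_att))


def nutrient_drawdown(depth_m: Sequence[float],
                      concentration: Sequence[float],
                      pycnocline_m: float = 50.0,
                      bottom_m: float = 100.0) -> float:
    """Nutrient consumption across the seasonal pycnocline.

    Delta = mean concentration in [pycnocline, bottom) minus the mean
    above the pycnocline; measurements below ``bottom_m`` are excluded
    from both strata.  A positive value means surface depletion relative
    to the sub-pycnocline reservoir, i.e. consumption.
    """
    d = np.asarray(depth_m, dtype=float)
    c = np.asarray(concentration, dtype=float)
    above = c[d < pycnocline_m]
    below = c[(d >= pycnocline_m) & (d <= bottom_m)]
    if above.size == 0 or below.size == 0:
        raise ValueError("need measurements both above and below the "
                         "pycnocline to compute drawdown")
    return float(below.mean() - above.mean())


def gel_image_particles(image: np.ndarray,
                        meta: GelImageMeta | None = None) -> pd.DataFrame:
    """Size particles in a gel-trap photograph.

    The image is converted to grayscale, the background removed with a
    global threshold (Otsu by default), and connected foreground
    components are measured.  The projected pixel area is calibrated to
    mm^2 and converted to the ESD of the circle with that area,
    ``ESD = 2 sqrt(area/pi)``.  Components below ``min_esd_mm`` are
    treated as noise and dropped.

    Returns a DataFrame with columns ``pixel_area``, ``area_mm2``,
    ``esd_mm`` (one row per particle; empty for a blank image).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    if meta is None:
        meta = GelImageMeta()
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img.astype(float)

    empty = pd.DataFrame(columns=["pixel_area", "area_mm2", "esd_mm"])
    if img.size == 0 or img.max() - img.min() < meta.min_dynamic_range:
        return empty

    if meta.threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(meta.threshold_method)
    mask = img > thr
    if not mask.any():
        return empty

    px_mm = meta.pixel_size_um / 1000.0
    rows = []
    for region in regionprops(label(mask)):
        area_mm2 = region.area * px_mm ** 2
        esd = 2.0 * np.sqrt(area_mm2 / np.pi)
        if esd >= meta.min_esd_mm:
            rows.append((int(region.area), float(area_mm2), float(esd)))
    return pd.DataFrame(rows, columns=["pixel_area", "area_mm2", "esd_mm"])


def size_class_summary(records: Sequence[AggregateRecord],
                       cut_mm: float = 0.512) -> pd.DataFrame:
    """Count aggregates below/above an ESD cut, per region.

    ESD exactly at the cut counts as "above" (inclusive upper class).
    """
    if len(records) == 0:
        raise ValueError("no aggregate records")
    rows = [(r.region, r.esd) for r in records]
    df = pd.DataFrame(rows, columns=["region", "esd"])
    out = df.groupby("region", sort=True)["esd"].agg(
        below=lambda s: int((s < cut_mm).sum()),
        above=lambda s: int((s >= cut_mm).sum()),
    ).reset_index()
    return out
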