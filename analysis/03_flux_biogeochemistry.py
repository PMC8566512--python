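"""Trap fluxes, aggregate characteristics and the flux-distance model.

Fits the exponential POC-flux vs ice-edge-distance model to the
simulated long-term trap series, summarises the regional aggregate
contrast (ESD, sinking velocity, size classes), computes molar C:N from
the drifting-trap fluxes, re-measures the rendered gel-trap image, and
projects the 100 m fluxes to 200 m with the Martin curve.

Run after 01:  python analysis/03_flux_biogeochemistry.py
"""

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from icesink import particle_flux as pf

INPUTS = Path("results/inputs")
OUT = Path("results")

DRIFTING_TRAP_FLUXES = {"ice-covered": (128.0, 17.5),
                        "ice-free": (63.0, 6.5)}   # POC, PON mg/m^2/d


def main() -> None:
    flux = pd.read_csv(INPUTS / "flux_series.tsv", sep="\t")
    model = pf.fit_ice_distance_model(flux["distance_km"],
                                      flux["poc_flux"])
    print(f"flux-distance fit: flux = {model.a:.2f} * "
          f"exp({model.b:.4f} * x), R^2 = {model.r2:.3f} "
          f"(n = {len(flux)})")
    half = np.log(2) / -model.b
    print(f"flux halves every {half:.1f} km from the ice edge")

    agg = pd.read_csv(INPUTS / "aggregates.tsv", sep="\t")
    records = [pf.AggregateRecord(r.x_mm, r.y_mm, r.z_mm, r.taxon,
                                  r.region, r.sinking_velocity_m_d)
               for r in agg.itertuples()]
    sizes = pf.size_class_summary(records, cut_mm=0.512)

    rows = []
    for region, (poc, pon) in sorted(DRIFTING_TRAP_FLUXES.items()):
        sub = agg[agg["region"] == region]
        rows.append({
            "region": region,
            "poc_flux_mg_m2_d": poc,
            "pon_flux_mg_m2_d": pon,
            "molar_cn": round(pf.molar_cn(poc, pon), 1),
            "mean_esd_mm": round(sub["esd_mm"].mean(), 2),
            "mean_sinking_velocity_m_d":
                round(sub["sinking_velocity_m_d"].mean(), 1),
            "poc_flux_at_200m_mg_m2_d":
                round(pf.attenuate_flux(poc, 100.0, 200.0), 1),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "flux_summary.tsv", sep="\t", index=False)
    sizes.to_csv(OUT / "aggregate_size_classes.tsv", sep="\t",
                 index=False)
    pd.DataFrame([{"a_mg_m2_d": round(model.a, 2),
                   "b_per_km": round(model.b, 4),
                   "r2": round(model.r2, 3)}]).to_csv(
        OUT / "flux_distance_model.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(sizes.to_string(index=False))

    image = iio.imread(INPUTS / "gel_ice_covered.png")
    particles = pf.gel_image_particles(image)
    f = {"n": len(particles),
         "mean_esd_mm": particles["esd_mm"].mean()}
    particles.round(4).to_csv(OUT / "gel_particles.tsv", sep="\t",
                              index=False)
    print(f"gel image: {f['n']} particles re-measured, mean ESD "
          f"{f['mean_esd_mm']:.2f} mm")


if __name__ == "__main__":
    main()
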