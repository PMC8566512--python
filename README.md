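# icesink

Sea ice shapes how efficiently the polar ocean exports carbon: aggregates
formed under ice (large, fast-sinking, diatom-dominated) reach the deep sea
faster than aggregates from open water (small, slow, flagellate-dominated),
and they carry surface microbes with them. `icesink` implements the full
computational chain needed to study this link — from physical particle
tracking to amplicon community statistics — as one tested Python package,
exercisable end-to-end on synthetic data with known ground truth.

It is written for biological oceanographers and microbial ecologists who
work with sediment-trap series, Lagrangian particle tracking output, and
16S rRNA ASV tables, and want each step of such an analysis to be a
reusable, testable function rather than a one-off script.

## What it computes

**Transport** (`icesink.transport`). Sinking aggregates sampled at depth
are backtracked to their surface origin by reversing the flow field: at
each 30-minute Euler step the particle moves by −(u, v)·Δt horizontally
and rises by (w_s − w)·Δt (depth positive down, w positive up, w_s the
constant sinking speed in m/d). Surface origins are classified as
ice-covered when the sea-ice concentration at the surfacing position and
date is ≥ 15%. Catchment radius (great-circle distance from release to
surfacing point), horizontal trajectory length, particle-density binning
(25 m × 0.05° bins), ice-day counts and distance to the 15% ice edge
follow.

**Particle flux** (`icesink.particle_flux`). Ellipsoid aggregate volume
V = (π/6)·x·y·z and equivalent spherical diameter ESD = (x·y·z)^(1/3);
flow-chamber sinking velocities; trap fluxes (mass / area / duration);
molar C:N = (POC/12.011)/(PON/14.007); the exponential ice-distance model
F(x) = a·e^(b·x) fitted by OLS on log flux with R² reported on the
original scale; Martin-curve attenuation F(z) = F(z₀)·(z/z₀)^(−b);
nutrient drawdown across the 50 m pycnocline; gel-trap image particle
sizing (Otsu threshold, connected components, ESD = 2√(area/π) at
12 µm/px).

**Source tracking** (`icesink.source_tracking`). Each particle-associated
(PA) community is modelled as a mixture of free-living (FL) source
communities plus an Unknown source. Read assignments are resampled by
collapsed Gibbs with conditional

    P(z_i = v) ∝ (m_tv + n_tv⁻ⁱ + α)/(m_·v + n_·v⁻ⁱ + Tα) · (n_v⁻ⁱ + β)

(m: training counts, zero for Unknown; T: number of ASVs), with burn-in
100, 10 restarts, α = β = 0.001, after rarefaction to 5000 reads — plus
leave-one-out validation of the sources themselves.

**Enrichment** (`icesink.enrichment`). ASVs are tested between
consecutive water layers (surface–epi, epi–meso, meso–bathy) with a
negative-binomial Wald test on median-of-ratios size factors and
method-of-moments dispersion, BH-adjusted per contrast; an ASV is
enriched when |log₂FC| > 1 and padj < 0.1 after a 4% prevalence filter.
The sequence footprint of PA-enriched ASVs is then measured in deep FL
and sediment communities.

**Community statistics** (`icesink.community`). Bias-corrected Chao1,
Shannon diversity (nats), PCA of variance-stabilised counts, paired
FL–PA Euclidean distances with a between-region rank test, and a one-way
PERMANOVA with permutation p-values.

**Synthetic data** (`icesink.synthetic`). Generates every input with
known ground truth: a two-jet velocity field (northward east / southward
west) with a drifting ice edge; flux–distance pairs from
F(x) = 13.6·e^(−0.015·x) with lognormal noise; layered FL communities
whose PA counterparts are known mixtures (γ) plus planted depth-enriched
ASVs; sediment communities seeded with a known fraction ρ of the
PA-enriched pool; aggregate records and rendered gel images.

## Worked example

```python
from icesink import particle_flux as pf, synthetic as syn

cfg = syn.SyntheticConfig(seed=7)
series = syn.make_flux_series(cfg, 200)          # (distance, POC flux)
model = pf.fit_ice_distance_model(series["distance_km"],
                                  series["poc_flux"])
print(f"flux = {model.a:.2f} * exp({model.b:.4f} x), R2 = {model.r2:.3f}")
print(f"molar C:N ice-free trap: {pf.molar_cn(63.0, 6.5):.1f}")
```

prints

```
flux = 14.50 * exp(-0.0157 x), R2 = 0.508
molar C:N ice-free trap: 11.3
```

i.e. the fitted export flux at the ice edge is ~14.5 mg C m⁻² d⁻¹,
falling by half every ~44 km of ice-edge distance (noise keeps a single
200-station realisation near, not at, the generating a = 13.6,
b = −0.015), and the drifting-trap fluxes give a molar C:N of 11.3,
characteristic of more degraded open-water material.

The full demonstration — trajectory summaries per sinking-velocity
scenario, flux tables, mixing proportions per water layer, enriched
families and sediment footprints — runs as numbered steps:

```
python analysis/01_simulate_inputs.py      # inputs + ground truth
python analysis/02_backtrack_trajectories.py
python analysis/03_flux_biogeochemistry.py
python analysis/04_source_tracking.py
python analysis/05_enrichment_footprint.py
python analysis/06_community_stats.py
```

or as one deterministic pipeline (`icesink report --seed 7`, or
`icesink.pipeline.run_pipeline`), writing seed-stamped TSV/JSON tables
under `results/`. A fixed seed reproduces every table byte-for-byte.

## Layout

```
src/icesink/        library (synthetic, transport, particle_flux,
                    source_tracking, enrichment, community, pipeline, cli)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance script
docs/methods.md     model assumptions, parameter choices, limitations
```
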