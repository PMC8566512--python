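# Methods

This note documents the models implemented in `icesink`, the parameter
choices that matter, what the synthetic data do and do not emulate, and
the numerical conventions adopted where the underlying methods leave
room.

## Lagrangian backtracking

Particles are advected with an explicit Euler scheme at a 30-minute
step through a gridded velocity field (regular lon/lat/depth/time axes;
trilinear in space, linear in time via `scipy` regular-grid
interpolation). Backtracking reverses the field: horizontal
displacement per step is −(u, v)·Δt, and with depth positive down and
the model vertical velocity w positive up, the particle rises by
(w_s − w)·Δt, where w_s is a constant sinking speed (m/d) added to the
model's vertical motion. Positions are stored bi-hourly.

Conventions the method itself does not fix:

- **Surface termination** is the top grid level; the integrator records
  the crossing position and time. Travel time is therefore quantised to
  the step, so closed-form checks are satisfied to within one advection
  step.
- **Domain exit** (spatial or temporal) freezes the particle with an
  `exited` status; such particles are excluded from surfacing
  statistics. A surfacing record is kept only inside the configured
  surfacing window (default days 60–212, the productive season).
- **Ice classification is inclusive**: concentration ≥ 0.15 at the
  surfacing position and date (nearest grid cell, nearest daily slice)
  counts as ice-covered. The same threshold defines the ice edge (an
  icy cell with an open-water 4-neighbour) and ice-day counts.
- **Trajectory length** is the horizontal path length over the stored
  bi-hourly positions. For deep stations the horizontal component
  dominates the 3-D path by two orders of magnitude, and the horizontal
  reading makes the uniform-flow identity (length = catchment radius)
  exact; the vertical leg can be reconstructed from the stored depths
  if needed.
- Great-circle distances use the haversine formula on a sphere of
  radius 6371 km; the integrator itself works in a local
  equirectangular metric (metres per degree at the current latitude).
  For long zonal tracks at high latitude the great-circle distance is
  slightly shorter than the integrated displacement — closed-form
  comparisons are made in the integrator's metric.
- An RK-style convergence check is provided implicitly: halving the
  step changes uniform-flow displacements by < 1%, which the tests
  assert.

## Particle and flux biogeochemistry

Aggregate volume assumes an ellipsoid, V = (π/6)·x·y·z, so the ESD
reduces to the geometric mean of the axes. Sinking velocity from the
flow chamber is mean volumetric flow / chamber cross-section. Trap
fluxes divide collected quantity by collection area × duration; the
drifting-trap cylinder area follows from its 10.4 cm inner diameter
(8.49×10⁻³ m²), and deployment duration must be supplied by the user.
Molar C:N uses atomic masses 12.011 and 14.007 g/mol.

The flux–ice-distance model F(x) = a·e^(b·x) is linearised and fitted
by ordinary least squares on ln F; because multiplicative lognormal
noise is additive on the log scale, this estimator is unbiased for
(ln a, b). R² is reported on the original flux scale (1 − SSres/SStot),
the scale on which the quantity is interpreted. Depth attenuation uses
the Martin curve F(z) = F(z₀)·(z/z₀)^(−b) with b = 0.858 by default
(the classical open-ocean composite value), overridable.

Gel-trap images are thresholded with Otsu's method after grayscale
conversion; connected foreground components are sized as
ESD = 2√(area/π) with the calibrated pixel area (default 12 µm/px),
discarding components below 0.1 mm ESD. Images whose gray-level range
is below 50 (8-bit) are treated as blank rather than thresholded, since
a global threshold on pure sensor noise would fabricate particles.

Nutrient drawdown is the mean concentration between 50 and 100 m minus
the mean above 50 m (the seasonal pycnocline); deeper measurements
enter neither stratum.

## Microbial source tracking

The sampler treats each sink read's source assignment as a latent
variable and resamples it by collapsed Gibbs using the conditional
given in the README: known sources are smoothed multinomials over their
training counts augmented by current assignments, and one Unknown
source has no training counts, learning its distribution from the
assignments alone. Defaults follow the standard configuration of
community-level Bayesian source tracking: Dirichlet hyperparameters
α = β = 0.001, burn-in 100 sweeps, 10 restarts with uniformly random
initial assignments, samples rarefied to 5000 reads (multivariate
hypergeometric, i.e. subsampling without replacement; shallower samples
are dropped with a warning). One draw is recorded per restart after
burn-in and proportions are averaged over restarts, with the
between-restart standard deviation reported as the uncertainty. Exact
numerical agreement with any particular external implementation is not
claimed; correctness is established by recovery of planted mixtures.

Free-living samples are pooled into one source per (layer, region)
before fitting. Pooling per layer only is supported but leaves
region-specific community structure unexplained, inflating the Unknown
component — visible directly in the synthetic suite, where upper-layer
communities carry a region effect.

A practical limit shared with all community-level trackers: similar
sources trade mass freely (surface vs epipelagic estimates are
anti-correlated), and sample-level biological variation not present in
the training profiles is absorbed by the Unknown component, typically a
few percent under the synthetic noise model.

## Differential abundance (depth enrichment)

The enrichment test is a deliberately transparent negative-binomial
procedure: median-of-ratios size factors (ASVs with any zero excluded
from the reference; library-size fallback with a warning when none
remain), group abundance estimated from normalized group totals with a
half-read pseudocount, pooled method-of-moments dispersion floored at
10⁻⁸, and a Wald test on the log₂ layer coefficient referred to a
Student-t distribution with n₁+n₂−2 degrees of freedom — the t
reference accounts for the estimated dispersion at the small group
sizes typical of such designs (n = 3–8), where a normal reference is
anti-conservative. p-values are BH-adjusted within each contrast.
Shrinkage estimators, outlier filtering and the like are intentionally
out of scope; instead, calibration is established by simulation: across
100 null Dirichlet-multinomial datasets the raw-p rejection rate at
nominal 0.05 is ~0.06, and planted 4-fold effects at n = 6/group and
10⁴ reads are detected with sensitivity ≥ 0.9 at the default
thresholds (|lfc| > 1, padj < 0.1).

The variance-stabilising transform used for ordination and distances is
the shifted log of size-factor-normalised counts, log₂(K/s + 1) — a
simplification that is monotone, maps zeros to zero, and serves only
the distance-based analyses, not the test.

## Community statistics

Chao1 uses the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)); Shannon
is reported in nats. The double-depth richness statement uses a
Chao1-based asymptotic extrapolation (a simple approximation of
coverage-based rarefaction/extrapolation estimators, adequate for the
qualitative "few additional ASVs" check). PCA is a centred SVD with a
deterministic sign convention (largest-|loading| element positive);
explained variance sums to 100% over all axes. PERMANOVA decomposes
summed squared distances into among/within parts, with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under free label permutation —
no strata are implemented. Permutations that happen to reproduce the
original partition tie with the observed statistic, so even perfectly
separated groups have p slightly above 1/(n_perm+1).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study system, not its
physics:

- **Velocity field**: two opposing meridional jets (northward east,
  southward west of the domain centre, tanh shear, default
  0.05–0.10 m/s) with an optional solid-body eddy. Incompressibility is
  not enforced — the field is only ever consumed by the advection
  scheme. Ice concentration is 0.9 behind a (possibly drifting) edge
  longitude with a smoothstep ramp, zero seaward.
- **Flux series**: distances uniform on 0–90 km, fluxes from
  13.6·e^(−0.015·x) with lognormal noise σ_log = 0.3 (comparable to the
  scatter of multi-year trap series).
- **Communities**: a lognormal abundance backbone with per-layer
  lognormal tilts gives the heavy-tailed ASV spectrum amplicon data
  show; samples are Dirichlet-perturbed (concentration 5000, i.e.
  per-ASV dispersions around 0.1 at 10⁻³ relative abundance) and read
  depths are uniform on 5000–30000 so rarefaction to 5000 always
  succeeds. PA sink profiles are exact mixtures (γ) of the FL layer
  profiles plus an Unknown profile; planted ASVs are overridden to
  relative abundance base·2^(lfc·layer), making the expected
  between-layer ratio exactly 2^lfc; sediment draws fraction ρ of reads
  from the planted pool (default 0.15) and the rest from a disjoint
  background. The default γ gives upper-layer PA communities ~85%
  shallow FL origin and deep PA communities ~70% Unknown with a
  persistent shallow imprint, echoing the field pattern.
- **Aggregates**: lognormal ESDs around region means of 0.9 mm
  (ice-covered) and 0.6 mm (ice-free) with sinking velocities scaling
  as a power of size around 53 and 30 m/d, n = 36 and 24 — the observed
  two-fold contrasts. Gel images render the drawn ESDs as
  non-overlapping disks at 12 µm/px.

Not emulated: mesoscale turbulence and realistic shear, seasonality of
production, sequence-level (FASTQ) errors and chimeras, phylogenetic
structure among ASVs, taxonomy beyond arbitrary family labels, and
spatial autocorrelation between stations. Passing tests therefore show
that the estimators recover known structure under realistic noise
levels — not that field data meet these assumptions.

## Problem sizes and determinism

The demonstration pipeline uses 25 release dates × 3 velocity
scenarios × 2 stations, a 600-ASV suite with 54 samples (24 FL, 24 PA,
6 sediment over 6 stations), 999 PERMANOVA permutations and the full
source-tracking configuration; one run takes well under a minute on a
single CPU, and a fixed seed makes every output table byte-identical
across runs (each table carries the seed and a configuration hash in a
header comment). All random streams derive from explicit seeds; the
Gibbs sampler's inner loop is numba-compiled with per-restart seeding.

## Known limitations

- Euler integration is first-order; the step-halving test bounds the
  error for the smooth synthetic fields but strongly sheared real
  fields would warrant a higher-order scheme.
- The NB test's method-of-moments dispersion is per-ASV and unshrunk;
  at very small n it trades some power against simplicity.
- The source tracker reports restart variability, not full posterior
  uncertainty, and inherits the usual identifiability limits between
  similar sources.
- `distance_to_ice_edge` measures to edge-cell centres, so its
  resolution is the ice grid spacing.
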