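# Methods

This note records the statistical model, the simulation reconstruction, the
synthetic-data design, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Variable construction

Child weight categories follow the age/sex-specific BMI-percentile
convention: obese at or above the 95th percentile, overweight from the 85th
up to the 95th, underweight below the 5th (CDC convention for the lower
cut), healthy otherwise. Lower bounds are closed — the published bands do
not state boundary handling, so `classify_bmi_percentile(95) == "obese"` by
this package's convention.

Prevalence is normalized per 1000 children (`1000·count/total`), kept at
full precision internally and rounded to the nearest integer only at report
time. One published worked value (overweight 79 of 702 → printed 112, while
nearest-integer rounding gives 113) is inconsistent with this rule; the
discrepancy is documented here rather than resolved, and the package keeps
nearest-integer rounding, which reproduces all other printed values
(27/212 → 127, 108/702 → 154).

Walkshed exposure counts children whose straight-line distance to the
nearest amenity is within 800 m (each child once, however many buffers
overlap), per-1000 normalized. Straight-line distance is a deliberate
simplification: network-based walksheds require a road network that is out
of scope. Walkability bands use the public Walkscore cut-points 50/70.

Adult education and immigrant counts are normalized by the total *child*
population — the study's stated convention, followed verbatim even though
the numerators describe adults.

Row exclusion: neighbourhoods with fewer than `min_children` (default 8,
the minimum of the published included range) or any missing required value
are dropped with a logged reason. Underweight children stay in the totals
but never enter a response variable.

## GWR engine

Estimation is weighted least squares per site:
`β̂(u_i,v_i) = (XᵀW_iX)⁻¹XᵀW_iY` with an intercept always included.

- **Kernel.** Adaptive bisquare by default: radius = distance to the
  bandwidth-th nearest neighbour, the regression point counting as its own
  first neighbour (inclusive convention — the published "local sample 50" is
  read as this bandwidth). A uniform weight function is provided because the
  all-ones limit must reproduce global OLS exactly, which is the engine's
  main internal consistency check. Fixed-distance kernels are supported.
- **Distances.** Euclidean on projected planar coordinates (metres). No CRS
  handling: the package requires projected input and says so in metadata.
- **Standard errors.** Sandwich `(XᵀWX)⁻¹XᵀW²X(XᵀWX)⁻¹` scaled by a global
  residual variance `σ̂² = RSS/(n − tr S)` where `tr S` is the hat-matrix
  trace (effective number of parameters). A global σ̂² stabilizes small-kernel
  local variance estimates.
- **Inference.** t values are classed two-sided at 90/95/99% against the
  standard normal by default; a Student-t reference with `n − tr S` degrees
  of freedom is available (`significance_reference="t"`). The published
  analysis states the classes but not the reference distribution.
- **Local R².** Kernel-weighted `1 − RSS_w/TSS_w`, clipped to [0, 1] against
  floating-point excursions.
- **Bandwidth selection.** Corrected AIC,
  `AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)` with
  `σ̂ = √(RSS/n)`; candidates with `tr S ≥ n − 2` are skipped; ties break
  toward the larger (smoother) bandwidth for determinism.
- **Degenerate cases.** A zero-variance response defines R² = 0 (avoids
  0/0). A covariate that is constant *inside a kernel* is flagged
  unestimable (NaN) at that site with a warning; the run continues. Global
  rank deficiency is rejected up front with the offending columns named.
  Duplicate coordinates that collapse the kernel radius are rejected with
  guidance to jitter.

Local multicollinearity tests are deliberately absent (their reliability is
contested in the GWR literature); `correlation_diagnostics` provides the
global-level advisory check only.

## Stock-flow reconstruction

The original simulation was specified in a proprietary tool whose equations
were not published; the package reconstructs it from the described
structure using the standard system-dynamics primitive, and this
reconstruction is a modelling assumption of this package:

- Three stocks per neighbourhood; two flows (obese↔overweight from the
  obesity model, overweight↔healthy from the overweight model); adjacent
  transitions only, so healthy↔obese transfer is identically zero.
- A scenario's walkscore change `Δ` (applied at the start year, clamped so
  walkscore stays in [0, 100]) sets fixed goal stocks
  `goal = stock₀ + β̂_ws·Δ·total/1000`, clamped at zero — a one-shot
  intervention, not re-derived each step.
- Each flow is first-order goal-seeking, `gap/τ` per year with τ = 1 (the
  stated intervention-and-adjustment granularity), integrated by explicit
  Euler with dt = 1 year by default (smaller dt available; halving dt moves
  end-year stocks by well under 1% on the test cases).
- **Backup bookkeeping.** The overweight↔healthy flow measures its gap on
  the overweight stock *net of the cumulative inflow received from the
  obese stock* (tracked in the state as `backup_in`). Without this, children
  displaced from the obese stock would immediately drain onward to healthy,
  which contradicts the described dynamics: the overweight→healthy flow
  stays small because the overweight model's walkscore coefficients are
  small, and the displaced children persist as a backup of overweight
  children. Whether the overweight-model goal should instead apply to the
  healthy stock is undecidable from the description; applying it to the
  overweight stock is the assumption made here.
- Flows are clamped so no stock goes negative within a step (clamping is
  logged); stocks are continuous, integers appear only in reports.
- Coefficients below any significance level still drive flows at face value
  by default (the described flows are small-but-nonzero); an optional
  `significance_gate` zeroes them.

Conservation (healthy + overweight + obese constant per neighbourhood) holds
exactly up to floating point because both flows are internal transfers.

## Targeting

A neighbourhood is targeted when all active rules pass: local walkscore
coefficient negative, significant at ≥ 95% (configurable floor), normalized
obese prevalence above the city mean, and walkscore below the city median
or in the car-dependent band. The published analysis describes but does not
print its thresholds; above-mean prevalence and below-median-or-car-dependent
walkability are this package's operationalizations, each overridable or
disableable. Loosening any single rule can only grow the selected set.

## Feedback loop

`feedback_rerun` renormalizes end-year obese (and overweight) counts with
the same per-1000 expression used in preprocessing, adds the scenario's Δ to
walkscore, and re-fits GWR with the *baseline* kernel spec — the bandwidth
is reused, not re-selected, so before/after local fits are like-for-like.
Under the base scenario the loop is exactly neutral: stocks, responses and
fits reproduce the baseline bit-for-bit, which the suite asserts. An
optional second pass re-fits the overweight model on post-intervention
overweight counts (off by default; the backup influx makes its response
scenario-dependent).

## Synthetic city

The generator emulates the statistical structure the analysis assumes; it
is a study-condition definition, not a fitted model of any real city.

- **Geometry.** 174 centroids on a jittered grid over a 25 km × 25 km
  projected plane (the real city's area is of this order); optional
  child/amenity point clouds. Administrative polygons are not reproduced.
- **Covariates.** Truncated normals per covariate with min/max/mean/sd
  matched to the published city-wide table (only those moments are
  printed). Fast-food and park exposures are instead *computed* from the
  generated point clouds with the same 800 m walkshed operation the
  preprocessing module exposes: 110 fast-food outlets uniform over the
  plane, a local park near 85% of centroids plus 60 city-wide extras —
  chosen once for realism (dense park access, patchier fast-food access).
- **Prevalence.** True per-1000 rates are
  `intercept + Σ_k surface_k(u,v)·x_k + N(0, noise_sd²)`, clamped to
  [0, 1000] with a logged warning. Default surfaces: constant coefficients
  at the published mean local values for six covariates, and a walkscore
  effect with base −0.05 plus a Gaussian bump of amplitude −1.5 centred in
  the northeast quadrant. The bump radius is 8 km: the 50-neighbour kernel
  averages over roughly 7.6 km, and a surface meant to represent a
  recoverable regional cluster must vary on a scale above the kernel's
  smoothing radius — a bump at or below that scale is attenuated toward
  unidentifiability at the study bandwidth. Intercept 130 puts mean obesity
  prevalence near the published 92 per-1000; default noise_sd is 20 per-1000
  (recovery checks use 10, their stated condition).
- **Counts.** Category counts are multinomial in the implied probabilities
  (underweight ≈ 4.7%, the published share, so the exclusion rule is
  exercised). A deterministic expected-count mode rounds `rate·total/1000`;
  in that mode the table's normalized columns carry the exact unrounded
  construction so that noiseless data admit an *exact* OLS recovery oracle —
  with rounded counts the oracle would hold only approximately.
- **Reproducibility.** One `numpy` Generator seeded from the config; same
  config + seed ⇒ byte-identical output.

What passing tests on this generator do **not** show: robustness to
irregular administrative geographies, spatially autocorrelated covariates
(the generator draws them independently per site), network rather than
straight-line walksheds, or measurement error in clinical BMI records. The
generator exposes the surface specs and all calibration constants so harder
conditions can be configured.

## Problem sizes

The default test and acceptance runs use the full 174-neighbourhood panel
for every study-scale check, 40–60-neighbourhood cities for I/O and loop
fixtures, and 100 random instances for the weighted/unweighted equivalence
sweep. These sizes are the package's standard verification conditions.

## Known limitations

- Significance classes ignore multiple testing across 174 local fits, as in
  the original analysis.
- The stock-flow equations are a reconstruction (see above); only their
  qualitative behaviour (equilibrium, dose ordering, backup influx,
  conservation) is anchored to the described results.
- Exposure via straight-line walksheds overstates access where street
  networks are sparse.
- The GeoJSON layer exports attributes and geometry only; no cartographic
  styling.
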