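# Methods

This note documents the statistical procedures implemented in
`elevshift`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model and standardization

Occurrence records carry site, species, calendar year, elevation (m),
individual count (≥ 1, populations are *detected* populations), a
habitat-preference category (one of six: forest, generalist, grassland,
semi-natural, subalpine, wetland) and an optional protection flag.
Records are assigned to a *historical* or *current* period by a
configurable boundary year (default 2003, i.e. 1990–2003 vs 2004–2017
within the default 1990–2017 study window).

Elevation is standardized **within species** to mean 0 and sample SD 1
(divisor n − 1) so elevational positions are comparable across species:
the most negative values are a species' rear (low, warm) edge.
Standardization is computed on the records entering each model, not once
globally; species with fewer than two distinct elevations cannot be
standardized and are excluded from models requiring it (with a warning).
Applying the transform twice is a no-op (location/scale invariance),
which the test suite checks.

## Range shifts

* **Density estimation.** Gaussian kernels, bandwidth
  h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a 512-point grid
  spanning the data range ± 3h and renormalized to integrate to 1
  (trapezoid rule). Bandwidth and grid are free choices; this rule is
  the classical rule of thumb for unimodal data.
* **Edges and optimum.** The rear and leading edges are the 5%/95%
  *sample* quantiles (linear interpolation), not quantiles integrated
  from the KDE: sample quantiles are deterministic, oracle-testable and
  asymptotically equivalent for the sample sizes the ≥ 30-record filter
  guarantees; the two versions differ by a fraction of a bandwidth in
  practice. The optimum is the grid elevation of the maximal density;
  exact ties are broken to the lowest elevation and logged. The optimum
  is the noisiest of the three positions — its sampling error scales
  with the KDE bandwidth (order 50–100 m for σ ≈ 300 m samples), so
  per-species optimum shifts carry much more variance than edge shifts.
* **Shift rates.** (current − historical) per position, divided by the
  period length (14 yr); positive = upslope. Rates are classified
  against the climate-tracking band (default 3.8–5.5 m yr⁻¹): below =
  lagging, inside = tracking, above = exceeding; a CI-aware variant
  requires the interval to lie wholly outside the band.
* **Decile comparison.** For q = 0.1 … 0.9 the Harrell–Davis estimator
  (Beta-weighted sum of order statistics) is applied to both periods;
  each period's sample is independently resampled B times (default
  2000), the CI is the (α/2, 1−α/2) percentile interval of the
  bootstrapped differences and p = 2·min(p̂, 1−p̂) with
  p̂ = (#{d* > 0} + ½#{d* = 0})/B. A decile is significant when the CI
  excludes 0. Simulation tests verify per-decile non-coverage of 0
  within 0.05 ± 0.03 under the null and ≥ 90% coverage of a true
  +70 m shift at n = 500.
* **Distribution screen.** Two-sample K–S per species,
  Benjamini–Hochberg step-up across species (checked exactly against a
  hand-coded step-up oracle).
* **Habitat models.** Gaussian linear model of annual rate on habitat
  category per position; the overall test is the OLS F-test (reported
  also as χ² = F·df), with Tukey HSD pairwise contrasts and a compact
  letter display. Categories with a single species stay in the fit but
  are flagged as unstable. Degenerate inputs (all group means equal)
  are reported as χ² = 0, p = 1 rather than a 0/0 F ratio.
* **Resurvey cross-check.** For species with ≥ 10 records in the
  initial survey *and* among surviving populations, edges/optimum are
  re-estimated from the two resurvey snapshots, converted to annual
  rates by the species' mean elapsed years, and Pearson-correlated with
  the full-data-set rates per position; with < 3 qualifying species the
  correlation is reported as undefined.

## Population trends

Per habitat category, a Poisson GLMM with log link:
count ~ time + z + z² + time·z, random intercepts for species and for
observation (OLRE) crossed. Time is calendar year centred on the study
midpoint (2003.5 by default), in years — the centring is a numerical
choice; only the intercept depends on it. The quadratic term encodes the
expected hump-shaped abundance profile (maximum at a thermal/habitat
optimum); a positive time × elevation coefficient with a negative time
coefficient produces the steeper-decline-at-the-rear-edge pattern.

### GLMM estimation

No installed Python package provides frequentist GLMMs with crossed
species + observation-level random intercepts, so the Laplace fitter is
implemented in `elevshift.glmm`:

* Given variance parameters, the fixed effects and random-effect modes
  are found jointly by penalized IRLS; because the species design is an
  indicator matrix and the OLRE design the identity, the OLRE block is
  eliminated in closed form (effective weights w̃ = w/(1 + σ²_olre·w))
  and each iteration solves a dense (p + S) system. Tolerance 1e-8 on
  the penalized deviance, at most 200 iterations.
* The Laplace-approximate deviance
  −2[log f(y|û) − ½û'D⁻¹û − ½log det(D·H)] is minimized over the
  variance parameters (σ ≥ 0, bounded quasi-Newton); σ = 0 is reached
  exactly and treated as dropping that random term, so in the
  zero-variance limit the fit coincides with the plain GLM (verified to
  1e-4 relative error). This profiles β inside PIRLS (the fast variant
  of the Laplace scheme); the test suite cross-checks one 4800-record
  fit against lme4's `glmer`, which agrees to a few percent on every
  coefficient and variance.
* Standard errors come from the fixed-effect block of the inverse joint
  penalized information (conditional on the estimated variances, as
  mixed-model software conventionally reports). Per-term tests are Wald
  χ² (= (coef/SE)² for single-df terms; quadratic forms for
  multi-coefficient terms); a likelihood-ratio option (`use_lrt`) refits
  without each term.
* Binomial fits flag complete separation (degenerate outcomes or
  runaway coefficients); variance estimates at the boundary are flagged
  as singular rather than fatal.

Simulation tests show each generating slope recovered within 2 SE in
≥ 90% of 50 replicates (12 species × 400 observations) and per-term
type-I error within 0.05 ± 0.03 over 200 smaller replicates (8 species
× 80 observations — sizes chosen to keep the default test run fast
while leaving enough information per term).

**Detection conditioning.** Occurrence records represent detected
populations (count ≥ 1), but the model is plain Poisson — the same
mismatch the original survey design implies. The induced bias is
negligible when mean counts are well above 1 and grows as the expected
count approaches 1 (it flattens the fitted quadratic); the
coefficient-recovery simulations therefore use an abundant-population
scenario, and the packaged default scenario (mean counts ≈ e²) accepts
a small conservative bias at the range margins.

## Resurvey survival

Filtering rules (order-independent, counts ledgered per rule):
phenology (|Δday-of-year| > 30), rarity (< 5 initial records per
species), elapsed (< 5 years between surveys). The survival model is a
binomial GLMM: survival ~ elapsed years + log(initial size) +
standardized elevation + habitat alteration + habitat preference, with
species random intercept. log is the natural log (sizes ≥ 1, no offset
needed); habitat preference enters with forest (alphabetically first)
as reference. Both the full model and a backward-reduced model
(iteratively dropping the highest-p term with p > 0.10; main effects
are protected while an interaction containing them remains; a threshold
≥ 1 strips every unprotected term) are always reported. Collinearity is
screened with VIFs — generalized VIFs per term
(det R₁₁·det R₂₂/det R, with the 1/(2·df) power for comparability) so
the categorical term is handled correctly; rank-deficient designs raise
an error naming the aliased columns. Habitat alteration is separately
modelled against raw elevation with a plain binomial GLM.

## Thermal niche

Realized thermal niche breadth = 95% − 5% quantile of per-record MAT
per species (≥ 10 records), using the *same* quantile routine as the
range edges. Per-occurrence-record quantiles are used (rather than
quantiles over a study-area raster): the records define the realized
niche. The geostatistical temperature surface of a real study is out of
scope; a declared elevation-lapse-rate surrogate
(MAT = t₀ − 6.5 °C km⁻¹·elevation + noise) generates per-record MAT for
testing, and real values can be supplied via `temperatures.csv`. The
ecological-indicator lookup shipped for the demonstration pipeline is
synthetic (`synthetic_landolt_table`), constructed so subalpine species
are the coldest-adapted, semi-natural grassland species the most
thermophilic, wetland species the only wet-soil group and forest
species the only shade-tolerant group.

## Synthetic-data generator

The generator produces data with exactly the structure the estimators
assume:

* **Elevational distributions**: truncated normal per species
  (optionally skew-normal via a shape parameter), bounds 66–2970 m by
  default; the current period's centre is displaced by `shift_m` within
  the same absolute bounds. Years are uniform within each period.
* **Counts**: zero-truncated Poisson draws from the abundance model
  above (zero counts are redrawn — the simplest detected-population
  mechanism; see the detection-conditioning note).
* **Resurveys**: stratified site selection over the four major habitat
  strata (167/53/198/45 of 463 sites), alteration Bernoulli
  (default 37%, optionally logit-linear in elevation — the slope
  defaults to 0 because no functional form is established), elapsed
  years normal (mean 20.5, SD 8.4) and survival Bernoulli from the
  logit model with a species random intercept. The default alteration
  effect is sized so the average marginal reduction in survival
  probability is ≈ 17 points.
* **Default study scenario**: 44 species in the category counts
  11 forest / 9 generalist / 6 grassland / 9 semi-natural / 5 subalpine
  / 4 wetland, with 250–900 records per species per period for the
  common groups and 60–260 for the record-poor semi-natural and wetland
  groups. Per-category 14-year shift defaults (with ±12 m per-species
  jitter) encode the qualitative pattern the analysis should recover:
  forest ≈ 0, generalist +40 m, grassland +85 m (exceeding the
  3.8–5.5 m yr⁻¹ band), semi-natural −45 m (downslope), subalpine
  +60 m and wetland +65 m (tracking) — which makes well over half the
  species lag behind warming. Per-category abundance coefficients give
  declining populations in forest/generalist/grassland/subalpine,
  stable semi-natural and wetland, and a weak hump for wetland.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real data: spatial autocorrelation and
geographic sampling structure (elevation is the only spatial axis),
observer effects and detectability variation, colonization beyond
historical leading edges, temporal autocorrelation within sites, and
any mechanistic link between a species' occurrence-distribution shift
and its resurvey survival pattern. The last point means the resurvey
cross-check correlations are ≈ 0 on synthetic data by construction
(in a real data set, true shifts drive both estimates); the cross-check
operation itself is verified with constructed perfect- and
independent-correlation cases.

## Reproducibility and numerical conventions

All randomness flows from one root seed through named per-stage
substreams (`SeedSequence(root, spawn_key=(stage,))`); identical seeds
give byte-identical outputs (CSV floats are written with a fixed
format; the run manifest contains no timestamps). Bootstrap and
simulation sizes in the default test run are scaled (B = 500–600,
150–300 replicates) as the package's own balance between test
sharpness and turnaround. Degenerate inputs — zero-variance species,
empty alteration classes, all-identical outcomes, rank-deficient
designs, infeasible truncation bounds — are either flagged in the
returned fit or raised with a message naming the offender, never
silently dropped; species excluded by record-count filters are listed
in structured exclusion tables.

## Known limitations

* The Laplace/PIRLS variant used here (β profiled with the random
  effects) can differ from higher-order Laplace or quadrature fits by a
  few tenths of a standard error in small samples; OLRE-Poisson models
  are themselves known to be slightly biased when the OLRE variance is
  large.
* KDE-based optima are bandwidth-limited; with multimodal species the
  "highest peak" can jump between modes of near-equal height (ties are
  logged).
* Sample quantiles vs KDE-integrated quantiles for the range edges
  differ at O(bandwidth/n) — immaterial at n ≥ 30 but a convention to
  keep in mind when comparing against other software.
* The backward-deletion procedure inherits the usual caveats of
  stepwise selection; both full and reduced fits are always reported.
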