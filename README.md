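# elevshift

Statistical pipeline for quantifying **local extinction, population-size
trends and elevational range shifts** of species from georeferenced
occurrence records collected in two survey periods — the situation of a
regional mountain flora (the motivating case is an Alpine orchid data
set) monitored over ~three decades, where each site is visited once and
the question is how populations and elevational ranges responded to
warming and land-use change.

It is written for quantitative ecologists who have:

* an **occurrence table** (site, species, year, elevation, individual
  count, habitat-preference category),
* optionally a **resurvey table** of historically recorded populations
  revisited once (initial/second visit dates, initial size, survival,
  habitat-alteration flag), and
* optionally per-record **mean annual temperature** values.

A seeded synthetic-data generator reproduces the statistical structure
all stages assume, so the entire pipeline is testable — and demonstrable
— without any field data.

## What it computes

**Range shifts.** Records are split into a historical and a current
period (default 1990–2003 vs 2004–2017). For each species with ≥ 30
records in both periods, a Gaussian-kernel density of occurrence
elevation is estimated per period; the *rear edge* and *leading edge*
are the 5% and 95% quantiles and the *optimum* the highest density peak.
Annual shift rates are (current − historical)/14 yr, positive = upslope,
and are classified against the regional climate-tracking band of
3.8–5.5 m yr⁻¹ (lagging / tracking / exceeding). Decile-wise change is
tested with the **Harrell–Davis quantile estimator**

  θ̂_q = Σᵢ wᵢ x₍ᵢ₎,  wᵢ = I_{i/n}(a,b) − I_{(i−1)/n}(a,b),
  a = (n+1)q, b = (n+1)(1−q),

compared between periods with a percentile bootstrap (CI and p per
decile), plus a two-sample Kolmogorov–Smirnov screen with
Benjamini–Hochberg correction across species, and Gaussian linear models
of shift rate ~ habitat category with Tukey HSD contrasts.

**Population trends.** Per habitat category, a Poisson GLMM (log link)

  count ~ time + z + z² + time·z + (1 | species) + (1 | observation)

where z is elevation standardized to mean 0 / SD 1 within species and
the observation-level random effect (OLRE) absorbs extra-Poisson
variation. Estimation is by Laplace approximation (hand-written fitter,
cross-checked against lme4 in the test suite); per-term Wald χ² and p
are reported.

**Resurvey survival.** After filtering (≤ 30-day phenology mismatch,
≥ 5 initial records per species, ≥ 5 years between visits), a binomial
GLMM of survival on elapsed time, log initial size, standardized
elevation, habitat alteration and habitat preference with a species
random intercept — plus VIF collinearity diagnostics, an
alteration ~ elevation GLM, and backward deletion of terms with
p > 0.10.

**Thermal niche.** Realized niche breadth per species = 95% − 5%
quantile of MAT over its records; per-category medians of ecological
indicator values.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
packaged 44-species synthetic scenario and write tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_range_shifts.py
```

prints (seed 1):

```
simulated study scenario (seed 1): {'occurrences': 38382, 'resurvey': 463, 'temperatures': 38382}
analyzed 44 species (0 excluded)
64% of species lag behind the (3.8, 5.5) m/yr warming band at the optimum
```

i.e. all 44 species pass the 30-records-per-period filter, and at the
distribution optimum two-thirds of species shift upslope more slowly
than regional warming requires. `analysis/04_survival.py` then fits the
survival model on the 463 simulated resurvey sites:

```
records kept after filtering: 459
           term  chisq  df     p
   time_elapsed  2.622   1 0.105
       log_size 31.581   1 0.000
  elevation_std 16.228   1 0.000
habitat_altered 15.716   1 0.000
   habitat_pref  5.061   3 0.167
```

— survival is driven by initial population size, elevational position
(rear-edge populations die more often) and habitat alteration, not by
elapsed time or habitat preference, matching the structure the generator
encodes.

The same pipeline runs from the command line
(`elevshift simulate|range-shift|trends|survival|niche|run-all`); the
`run-all` subcommand writes every stage table plus a `manifest.json`
that makes runs byte-for-byte reproducible given a seed.

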