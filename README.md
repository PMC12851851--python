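# kelpcohorts

Cohort demography of giant kelp (*Macrocystis pyrifera*) from long-term
quadrat censuses: algal community states, recruitment-pulse cohort detection,
Kaplan–Meier survivorship, and additive models of cohort size and longevity.

## Who this is for

Kelp-forest ecologists running (or reanalyzing) permanent-transect monitoring
programs in which laminarian life stages and turf covers are censused
quarterly in fixed quadrats, individual adult plants are mapped at
recruitment and followed until death, and bottom temperature and a wave
hindcast provide the disturbance context.  The package turns those long-format
tables into the standard demographic products of such a program, and ships an
individual-based simulator that generates every input table with known ground
truth, so the whole pipeline is testable without field data.

## What it computes

**Algal states.** Each quadrat-census is reduced to nine scaled canopy-guild
features (adults, stipes, juveniles + pre-adults, stipitate and laminate
kelps, brown/red turf, articulated corallines, *Desmarestia*) and clustered
with CLARA k-medoids under Manhattan distance; the gap statistic guides the
number of clusters, and the five-state solution is labeled Kelp / Disturbed /
Recovery / Mixed / Understory.  Site timelines of state fractions feed a
persistent state-shift detector.

**Cohorts.** Adult-recruitment dates at a site are partitioned into *cohort
windows*: maximal runs separated by at least one year (pulses typically span
under 18 months; longer windows are flagged).  A cohort is *pulsed* when at
least 80% of its plants recruited within the first year of the window and it
is at least one year distinct from its neighbors — otherwise *trickled* — and
*blended* when survivors of an earlier cohort are still alive at its onset.
Each cohort gets a parameter vector: N, singles, pre-adults and juveniles in
the year before onset, previously existing adults (spore provisioning),
understory, mean lifespan, mean per-plant maximum stipe count, Kaplan–Meier
survival quantiles, and 80th-percentile temperature and wave-energy
covariates over its lifetime.

**Survivorship.** Product-limit estimation with right-censoring,

    S(t) = prod_{t_i <= t} (1 - d_i / n_i),

with quantiles q(p) = smallest event time with S(t) <= 1 − p.  Interval-
censored deaths on the quarterly grid are resolved to the midpoint between
the last sighting and the first missed census (configurable).

**Wave forcing.** Weekly maximum significant wave height H_s with coincident
period, converted to deep-water energy density E = ρ g H_s² / 16 (J m⁻²).

**Models.** `CohortSizeModel` and `CohortLongevityModel` are negative-binomial
additive models (penalized B-spline smooths, GCV-selected penalties, decade
as a parametric factor with the 2000s as reference); `factor_model` gives a
varimax-rotated maximum-likelihood factor analysis of the cohort parameters;
`trend_tests` runs the linear model of cohort size over time and the logistic
model of trickled-vs-pulsed recruitment over time.

## Worked example

Simulate one site for 25 years, detect its cohorts, and fit survivorship:

```python
from kelpcohorts.simulate import SimulationConfig, simulate_forcing, simulate_site
from kelpcohorts.cohorts import detect_cohort_windows, assign_plants, classify_pulse
from kelpcohorts.core_data import add_lifespans
from kelpcohorts.survival import km_fit, km_quantile

cfg = SimulationConfig(seed=7, n_sites=1, years=25)
census, plants, truth = simulate_site(cfg, 0, forcing=simulate_forcing(cfg))

windows = detect_cohort_windows([p.recruit_date for p in plants], "S01")
rosters, _ = assign_plants(windows, plants)
lt = add_lifespans(plants)
curve = km_fit(lt["duration"], lt["event"])
[km_quantile(curve, p) for p in (0.25, 0.5, 0.75, 0.95)]
```

prints 669 plants in 7 cohorts, e.g.

```
S01-1: 1983.25-1983.75  N=92   pulsed
S01-2: 1987.50-1989.50  N=151  trickled
S01-3: 1992.25-1993.50  N=114  trickled
pooled KM quantiles (25/50/75/95%): [0.375, 0.625, 1.625, 3.875]
```

— a strong post-disturbance pulse in 1983 followed by more gradual cohorts,
with a quarter of plants gone within ~4–5 months of adult recruitment and 5%
surviving past ~3.9 years.  Fitting the cohort-size model on a simulated
150-cohort table:

```python
from kelpcohorts.modeling import CohortSizeModel
from kelpcohorts.simulate import simulate_cohort_table

fit = CohortSizeModel.from_frame(simulate_cohort_table(150, seed=7)).fit()
print(fit.summary())
```

```
Parametric coefficients
==============================================================
                Estimate       SE       z           p
(Intercept)        3.069    0.152   20.21     7.4e-91
decade1980        -0.014    0.123   -0.11        0.91
decade1990         0.011    0.107    0.10        0.92
decade2010         0.082    0.109    0.76        0.45
decade2020         0.032    0.156    0.20        0.84
Significance of smooth terms
                   edf      chi2           p
s(Adults)         1.01      5.19       0.023
s(Understory)     1.03    158.49     2.6e-36
R-sq(adj) = 0.472; deviance explained = 56.15%
```

Cohort size rises with the number of previously existing adults and falls
with understory cover — the planted generative effects.  `fit.plot_smooths()`
draws the partial smooths; `curve.plot()` draws the survivorship step curve.

The same stages are available from the shell:

```bash
kelpcohorts simulate --seed 7 --n-sites 2 --years 25 --out-dir runs/demo
kelpcohorts cohorts-detect runs/demo/plants.csv --out runs/demo/cohorts.csv
kelpcohorts survival-fit runs/demo/plants.csv --out-dir runs/demo
kelpcohorts run-all --config config.yaml --out-dir runs/full
```

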