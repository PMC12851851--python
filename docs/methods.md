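# Methods

This note documents the models, conventions, and numerical choices behind
`kelpcohorts`, and what the synthetic-data generator does and does not
emulate.

## Data model and time conventions

All time is decimal years; censuses sit on a quarterly grid (.00/.25/.50/.75).
ISO dates are converted as `year + (day_of_year - 1)/365.25`.  A census row is
one quadrat (5 × 2 m) at one date with laminarian life-stage counts
(juveniles: <1 m and <2 stipes; pre-adults: past the primary dichotomy and
>1 m; adults: ≥4 stipes), total stipe counts, fractional turf covers in
[0, 1], and sea urchin densities.  A plant record spans adult recruitment
(first census with ≥4 stipes) to death or right-censoring, with the full
stipe series.

**Death-time convention.** A death is observed only as an interval between
the last sighting and the first missed census.  The default resolves it to
the interval midpoint, which is unbiased when deaths are uniform within the
quarter; `last-seen` and `first-missed` are available for sensitivity.  The
choice shifts every lifespan by at most ±0.125 yr and is applied uniformly,
so survivorship comparisons between groups are unaffected.

## Environment preprocessing

Temperature (nominal 3-h cadence) is regridded; gaps up to one month are
linearly interpolated, longer gaps are left missing and reported.  The
seasonal climatology is the across-year mean per day-of-year.  It is smoothed
with a *circular Savitzky–Golay* (local quadratic) filter of width 31 d
rather than a flat moving mean: a 31-d boxcar attenuates the annual harmonic
by ~1.2%, which leaks the seasonal cycle into the anomalies, while the
quadratic-preserving weights keep that error below 0.1%.  The climatology is
evaluated by circular interpolation between day-bin centers, avoiding a
daily staircase in the anomalies.  Detrending requires ≥2 full years; note
that an anomaly present in 1 of Y years is absorbed into the climatology at
rate 1/Y, so transient events are recovered at (1 − 1/Y) of their amplitude.

Waves are decimated to the weekly maximum H_s and its coincident period
(ties resolve to the earliest observation), then converted to deep-water
energy density E = ρ g H_s²/16 with ρ = 1025 kg m⁻³, g = 9.81 m s⁻².  The
period does not enter E; an energy-flux form ρ g² H_s² T/(64π) (W m⁻¹) is
available behind `formula="flux"` for sensitivity work, without any claim of
equivalence.  All windowed covariates use the linear-interpolation (type-7)
empirical quantile over observations with t0 ≤ t < t1.

## Algal states

Nine guild features per quadrat-census; juveniles pool all pre-adult life
stages, and *Cystoseira* is pooled into brown turf (it grows turf-like most
of the year) while remaining a separate census column.  Scaling is a
per-feature z-score over all quadrat-censuses pooled across sites and times,
with the sample (n−1) standard deviation; range scaling to [0, 1] is a
config alternative.  Zero-variance features scale to 0 with a warning.

Clustering is CLARA k-medoids under Manhattan distance: PAM (greedy BUILD
plus best-improvement SWAP, the swap search vectorized over candidates) run
on subsamples of size 40 + 2k, with 5 subsamples, each subsequent subsample
seeded with the incumbent medoids, and the medoid set scored on the *full*
data.  PAM's swap neighborhood can stall in local optima on adversarial
instances, so small instances (n ≤ 20) add 12 random-restart initializations
(2 otherwise); in testing this reaches the exhaustive-search optimum on all
instances with n ≤ 14.  The gap statistic uses W_k = total Manhattan distance
to medoids, a uniform reference over per-feature ranges, and the standard
one-standard-error rule; the pipeline default is nonetheless k = 5 with the
gap value reported, reflecting that a mixed kelp/understory state is
ecologically meaningful even when the gap curve prefers fewer clusters.

Labeling of the five-cluster solution is rule-based on the medoids, in
priority order: Kelp = largest adult+stipe score; Recovery = largest juvenile
score among the rest; Disturbed = largest *Desmarestia* score; of the final
two, the larger pooled understory score is Understory and the remainder
Mixed.  Exact score ties between distinct medoids break toward the less
kelp-like medoid; identical medoids are an error.  These rules reproduce the
orderings that distinguish the five canonical states but are a construction
of this package — with other data the medoids should be inspected.

State timelines are quadrat fractions per site-date (missing quadrats leave
the denominator).  A site is "in" a state when that state holds the maximum
fraction and at least the dominance threshold (default 0.4); a run counts as
established when it spans at least the persistence window (default 1 yr,
duration inclusive of one census interval), and shift events are emitted
between consecutive established states.  Both thresholds are config-exposed
since no field standard exists.

## Cohorts

Windows split recruitment dates at every gap ≥ 1 yr; a span ≥ 1.5 yr flags
the window `extended` rather than splitting it (the 18-month pulse length is
typical, not absolute).  Isolated recruits form singleton windows — small
cohorts are kept and can be labeled "small cohort" downstream.  The pulsed
rule is inclusive: exactly 80% in the first year qualifies.  Blending needs
just one survivor from any earlier cohort at onset.

"Within one year of cohort onset" for pre-adults, juveniles, prior adults,
and understory is resolved as the year *before* onset, since these condition
adult recruitment; a config switch allows centered or following windows.
Lifetime covariates (temperature and wave-energy 80th percentiles, urchin
means) span [onset, onset + t95] with t95 the cohort's Kaplan–Meier 95%
quantile (maximum observed duration if undefined; at least one quarter).
The covariate quantile level is configurable for sensitivity sweeps.

Mortality attribution is an explicit rule-based stand-in for a field-note
judgment, evaluated over the terminal phase (50% → 95% cumulative
mortality): heat if the 80th-percentile temperature exceeds 18 °C (above the
seasonal envelope; configurable), waves if any weekly energy exceeds
6800 J m⁻², urchins above 2.5 m⁻² (purple) or 0.25 m⁻² (red), "small cohort"
below N = 5; two or more firing rules join as e.g. "heat/waves", none gives
"not known".  Amphipod infestation cannot be detected from these inputs and
is never auto-assigned.

## Survivorship

The product-limit estimator is computed via lifelines; events precede
censorings at tied times.  Quantiles use q(p) = smallest *event time* with
S(t) ≤ 1 − p, applied uniformly (so a curve that plateaus exactly at 1 − p
returns the time it first reaches the plateau); quantiles the curve never
reaches are NaN, not errors.  Plants alive at the series end are
right-censored, and cohorts with any censored member are flagged `alive` and
excluded from the additive models rather than deleted.

## Modeling

**Factor analysis** standardizes the cohort parameters, fits a
maximum-likelihood factor model (scikit-learn's EM implementation), applies
a hand-written varimax rotation, and computes Thomson regression scores
Ẑ R⁻¹ Λ.  Factors are sign-fixed (largest loading positive) and ordered by
variance share Σλ²/p.  The default input is the numeric cohort-parameter
columns; the selection is config-exposed because reasonable analysts differ
on whether covariates belong in the factor space.

**Screening** uses a random-forest regression with permutation importance
evaluated on a held-out 30% split — in-sample permutation importance is
systematically positive even for pure-noise predictors because the forest
overfits its training data.

**Additive models** use penalized B-splines (statsmodels GLMGam) with a
negative-binomial family.  The NB dispersion is a method-of-moments estimate
(Var = μ + αμ², α clipped to [0.01, 10]) from a Poisson warm start.  Penalty
weights are selected by a GCV criterion n·D/(n − edf)² on a log-spaced grid:
one shared sweep, then one per-term refinement pass.  This shrinks smooths
toward linearity (edf → ~1) but, unlike a double-penalty scheme, cannot
remove a term entirely — the unpenalized linear component always remains, a
known limitation.  Basis dimension is 10 per smooth, capped on small data
sets; smooth-term significance is a Wald test on the spline coefficients.
Cohort longevity is mean lifespan rounded to integer days so the count
family applies; a continuous check model is available via
`response_scale="years"`.  Decade enters as a parametric factor with the
2000s as reference.  No multiple-testing correction is applied across terms.

**Trend tests** are OLS of N on onset date (slope, F, p) and a logistic
regression of trickled(1)/pulsed(0) on onset date; a single-class response
flags the logistic model degenerate instead of failing.

## Synthetic data

The generator emulates the sampling design of a multi-decade monitoring
program — 20 sites at 8–21 m depth, 4 transects × 10 quadrats, quarterly
censuses over 1983–2023 — driven by one shared forcing pair: 3-h temperature
(seasonal sinusoid, AR(1) noise with ~10-d decorrelation, flat-topped warm
anomalies for the scheduled El Niño / heat-wave events) and daily waves
(seasonal Weibull H_s plus scheduled storms, the 1988-scale event largest).

Site dynamics are individual-based at quadrat resolution, so census counts
and plant tables are mutually consistent by construction.  Juveniles recruit
when light (canopy) and space (understory, grazing) allow; pre-adults mature
into adults only while the *stand* is open — a site-level canopy gate with
hysteresis (self-shading closes the stand above 18% of canopy capacity;
recruitment reopens below 6%).  The hysteresis is what produces discrete
recruitment pulses after mass mortality and gradual trickles when thinning
reopens the stand slowly, with defaults chosen to give field-realistic
structure: a cohort every ~3–5 years per site, pulsed recruitment slightly
dominant, pooled survival quantiles of order 0.1/0.6/1.4/3.9 yr and maxima
near a decade, and ~10³ plants per site over 40 years.  Adult mortality is
discrete-time survival per census step (hazard h₀·exp(β_T·anomaly +
β_W·1[storm] + β_U·urchins), plus a first-year self-thinning excess, scaled
by depth), which keeps the Kaplan–Meier estimator exact on the generated
data.  Understory encroaches logistically when the canopy is low and is
knocked back by storms; *Desmarestia* blooms briefly after disturbance;
stipe counts follow a saturating-growth-then-senescence trajectory toward a
plant-specific lognormal maximum.

Three regimes: `disturbance` (mechanistic, cohorts emergent), `planted`
(explicit pulse windows with known spacing and span; every quarter inside a
window produces recruits, so window recovery is exactly decidable — the
ground-truth regime), and `trickled` (continuous low-rate recruitment).
`simulate_cohort_table` separately draws cohort-parameter tables from the
additive models' own generative form (including a rise-plateau-decline wave
response with breakpoints at 4000 and 6800 J m⁻²) for effect-recovery
checks.

**What passing tests do and do not show.** The generator has no spatial
correlation between sites beyond shared forcing, no dispersal or spore
limitation, no observation error in counts, and hazards that follow the
fitted models' functional form.  Recovery of planted effects therefore
demonstrates the estimators' correctness, not their robustness to
model misspecification in field data.

## Verification problem sizes

The acceptance script runs the exhaustive product-limit check over all 510
event/censor patterns with n ≤ 8; 100 planted-pulse sites (5 pulses,
spacing ≥ 1.25 yr, span ≤ 1 yr) for cohort recovery; 60 instances with
n ≤ 14 against exhaustive k-medoids search plus 20 seeded three-cluster gap
runs; 50 seeded 150-cohort tables for longevity-effect sign recovery; 1000
shuffled-null replicates for trend-test type-I error; and one full 20-site ×
40-year synthetic run summarized end to end.
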