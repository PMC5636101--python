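# Methods

This note documents the models, conventions and numerical choices behind the
pipeline, and what the synthetic-data tests do and do not demonstrate.

## Study design assumed by the pipeline

GPS collars record one fix every 15 minutes over a 24-hour intensive
sampling period starting at local noon, once per week: up to 96 fixes and 95
travel segments per period. Coordinates are planar meters in a projected,
locally distance-preserving CRS; at the ≤150 m buffer scales analyzed here
planar Euclidean distance is used throughout and no geodesy is performed.
Timestamps are stored UTC; a configurable `utc_offset_hours` maps them to
local clock time for day/night and sampling-period assignment.

## Behavioral states

Each inter-fix interval at the nominal cadence is assigned exactly one of
two mutually exclusive states. The primary rule is displacement ≥ 70 m →
active; the cutoff is the step length predicted at 10% accelerometer
activity by an OLS regression of step length on activity fraction
(`calibrate_cutoff`). Both boundary cases (exactly 70 m, exactly 10%)
classify as active; the conventions are configurable
(`StudyConfig.distance_cutoff_m`, `activity_cutoff`). Segments spanning
missing fixes are gaps: they produce no interval and break the Markov chain,
as do the weekly boundaries between sampling periods. No imputation is
performed.

## Transition tables and log-linear models

Consecutive intervals of one animal form a transition record (B = preceding
state, A = succeeding state) with covariates read at the junction fix — the
GPS acquisition between the two intervals: H (distance to nearest house
≤ 150 m, closed disk), T (day/night), S (sex), L (habitat). Records are
cross-classified into contingency tables.

Hierarchical log-linear models specified by generating classes (e.g.
`(BA, BHT)`: A depends only on B; house/time structure is a nuisance margin)
are fitted by iterative proportional fitting. Numerics: fit initialized
uniform; sweeps adjust one generating-class margin at a time; convergence
when every margin matches the observed margin within 1e-10 (max 1,000
sweeps, failure raises). Cells with zero observed count contribute nothing
to G². Residual degrees of freedom are cells minus parameters, where the
parameter count enumerates every interaction subset contained in at least
one generating class (inclusion–exclusion over the subset lattice), each
worth ∏(levels−1).

Model comparison uses `aic_rel = G² − 2·df`. Since AIC = deviance + 2·(number
of parameters) up to a constant shared by all models on one table, pairwise
`aic_rel` differences equal AIC differences; the saturated model sits at 0.
Candidate lattice (per study group): `(BA,BHT)`, `(BAH,BHT)`, `(BAT,BHT)`,
`(BAT,BAH,BHT)`, `(BAHT)`. Pairs within ΔAIC < 0.2 are flagged
statistically indistinguishable. Likelihood-ratio tests report
ΔG² = G²(nested) − G²(wider) against the chi-square upper tail on
Δdf = df(nested) − df(wider). p-values are unadjusted; no multiple-testing
correction is applied.

Study groups mirror the field analysis: a three-way B×A×S test splits the
sexes; a B×A×L test per sex splits males by habitat (females pool
habitats). The pipeline reproduces this grouping when sex/habitat columns
are present and falls back to a single pooled group otherwise.

## Behavioral budgets

Per covariate stratum, the 2×2 row-normalized transition matrix yields the
stationary distribution as the left eigenvector at eigenvalue 1, verified
internally against the two-state closed form
π(active) = P(I→A)/(P(I→A)+P(A→I)) to 1e-12. Proportions carry Wilson score
intervals; contrasts use the pooled two-proportion z-test (a degenerate
pooled proportion of exactly 0 or 1 returns z = 0, p = 1 with a warning).

For parameter-recovery testing the package also provides a Markov effective
sample size: state-occupancy proportions from a two-state chain with second
eigenvalue ρ = 1 − P(I→A) − P(A→I) have variance inflated by
(1+ρ)/(1−ρ) relative to i.i.d. sampling, so a Wilson interval built on
n_eff = n(1−ρ)/(1+ρ) has near-nominal coverage for the stationary-budget
estimator (whose delta-method variance equals the binomial variance at
exactly that n_eff), whereas the plain-n interval is anti-conservative for
persistent chains. Reported budgets use the plain Wilson interval, the
field convention; the effective-n interval is used where an honest coverage
statement about the estimator is needed.

## Energetics chain

1. **Day filter.** A sampling period is retained iff it holds at least 87 of
   96 fixes (missing ≤ 9). `n` counts recorded segments; segments spanning a
   gap use the actual elapsed time for velocity.
2. **Distance correction.** D_total = D_summed × 95/n.
3. **Cost of transport.** Power (W/kg) = 10.7·wt^−0.316·v + 6.03·wt^−0.303,
   with wt the capture body mass (kg) and v the segment velocity (m/s).
   Because the locomotor term is linear in v, the daily total is a closed
   form of distance and mass. The postural term accrues over the full
   86,400 s period (being upright is paid for around the clock, including
   interval gaps), and the locomotor term uses the corrected distance so
   the missing-fix correction propagates to energy. Conversion: 4186.8
   J/kcal.
4. **ODBA correction.** Daily kcal/kg are mapped through
   corrected = intercept + slope × raw, defaults (8.21, 1.88, r = 0.75) on
   the per-day kcal/kg basis; `calibrate_correction` refits the line when
   paired GPS/ODBA days are available. The basis is a labeled field of
   `CorrectionModel` so alternatives can be tested. The day/night
   decomposition applies the slope to each period's raw energy and splits
   the intercept by period time fraction, making day + night = total exact
   by construction.
5. **Prey demand.** Deer biomass (kg/day) = kcal / (1890 × 0.86 × 0.88);
   doe equivalents/yr = biomass × 365 / (36.5 × 0.79). The division by
   assimilation efficiency and diet fraction is the reading verified by the
   published example chains (5,145 kcal/day ↔ 45.5 doe/yr).

Cohort summaries report both day-weighted means of per-animal means
(weights = days monitored; the "total"-row convention of the published
per-animal table) and unweighted means (the in-text convention), with
SE = sd/√n across animals.

## Housing exposure

Per fix: distance to nearest house (KD-tree; +inf sentinel when the layer
is empty), closed-disk buffer count at 150 m, majority habitat of the
150 m disk (32-edge polygonized disk; exact 50/50 ties classify as forest),
day/night (fixed 06:00/18:00 clock bounds by default, half-open at sunset;
optional NOAA solar approximation given site coordinates). Per day: mean
buffer counts by period, and two density readings — houses inside the union
of the day's buffer disks divided by union area (drives the Theobald
class), and the per-fix mean count divided by single-buffer area. The
published description is ambiguous between these; both are emitted, and the
per-fix mean is the default quartile ranking key.

Theobald development classes use half-open intervals (0, 0.062] rural,
(0.062, 1.236] exurban, (1.236, 9.884] suburban houses/ha, zero = no
housing; higher densities are urban, outside the study vocabulary, and
raise an error.

The mixed model regresses mean per-segment kcal (day and night rows per
animal-day) on sex, time (day = 1), ln(mean houses + 1) — the +1 keeps
zero-house days finite, configurable — sex×time and time×houses, with
by-animal random intercepts and slopes (time, log-houses, interaction),
fitted by REML through standard linear-mixed-model machinery. The random
structure is chosen by AIC (−2·llf + 2·k) against fixed-only and
random-intercept-only variants; singular random-effect covariances are
reported, never silently absorbed.

Quartile contrasts rank an animal's accepted days by exposure (ties broken
by date), take ceil(n/4) days at each extreme, and difference the mean
day-kcal and night-kcal between top and bottom groups; the total difference
is expressed as a percentage of the animal's mean daily expenditure and as
doe equivalents via the prey-demand chain (sign-preserving for negative
contrasts). Only animals with at least 20 day and 20 night measurements are
contrasted; exclusions are logged. Sex-level summaries are unweighted means
with SE = sd/√n.

## Synthetic-data generator

The generator emulates the study conditions: 11 males and 11 females by
default (masses 53.3 ± 7.8 and 39.8 ± 2.7 kg), 17 weekly intensive periods
per animal, fixes every 900 s. Movement is a two-state state-switching
random walk — uniform directions, half-normal inactive steps (mean 15 m)
and gamma active steps (shape 5, mean 300 m), reflected at the arena
boundary. It deliberately omits home-range attraction, kill-site fidelity
and autocorrelated headings; it exists to exercise the downstream
statistics, not to imitate puma space use. The latent chain's transition
probabilities start from a baseline (day, far, forest, female:
P(I→A) = 0.04, P(A→I) = 0.50, long-run activity ≈ 7%) and add logit offsets
on P(next = active): night +0.5, night×near-house +0.6, day×near-house
−0.4, shrubland −0.25, male +0.35 — encoding the study's qualitative
structure (nocturnal activity, a further nocturnal increase near houses, a
diurnal decrease near houses). Covariates are evaluated at the junction
fix, exactly where the analysis pipeline reads them, so per-stratum
transition counts are directly comparable between generator truth and
pipeline output. Houses are placed by a homogeneous Poisson process per
rectangular zone (default: an undeveloped half and an exurban-density half
at 0.3 houses/ha); habitat is a vertical-strip mosaic. Accelerometer
activity fractions are Beta draws per state (means 0.5 active, 0.04
inactive — well separated from the 10% cutoff); per-interval ODBA energy is
a noisy linear map of the interval's raw cost. All randomness descends from
a single generator; identical seeds give bit-identical output.

Two generator artifacts matter for interpretation. Boundary reflection can
fold a long active step into a short net displacement, so the 70 m rule
misclassifies a small fraction of intervals near arena walls (the
recovery tests tolerate this as noise; the exact-equality test runs far
from walls). And because the walk has no home range, per-animal exposure
distributions are landscape- rather than territory-driven. Consequently,
passing tests demonstrate estimator correctness under the modeled data
process — they do not validate behavioral realism against wild pumas.

## Problem sizes used in validation

The replicated recovery study runs 200 replicates of 12 animals × 18
periods (~20,000 transitions each — the scale at which interaction
selection is reliable), checking that AIC selection picks the saturated
house×time model and that per-stratum stationary budgets cover generator
truth in at least 90% of replicates (effective-n Wilson intervals, per
stratum). The IPF/ML equivalence is checked on 100 random 2×2×2×2 tables
against an independent Poisson-regression oracle (within 1e-6); the
eigen/closed-form stationary identity on 1,000 random chains (within
1e-12); and the end-to-end energy closed form on simulated days (within
1e-9).

## Known limitations

- The ODBA correction defaults come from the published coefficients; the
  published calibration day-pairs alone do not determine the regression
  scale (individual masses are not printed), so refitting them is not
  attempted.
- One row of the published model-comparison table and the published
  quartile-table deer column are internally inconsistent with their own
  printed companions; the package implements the conventions that reproduce
  every other printed value and documents the discrepancies in the tests.
- REML AIC comparison across random-effect structures (and against the OLS
  fixed-only fit) follows the published workflow; it is a pragmatic, not
  exact, model-selection criterion.
- No road/freeway covariates, topographic or substrate energetic
  surcharges, feeding energetics, or spatial-autocorrelation corrections.
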