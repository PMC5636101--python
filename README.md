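# puma-energetics

Behavioral Markov-chain and locomotion-energetics analysis of GPS/accelerometer
telemetry for a large carnivore living along a residential housing-density
gradient.

Wildlife at the wildland–urban interface changes its behavior in response to
houses, lights and human activity, and those behavioral shifts have a caloric
price. This package implements, as a tested and reusable pipeline, the
analysis chain used to quantify that price for pumas (*Puma concolor*)
tracked with GPS collars at a 15-minute cadence over weekly 24-hour intensive
sampling periods, with onboard accelerometers on a subset of animals. It is
aimed at movement ecologists and bio-logging analysts who want each stage —
behavioral state classification, transition modeling, energetics, exposure
analysis — as a well-specified, independently testable unit.

## What it computes

**Behavioral states and Markov transitions.** Each 15-minute inter-fix
interval is classified *active* or *inactive* from its straight-line
displacement (cutoff 70 m, calibrated so that it matches 10% accelerometer
activity). Consecutive intervals form first-order transitions B → A annotated
at the junction GPS fix with house proximity *H* (≤ 150 m), time of day *T*,
sex *S* and habitat *L*. Multi-way contingency tables over (B, A, H, T) are
fitted with hierarchical log-linear models by iterative proportional fitting;
models are compared with likelihood-ratio tests on the deviance

G² = 2 Σ n<sub>obs</sub> ln(n<sub>obs</sub>/n<sub>fit</sub>)

and selected by a relative AIC, `aic_rel = G² − 2·df`, whose pairwise
differences equal ordinary AIC differences. Behavioral budgets are the
stationary distribution π of the 2×2 transition matrix (left eigenvector at
eigenvalue 1; for two states π<sub>active</sub> = P(I→A)/(P(I→A)+P(A→I))),
reported with Wilson score intervals and two-proportion z-tests.

**Energetics.** Days missing more than 9 of 96 fixes are dropped; distance is
corrected for the remaining gaps as D<sub>total</sub> = D<sub>summed</sub> ×
95/n. Metabolic power follows the Taylor allometric cost-of-transport
equation,

COT (W/kg) = 10.7·wt<sup>−0.316</sup>·v + 6.03·wt<sup>−0.303</sup>,

summed over segments (the postural term accrues over the full 86,400 s day)
and converted to kcal with 4186.8 J/kcal. Because straight-line GPS paths
undercount true travel, daily kcal/kg are calibrated against accelerometer
ODBA (Overall Dynamic Body Acceleration) energy estimates via a linear
correction (default intercept 8.21, slope 1.88). Daily kilocalories convert
to prey demand through deer caloric density (1890 kcal/kg), assimilation
efficiency (0.86) and the deer fraction of the diet (0.88), then to annual
doe equivalents via doe mass (36.5 kg) and edible fraction (0.79).

**Housing exposure.** Each fix carries its 150 m-buffer house count; each
day, the per-fix mean and the density over the union of buffer disks
(classified into Theobald's no-housing / rural / exurban / suburban classes).
A linear mixed model (REML, by-animal random intercepts and slopes) relates
per-segment calories to sex, time of day, log-transformed house counts and
their interactions, and a within-animal quartile contrast reports how many
extra kcal — and extra deer per year — days in the top housing-density
quartile cost relative to the bottom quartile.

**Synthetic telemetry.** Because the original telemetry is not public, a
first-class generator produces landscapes (Poisson house placement by zone,
habitat mosaics), covariate-modulated two-state tracks at the study cadence,
and matched accelerometer/ODBA streams with full ground truth, so every
stage is testable end to end.

## Worked example

Simulate a small cohort (2 males, 2 females, 24 weekly sampling days each),
run every stage and render the report:

```bash
puma-energetics run --simulate --males 2 --females 2 --days 24 --seed 11 --out demo
puma-energetics report --run-dir demo
```

which prints (abridged):

```
Behavioral transition model selection (per study group)
  females_all:
    (BA, BHT)              aic_rel=   77.53  G2=   89.53  df=6
    (BAH, BHT)             aic_rel=   64.87  G2=   72.87  df=4
    (BAT, BHT)             aic_rel=   36.64  G2=   44.64  df=4
    (BAT, BAH, BHT)        aic_rel=   26.20  G2=   30.20  df=2
    (BAHT)                 aic_rel=    0.00  G2=    0.00  df=0 *

Energetics (per sex, day-weighted means of per-animal means)
  F: 2 animals over 48 days; distance 4.80 km/day; 91.4 kcal/kg/day; 3726 kcal/day; 33.0 deer/yr
  M: 2 animals over 48 days; distance 6.44 km/day; 87.7 kcal/kg/day; 4567 kcal/day; 40.4 deer/yr

Housing-exposure quartile contrast (mean ± SE across animals)
  F: Δkcal 102 ± 21; increase 2.7 ± 0.6 %; extra deer/yr 0.9
  M: Δkcal 116 ± 37; increase 2.5 ± 0.8 %; extra deer/yr 1.0
```

Reading the output: the saturated model `(BAHT)` — succeeding behavior
depends on preceding behavior, house proximity, time of day *and* their
interaction — minimizes `aic_rel` in both groups, recovering the
house × time interaction built into the generator. The energetics rows give
day-weighted cohort means of per-animal daily distance, mass-specific and
absolute corrected expenditure, and annual doe equivalents. The contrast
rows say that days spent in each animal's top housing-density quartile cost
on average ~100 extra kcal/day (≈ 2.5–2.7% of daily expenditure), equivalent
to about one extra deer per year — the generator's built-in nocturnal
housing effect, recovered by the full pipeline.

Each stage is also available as a library function
(`puma_energetics.markov.ipf_fit`, `energetics.deer_requirement`,
`exposure.quartile_contrast`, …) and as individual subcommands
(`simulate`, `annotate`, `transitions`, `loglinear`, `energetics`,
`exposure`).

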