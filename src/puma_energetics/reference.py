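"""Published field-study reference values used as validation inputs.

These are the printed per-animal and model-comparison summaries from the
original Santa Cruz Mountains puma GPS/accelerometer field study that this
package's methods reimplement.  The raw telemetry was never deposited, so
these printed summaries are the study-scale inputs available for checking
the arithmetic conventions (AIC convention, cohort means, weighted totals,
prey-demand chain) against their published outputs.
"""

from __future__ import annotations

import pandas as pd

#: Published mean daily caloric expenditure (kcal/day), after ODBA correction.
MEAN_DAILY_KCAL = {"M": 5145.0, "F": 4760.0}

#: Published annual doe-equivalent requirements derived from the means above.
PUBLISHED_DEER_PER_YEAR = {"M": 45.5, "F": 42.0}

#: Per-animal summary table: days monitored, mean daily distance (m), mean
#: daily kcal/kg, mean annual deer requirement.
PER_ANIMAL_SUMMARY = pd.DataFrame(
    [
        ("7F", "F", 42, 3236.0, 97.8, 36.3),
        ("11F", "F", 22, 3935.0, 104.5, 35.2),
        ("18F", "F", 8, 4001.0, 119.3, 40.0),
        ("19F", "F", 35, 3927.0, 107.9, 39.9),
        ("23F", "F", 38, 4389.0, 133.3, 48.0),
        ("24F", "F", 15, 3966.0, 145.0, 47.7),
        ("25F", "F", 14, 4493.0, 138.2, 48.1),
        ("28F", "F", 24, 4111.0, 129.9, 41.6),
        ("29F", "F", 18, 5060.0, 124.8, 42.2),
        ("16M", "M", 12, 10760.0, 96.2, 50.4),
        ("17M", "M", 8, 4297.0, 95.0, 40.2),
        ("22M", "M", 29, 9830.0, 91.2, 52.0),
        ("26M", "M", 28, 6743.0, 103.0, 39.6),
        ("27M", "M", 22, 6853.0, 99.5, 43.4),
        ("31M", "M", 10, 7047.0, 94.8, 46.1),
        ("34M", "M", 17, 6504.0, 90.1, 47.1),
        ("35M", "M", 19, 4215.0, 97.3, 38.8),
        ("36M", "M", 6, 9192.0, 96.4, 49.4),
        ("37M", "M", 2, 8877.0, 98.23, 48.4),
    ],
    columns=["animal_id", "sex", "days", "distance_m", "kcal_per_kg", "deer_per_year"],
)

#: Published pooled "total" rows of the per-animal summary (day-weighted).
SEX_TOTALS = {
    "F": {"days": 216, "distance_m": 4132.0, "kcal_per_kg": 118.9, "deer_per_year": 41.6},
    "M": {"days": 153, "distance_m": 7334.0, "kcal_per_kg": 96.3, "deer_per_year": 45.0},
}

#: Published high-vs-low housing-density quartile contrasts per animal:
#: day/night/total kcal differences, percent of mean daily kcal, extra annual
#: deer equivalents.
QUARTILE_CONTRASTS = pd.DataFrame(
    [
        ("23F", "F", -754.5, 809.5, 55.1, 1.1, 0.4),
        ("11F", "F", 94.1, 19.8, 113.9, 2.9, 0.9),
        ("28F", "F", 128.7, 128.3, 256.9, 5.7, 2.0),
        ("7F", "F", 124.9, 206.3, 331.2, 8.3, 2.6),
        ("19F", "F", 509.1, 10.5, 519.6, 12.3, 4.0),
        ("25F", "F", 54.7, 736.1, 790.9, 16.2, 6.2),
        ("29F", "F", 21.2, 951.3, 972.6, 24.4, 7.6),
        ("26M", "M", -23.5, 328.6, 305.1, 7.2, 2.4),
        ("22M", "M", 114.9, 288.1, 403.0, 7.5, 3.1),
        ("17M", "M", 418.8, 40.2, 459.0, 11.8, 3.6),
        ("27M", "M", 63.0, 408.4, 471.4, 10.9, 3.7),
        ("35M", "M", 2.8, 543.6, 546.3, 12.9, 4.3),
        ("16M", "M", 343.1, 551.9, 895.0, 19.3, 7.0),
    ],
    columns=["animal_id", "sex", "d_kcal_day", "d_kcal_night", "d_kcal_total", "percent", "d_deer"],
)

#: Published cohort summaries of the quartile contrasts (mean ± SE per sex).
QUARTILE_COHORT = {
    "F": {"d_kcal_total": 434.3, "d_kcal_total_se": 130.3, "percent": 10.1, "percent_se": 3.1, "d_deer": 3.4},
    "M": {"d_kcal_total": 513.3, "d_kcal_total_se": 83.1, "percent": 11.6, "percent_se": 1.8, "d_deer": 4.0},
}

#: Published log-linear model comparison per study group: model generating
#: classes, the published AIC difference to the group's best model, and the
#: published (G² vs saturated, residual df) pair.  ``consistent`` marks rows
#: whose printed ΔAIC equals G² − 2·df − min(G² − 2·df) to the printed
#: precision; the single inconsistent row disagrees with its own printed
#: G²/df pair by 1.8 (consistent with a 76.4/74.6 digit transposition in the
#: published table) and no single convention can reproduce it.
MODEL_COMPARISON = pd.DataFrame(
    [
        ("males_forest", "(BA, BHT)", 72.0, 84.0, 6, True),
        ("males_forest", "(BAH, BHT)", 63.8, 71.8, 4, True),
        ("males_forest", "(BAT, BHT)", 2.2, 10.2, 4, True),
        ("males_forest", "(BAT, BAH, BHT)", 0.01, 4.01, 2, True),
        ("males_forest", "(BAHT)", 0.0, 0.0, 0, True),
        ("males_shrubland", "(BA, BHT)", 53.4, 65.4, 6, True),
        ("males_shrubland", "(BAH, BHT)", 54.0, 62.0, 4, True),
        ("males_shrubland", "(BAT, BHT)", 8.4, 16.4, 4, True),
        ("males_shrubland", "(BAT, BAH, BHT)", 11.5, 15.5, 2, True),
        ("males_shrubland", "(BAHT)", 0.0, 0.0, 0, True),
        ("females_all", "(BA, BHT)", 90.8, 102.8, 6, True),
        ("females_all", "(BAH, BHT)", 66.6, 76.4, 4, False),
        ("females_all", "(BAT, BHT)", 41.3, 49.3, 4, True),
        ("females_all", "(BAT, BAH, BHT)", 24.5, 28.5, 2, True),
        ("females_all", "(BAHT)", 0.0, 0.0, 0, True),
    ],
    columns=["group", "model", "delta_aic", "g2", "df", "consistent"],
)

#: Published sex-difference likelihood-ratio test on the three-way B×A×S table.
SEX_LRT = {"delta_g2": 159.8, "df": 1}

#: Published habitat likelihood-ratio tests (B×A×L per sex).
HABITAT_LRT = {
    "M": {"delta_g2": 7.9, "df": 1},
    "F": {"delta_g2": 3.18, "df": 1, "p": 0.0744},
}
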