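import numpy as np
import pandas as pd
import pytest

from puma_energetics import reference
from puma_energetics.annotate import annotate_fixes
from puma_energetics.energetics import day_records
from puma_energetics.exposure import (
    build_exposure_days,
    cohort_summary,
    contrasts_frame,
    fit_exposure_model,
    quartile_contrast,
)
from puma_energetics.io import HouseLayer
from puma_energetics.simulate import SimScenario, simulate_dataset


def _mixed_model_data(rng, n_animals=50, n_days=40, beta_th=-1.5, slope_sd=0.3):
    rows = []
    for a in range(n_animals):
        b0 = rng.normal(0, 2)
        bt = rng.normal(0, 1)
        bh = rng.normal(0, slope_sd)
        bth = rng.normal(0, slope_sd)
        sex = a % 2
        for d in range(n_days):
            for t in (0, 1):
                lh = np.log1p(rng.gamma(2, 2))
                y = (
                    20 + 5 * sex - 1 * t + 1.2 * lh - 3 * sex * t + beta_th * t * lh
                    + b0 + bt * t + bh * lh + bth * t * lh + rng.normal(0, 2)
                )
                rows.append(
                    {
                        "animal_id": f"a{a:02d}",
                        "sex01": sex,
                        "time01": t,
                        "log_houses": lh,
                        "mean_kcal": y,
                    }
                )
    return pd.DataFrame(rows)


class TestExposureDays:
    def test_partition_and_means(self, small_annotated, config):
        exp = build_exposure_days(small_annotated, config)
        assert set(exp["period"].unique()) == {"day", "night"}
        # day + night segment counts per animal-day == segments in that day
        per_day = exp.groupby(["animal_id", "sampling_day"])["n_segments"].sum()
        assert (per_day == config.fixes_per_day - 1).all()
        assert (exp["mean_kcal"] > 0).all()
        np.testing.assert_allclose(
            exp["log_houses"], np.log1p(exp["mean_houses"]), rtol=1e-12
        )

    def test_zero_houses_log_covariate(self, config):
        ts = pd.date_range("2011-01-03T12:00:00Z", periods=96, freq="15min")
        df = pd.DataFrame(
            {
                "animal_id": "p1",
                "timestamp": ts,
                "x": np.linspace(0, 500, 96),
                "y": 0.0,
                "sex": "F",
                "body_mass_kg": 39.8,
            }
        )
        ann = annotate_fixes(df, HouseLayer(np.empty((0, 2))), None, config)
        exp = build_exposure_days(ann, config)
        assert (exp["log_houses"] == 0.0).all()

    def test_mean_kcal_matches_direct_computation(self, small_annotated, config):
        from puma_energetics.energetics import DEFAULT_CORRECTION, DEFAULT_PARAMS

        exp = build_exposure_days(small_annotated, config)
        g = small_annotated[small_annotated["animal_id"] == exp["animal_id"].iloc[0]]
        day = g[g["sampling_day"] == exp["sampling_day"].iloc[0]].sort_values("timestamp")
        xy = day[["x", "y"]].to_numpy()
        dist = np.hypot(*(xy[1:] - xy[:-1]).T)
        wt = day["body_mass_kg"].iloc[0]
        p, c = DEFAULT_PARAMS, DEFAULT_CORRECTION
        raw = (p.loco_w_per_kg_per_mps(wt) * dist + p.postural_w_per_kg(wt) * 900.0) / p.joules_per_kcal
        kcal = (c.slope * raw + c.intercept * 900.0 / 86400.0) * wt
        mask = day["period"].to_numpy()[:-1] == exp["period"].iloc[0]
        expected = kcal[mask].mean()
        assert exp["mean_kcal"].iloc[0] == pytest.approx(expected, rel=1e-12)


class TestMixedModel:
    def test_recovers_interaction_sign(self, rng):
        df = _mixed_model_data(rng, beta_th=-1.5)
        fit = fit_exposure_model(df)
        assert fit.coefficients.loc["time01:log_houses", "beta"] < 0
        assert fit.coefficients.loc["time01:log_houses", "p"] < 0.05
        assert set(fit.coefficients.index) >= {
            "sex01",
            "time01",
            "log_houses",
            "sex01:time01",
            "time01:log_houses",
        }

    def test_random_slopes_preferred_when_true(self, rng):
        df = _mixed_model_data(rng, n_animals=30, n_days=20, slope_sd=1.0)
        fit = fit_exposure_model(df)
        aic = fit.aic_comparison.set_index("model")["aic"]
        assert aic["random_slopes"] < aic["fixed_only"]
        assert aic["random_slopes"] < aic["random_intercepts"]

    def test_constant_response_gives_null_slopes(self, rng):
        df = _mixed_model_data(rng, n_animals=10, n_days=10, beta_th=0.0, slope_sd=0.0)
        df["mean_kcal"] = 42.0
        fit = fit_exposure_model(df)
        np.testing.assert_allclose(
            fit.coefficients.loc[["log_houses", "time01:log_houses"], "beta"], 0.0, atol=1e-6
        )

    def test_requires_two_animals(self, rng):
        df = _mixed_model_data(rng, n_animals=1, n_days=10)
        with pytest.raises(ValueError, match="2 animals"):
            fit_exposure_model(df)


def _synthetic_contrast_inputs(rng, n_days=40, effect=300.0):
    """Hand-built day records + exposure frame with a known housing effect."""
    days = pd.date_range("2011-01-03", periods=n_days, freq="7D").date
    houses = rng.gamma(2, 1.5, n_days)
    base = 4000 + rng.normal(0, 50, n_days)
    kcal = base + effect * (houses - houses.mean()) / houses.std()
    rec = pd.DataFrame(
        {
            "animal_id": "p1",
            "sex": "F",
            "sampling_day": days,
            "kcal_day": 0.4 * kcal,
            "kcal_night": 0.6 * kcal,
            "corrected_kcal": kcal,
        }
    )
    exp = pd.DataFrame(
        {
            "animal_id": "p1",
            "sampling_day": days,
            "mean_houses": houses,
            "union_density_ha": houses / 100.0,
        }
    )
    return rec, exp


class TestQuartileContrast:
    def test_additivity_and_sign(self, rng):
        rec, exp = _synthetic_contrast_inputs(rng)
        contrasts, excluded = quartile_contrast(rec, exp)
        assert not excluded
        (c,) = contrasts
        assert c.d_kcal_total == pytest.approx(c.d_kcal_day + c.d_kcal_night, rel=1e-12)
        assert c.d_kcal_total > 0
        assert c.quartile_days == 10
        assert c.percent_increase == pytest.approx(
            100 * c.d_kcal_total / rec["corrected_kcal"].mean(), rel=1e-9
        )

    def test_constant_data_zero_contrast(self, rng):
        rec, exp = _synthetic_contrast_inputs(rng, effect=0.0)
        rec[["kcal_day", "kcal_night", "corrected_kcal"]] = [[1600.0, 2400.0, 4000.0]] * len(rec)
        exp["mean_houses"] = 2.0
        contrasts, _ = quartile_contrast(rec, exp)
        (c,) = contrasts
        assert c.d_kcal_total == pytest.approx(0.0, abs=1e-9)
        assert c.percent_increase == pytest.approx(0.0, abs=1e-9)

    def test_eligibility_threshold(self, rng):
        rec, exp = _synthetic_contrast_inputs(rng, n_days=15)
        contrasts, excluded = quartile_contrast(rec, exp)
        assert not contrasts
        assert excluded and "p1" in excluded[0]

    def test_deer_conversion_consistent_with_chain(self, rng):
        from puma_energetics.energetics import deer_requirement

        rec, exp = _synthetic_contrast_inputs(rng)
        (c,), _ = quartile_contrast(rec, exp)
        assert c.d_deer_per_year == pytest.approx(deer_requirement(c.d_kcal_total)[1])


class TestCohortSummary:
    def test_published_quartile_columns_reproduce_cohort_values(self):
        df = reference.QUARTILE_CONTRASTS.rename(
            columns={"percent": "percent_increase", "d_deer": "d_deer_per_year"}
        )
        out = cohort_summary(df).set_index("sex")
        assert round(out.loc["F", "d_kcal_total_mean"], 1) == 434.3
        assert round(out.loc["M", "d_kcal_total_mean"], 1) == 513.3
        assert round(out.loc["F", "percent_increase_mean"], 1) == 10.1
        assert round(out.loc["M", "percent_increase_mean"], 1) == 11.6

    def test_single_animal_sex_reports_missing_se(self):
        df = pd.DataFrame(
            {
                "sex": ["F"],
                "d_kcal_day": [1.0],
                "d_kcal_night": [2.0],
                "d_kcal_total": [3.0],
                "percent_increase": [0.1],
                "d_deer_per_year": [0.02],
            }
        )
        out = cohort_summary(df)
        assert np.isnan(out["d_kcal_total_se"].iloc[0])


class TestEndToEndExposure:
    def test_nocturnal_housing_effect_recovered(self, config):
        """With the generator's positive night x house activity offset, the
        fitted time x houses interaction is negative (day = 1 coding) on a
        simulated multi-animal dataset."""
        scenario = SimScenario(n_males=4, n_females=4, n_days=10)
        fixes, houses, habitat, _ = simulate_dataset(scenario, seed=41, config=config)
        ann = annotate_fixes(fixes, houses, habitat, config)
        exp = build_exposure_days(ann, config)
        fit = fit_exposure_model(exp)
        assert fit.coefficients.loc["time01:log_houses", "beta"] < 0
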