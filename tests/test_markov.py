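import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import poisson_deviance, simulate_two_state_chain

from puma_energetics.markov import (
    ContingencyTable,
    DEFAULT_CANDIDATES,
    aic_rel,
    build_transitions,
    calibrate_cutoff,
    classify_by_activity,
    classify_by_distance,
    classify_intervals,
    effective_sample_size,
    ipf_fit,
    is_nested,
    lrt,
    select_model,
    stationary_closed_form,
    stationary_eigen,
    transition_matrix,
    two_prop_z,
    wilson_ci,
)


class TestStateClassification:
    @pytest.mark.parametrize(
        "step,expected", [(70.1, "active"), (69.9, "inactive"), (70.0, "active"), (0.0, "inactive")]
    )
    def test_distance_rule(self, step, expected):
        assert classify_by_distance(step) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_by_distance(-1.0)

    @pytest.mark.parametrize(
        "frac,expected", [(0.25, "active"), (0.05, "inactive"), (0.10, "active")]
    )
    def test_activity_rule(self, frac, expected):
        assert classify_by_activity(frac) == expected

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            classify_by_activity(1.5)


class TestCutoffCalibration:
    def test_exact_linear_inversion(self):
        frac = np.linspace(0.0, 1.0, 20)
        cal = calibrate_cutoff(frac, 700.0 * frac)
        assert cal.cutoff_m == pytest.approx(70.0, abs=1e-9)
        assert cal.r == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate_cutoff(np.full(20, 0.5), np.arange(20.0))

    def test_noisy_recovery_within_ols_theory(self, rng):
        n, sigma = 200, 30.0
        frac = rng.uniform(0, 1, n)
        step = 700.0 * frac + rng.normal(0, sigma, n)
        cal = calibrate_cutoff(frac, step)
        sxx = np.sum((frac - frac.mean()) ** 2)
        se_pred = sigma * np.sqrt(1 / n + (0.10 - frac.mean()) ** 2 / sxx)
        assert abs(cal.cutoff_m - 70.0) < 3 * se_pred


class TestTransitions:
    def _intervals(self, config, times_min, xy):
        df = pd.DataFrame(
            {
                "animal_id": "p1",
                "timestamp": pd.Timestamp("2011-01-03T12:00:00Z")
                + pd.to_timedelta(times_min, unit="min"),
                "x": [p[0] for p in xy],
                "y": [p[1] for p in xy],
            }
        )
        return df, classify_intervals(df, config)

    def test_three_consecutive_intervals_two_records(self, config):
        df, ints = self._intervals(
            config, [0, 15, 30, 45], [(0, 0), (100, 0), (110, 0), (300, 0)]
        )
        assert len(ints) == 3
        ann = df.assign(near_house=False, period="day")
        recs = build_transitions(ints, ann)
        assert len(recs) == 2
        assert list(recs["B"]) == ["active", "inactive"]
        assert list(recs["A"]) == ["inactive", "active"]

    def test_gap_breaks_chain(self, config):
        # fix missing at t=45: intervals 0-15, 15-30 and 60-75 exist but only
        # the first pair is chained, so one record survives
        df, ints = self._intervals(
            config,
            [0, 15, 30, 60, 75],
            [(0, 0), (100, 0), (110, 0), (300, 0), (500, 0)],
        )
        assert len(ints) == 3
        ann = df.assign(near_house=False, period="day")
        recs = build_transitions(ints, ann)
        assert len(recs) == 1

    def test_simulated_counts_match_generator_truth(self, config):
        """With near-perfect state separation (and no boundary reflections,
        which can fold a long step into a short displacement) the
        distance-rule pipeline reproduces the generator's per-stratum
        transition counts exactly."""
        from puma_energetics.annotate import annotate_fixes
        from puma_energetics.simulate import (
            AnimalSpec,
            LandscapeSpec,
            SimScenario,
            StepModel,
            Zone,
            generate_landscape,
            simulate_dataset,
            simulate_track,
        )

        arena = 40_000.0
        landscape_spec = LandscapeSpec(
            width_m=arena,
            height_m=arena,
            zones=[
                Zone(0, arena, 0, arena, 0.0),
                Zone(arena / 2 - 1000, arena / 2 + 1000, 0, arena, 0.3),
            ],
        )
        scenario = SimScenario(
            n_days=2,
            landscape=landscape_spec,
            steps=StepModel(inactive_mean_m=1.0, active_mean_m=500.0, active_shape=20.0),
        )
        landscape = generate_landscape(landscape_spec, seed=29)
        frames, truth_counts = [], np.zeros((2, 2, 2, 2))
        for i, sex in enumerate(["F", "M"]):
            animal = AnimalSpec(f"p{i}", sex, 45.0, start_xy=(arena / 2, arena / 2))
            track, truth = simulate_track(scenario, landscape, animal, seed=29 + i, config=config)
            frames.append(track)
            truth_counts += truth.transition_counts
        fixes = pd.concat(frames, ignore_index=True)
        ann = annotate_fixes(fixes, landscape[0], landscape[1], config)
        ints = classify_intervals(ann, config)
        recs = build_transitions(ints, ann)
        table = ContingencyTable.from_records(recs, "BAHT")
        np.testing.assert_array_equal(table.counts, truth_counts)


class TestIPF:
    def test_saturated_model_reproduces_observed(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[10, 20], [30, 40]])
        m = ipf_fit(t, ["BA"])
        np.testing.assert_allclose(m.fitted, t.counts, atol=1e-9)
        assert m.g2 == pytest.approx(0.0, abs=1e-10)
        assert m.df == 0
        assert m.aic_rel == pytest.approx(0.0, abs=1e-10)

    def test_independence_closed_form(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[10, 20], [30, 40]])
        m = ipf_fit(t, ["B", "A"])
        np.testing.assert_allclose(m.fitted, [[12, 18], [28, 42]], atol=1e-8)
        assert m.g2 == pytest.approx(0.80434865, abs=1e-6)
        assert m.df == 1

    def test_margins_match_observed(self, rng):
        t = ContingencyTable(dims=("B", "A", "H", "T"), counts=rng.poisson(40, (2, 2, 2, 2)))
        m = ipf_fit(t, ("BA", "BHT"))
        np.testing.assert_allclose(
            m.fitted.sum(axis=(2, 3)), t.counts.sum(axis=(2, 3)), atol=1e-8
        )
        np.testing.assert_allclose(m.fitted.sum(axis=1), t.counts.sum(axis=1), atol=1e-8)

    @pytest.mark.parametrize("classes", DEFAULT_CANDIDATES)
    def test_g2_matches_ml_oracle(self, rng, classes):
        """IPF deviance equals the maximum-likelihood Poisson-regression
        deviance for every model in the candidate lattice."""
        t = ContingencyTable(
            dims=("B", "A", "H", "T"), counts=rng.poisson(30, (2, 2, 2, 2)) + 1
        )
        m = ipf_fit(t, classes)
        assert m.g2 == pytest.approx(poisson_deviance(t, classes), abs=1e-6)

    def test_zero_cells_handled(self):
        counts = np.array([[[5, 0], [3, 2]], [[0, 4], [6, 1]]], dtype=float)
        t = ContingencyTable(dims=("B", "A", "H"), counts=counts)
        m = ipf_fit(t, ("BA", "BH"))
        assert np.isfinite(m.g2)
        assert m.g2 >= 0

    def test_unknown_factor_rejected(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="generating class"):
            ipf_fit(t, ["BX"])


class TestLRT:
    def test_identical_models(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[10, 20], [30, 40]])
        m = ipf_fit(t, ["B", "A"])
        dg2, ddf, p = lrt(m, m)
        assert dg2 == 0.0
        assert p == 1.0

    def test_published_tail_probabilities(self):
        """Chi-square upper tails match the published habitat tests: 3.18 on
        1 df gives p ~= 0.0745 (printed 0.0744 from unrounded G²) and 7.9 on
        1 df gives p < 0.005."""
        from scipy import stats

        assert stats.chi2.sf(3.18, 1) == pytest.approx(0.0745, abs=5e-4)
        assert stats.chi2.sf(7.9, 1) < 0.005

    def test_non_nested_rejected(self):
        t = ContingencyTable(dims=("B", "A", "H"), counts=np.ones((2, 2, 2)))
        wide = ipf_fit(t, ("BA", "BH"))
        other = ipf_fit(t, ("AH",))
        assert not is_nested(other.classes, wide.classes)
        with pytest.raises(ValueError, match="not nested"):
            lrt(other, wide)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_delta_g2_non_negative_across_lattice(self, seed):
        """ΔG² >= 0 for every nested pair in the candidate lattice, any table."""
        rng = np.random.default_rng(seed)
        t = ContingencyTable(
            dims=("B", "A", "H", "T"), counts=rng.poisson(20, (2, 2, 2, 2)) + 1
        )
        models = {c: ipf_fit(t, c) for c in DEFAULT_CANDIDATES}
        for a in DEFAULT_CANDIDATES:
            for b in DEFAULT_CANDIDATES:
                if a != b and is_nested(a, b):
                    dg2, ddf, _ = lrt(models[a], models[b])
                    assert dg2 >= 0
                    assert ddf >= 0


class TestModelSelection:
    @pytest.mark.parametrize("g2,df,expected", [(84.0, 6, 72.0), (4.01, 2, 0.01), (0.0, 0, 0.0)])
    def test_aic_convention(self, g2, df, expected):
        assert aic_rel(g2, df) == pytest.approx(expected, abs=1e-9)

    def test_true_interaction_selected_at_large_n(self, rng):
        """A synthetic table with a genuine house x time interaction on the
        succeeding state selects the saturated model at n = 20,000."""
        from puma_energetics.simulate import TransitionModel

        tm = TransitionModel()
        n = 20_000
        counts = np.zeros((2, 2, 2, 2))
        for h in (0, 1):
            for t in (0, 1):
                for b in (0, 1):
                    m = n // 16
                    p = tm.p_active(bool(b), bool(t), bool(h), False, False)
                    k = rng.binomial(m, p)
                    counts[b, 1, h, t] += k
                    counts[b, 0, h, t] += m - k
        table = ContingencyTable(dims=("B", "A", "H", "T"), counts=counts)
        sel = select_model(table)
        assert sel.best.name == "(BAHT)"

    def test_indistinguishable_pairs_flagged(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[50, 50], [50, 50]])
        sel = select_model(t, candidates=(("B", "A"), ("BA",)), indistinguishable_daic=5.0)
        assert sel.indistinguishable

    def test_sex_effect_detected_in_three_way_table(self, rng):
        """With genuinely different chains per sex, adding the A x S term to
        the B x A x S table rejects at alpha = 0.001 for n >= 10,000."""
        f = simulate_two_state_chain(0.08, 0.45, 5000, rng)
        m = simulate_two_state_chain(0.14, 0.35, 5000, rng)
        counts = np.stack([f, m], axis=-1)  # B, A, S
        t = ContingencyTable(dims=("B", "A", "S"), counts=counts)
        null = ipf_fit(t, ("BA", "BS"))
        alt = ipf_fit(t, ("BA", "AS", "BS"))
        dg2, ddf, p = lrt(null, alt)
        assert ddf == 1
        assert p < 0.001


class TestTransitionMatrix:
    def test_closed_form_example(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[90, 10], [30, 70]])
        tm = transition_matrix(t)
        np.testing.assert_allclose(tm.P, [[0.9, 0.1], [0.3, 0.7]])
        np.testing.assert_allclose(tm.pi, [0.75, 0.25], atol=1e-12)

    def test_symmetric_chain(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[50, 50], [50, 50]])
        np.testing.assert_allclose(transition_matrix(t).pi, [0.5, 0.5], atol=1e-12)

    def test_eigen_equals_closed_form_on_random_chains(self, rng):
        for _ in range(100):
            q, r = rng.uniform(0.01, 0.99, 2)
            P = np.array([[1 - q, q], [r, 1 - r]])
            np.testing.assert_allclose(
                stationary_eigen(P), stationary_closed_form(P), atol=1e-12
            )

    def test_stratum_selection(self):
        counts = np.zeros((2, 2, 2))
        counts[:, :, 0] = [[90, 10], [30, 70]]
        counts[:, :, 1] = [[50, 50], [50, 50]]
        t = ContingencyTable(dims=("B", "A", "H"), counts=counts)
        np.testing.assert_allclose(transition_matrix(t, {"H": False}).pi, [0.75, 0.25])
        np.testing.assert_allclose(transition_matrix(t, {"H": True}).pi, [0.5, 0.5])

    def test_empty_row_rejected(self):
        t = ContingencyTable(dims=("B", "A"), counts=[[0, 0], [30, 70]])
        with pytest.raises(ValueError, match="empty transition row"):
            transition_matrix(t)

    def test_effective_sample_size_bounds(self):
        P_fast = np.array([[0.5, 0.5], [0.5, 0.5]])
        P_slow = np.array([[0.95, 0.05], [0.05, 0.95]])
        assert effective_sample_size(1000, P_fast) == pytest.approx(1000.0)
        assert effective_sample_size(1000, P_slow) < 100


class TestProportions:
    def test_wilson_published_example(self):
        lo, hi = wilson_ci(50, 100)
        assert (round(lo, 3), round(hi, 3)) == (0.404, 0.596)

    def test_wilson_zero_successes(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0
        assert 0 < hi < 1

    def test_wilson_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_ci(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_two_prop_equal_samples(self):
        z, p = two_prop_z(30, 100, 30, 100)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_prop_pooled_formula(self):
        z, _ = two_prop_z(60, 100, 40, 100)
        assert z == pytest.approx(2.828, abs=1e-3)

    def test_two_prop_antisymmetric(self):
        z1, p1 = two_prop_z(60, 100, 40, 100)
        z2, p2 = two_prop_z(40, 100, 60, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = two_prop_z(0, 10, 0, 10)
        assert (z, p) == (0.0, 1.0)
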