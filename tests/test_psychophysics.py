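"""Experiment-analysis layer: 2AFC enumeration oracles, ANOVA sums-of-squares
against statsmodels, constancy-group brute force, decile selection, data
transforms, noise ceiling, and synthetic-observer parameter recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glossim.psychophysics import (
    SequenceProfile, ChoiceDataset, RatingDataset, ObserverParams,
    simulate_2afc, two_way_anova_interaction, rank_sequences_by_disagreement,
    classify_constancy_pattern, select_percentile_pairs, normalize_unit_range,
    choices_to_proportions, model_delta_for_pairs, ranks_to_positions,
    evaluate_predictions, noise_ceiling, synthetic_observer,
    fit_observer_params, default_observer_population,
)


class TestSimulate2AFC:
    def test_strictly_increasing_predictions_give_linear_profile(self):
        prof = simulate_2afc(np.arange(7.0))
        np.testing.assert_allclose(prof.proportions, np.arange(7) / 6)

    def test_all_ties_split_evenly(self):
        prof = simulate_2afc(np.ones(5))
        np.testing.assert_allclose(prof.proportions, 0.5)

    def test_three_image_enumeration(self):
        prof = simulate_2afc([3.0, 1.0, 2.0])
        np.testing.assert_allclose(prof.proportions, [1.0, 0.0, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=9))
    def test_profile_mean_is_exactly_half(self, preds):
        prof = simulate_2afc(preds)
        assert prof.proportions.mean() == pytest.approx(0.5, abs=1e-12)


class TestAnova:
    def test_matches_statsmodels_on_random_table(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = rng.random((2, 7, 5))
        res = two_way_anova_interaction(cells)
        rows = [{"a": i, "b": j, "y": cells[i, j, r]}
                for i in range(2) for j in range(7) for r in range(5)]
        df = pd.DataFrame(rows)
        fit = ols("y ~ C(a) * C(b)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res["F_interaction"] == pytest.approx(
            table.loc["C(a):C(b)", "F"], abs=1e-8)
        assert res["F_a"] == pytest.approx(table.loc["C(a)", "F"], abs=1e-8)
        assert res["F_b"] == pytest.approx(table.loc["C(b)", "F"], abs=1e-8)

    def test_identical_profiles_rank_last(self, rng):
        flat = np.tile(np.linspace(0, 1, 7), (3, 1))
        inc = flat + 0.02 * rng.standard_normal((3, 7))
        profs_a = [flat, inc]
        profs_b = [flat, np.tile(np.full(7, 0.5), (3, 1)) + 0.02 * rng.standard_normal((3, 7))]
        ranked = rank_sequences_by_disagreement(profs_a, profs_b)
        assert ranked[0][0] == 1  # disagreeing sequence first
        assert ranked[-1][0] == 0

    def test_interaction_dominates_when_one_model_flat(self, rng):
        steps = np.linspace(0, 1, 7)
        a = np.tile(steps, (4, 1)) + 0.01 * rng.standard_normal((4, 7))
        b = np.tile(np.full(7, 0.5), (4, 1)) + 0.01 * rng.standard_normal((4, 7))
        cells = np.stack([a.T, b.T], axis=0)
        res = two_way_anova_interaction(cells)
        assert res["F_interaction"] > res["F_a"]


class TestConstancyClassifier:
    def test_flat_profile_is_constant_group(self):
        assert classify_constancy_pattern(np.full(7, 0.5)) == "constant"

    def test_exact_line_with_full_range_is_linear_group(self):
        assert classify_constancy_pattern(np.arange(7) / 6) == "linear"

    def test_inverted_u_is_non_monotonic_group(self):
        x = np.arange(7.0)
        y = -((x - 3.0) ** 2) / 9.0 + 1.0
        y = (y - y.min()) / (y.max() - y.min()) * 0.6 + 0.2
        assert classify_constancy_pattern(y) == "non_monotonic"

    def test_upward_swing_is_nonlinear_upward_group(self):
        x = np.arange(7.0)
        y = (x / 6.0) ** 2 * 0.8
        assert classify_constancy_pattern(y) == "nonlinear_upward"

    def test_agrees_with_brute_force_on_random_profiles(self, rng):
        def brute(y):
            x = np.arange(len(y), dtype=float)
            rng_ = y.max() - y.min()
            cl, _ = np.polyfit(x, y, 1, full=False), None
            lin_pred = np.polyval(np.polyfit(x, y, 1), x)
            quad_coef = np.polyfit(x, y, 2)
            quad_pred = np.polyval(quad_coef, x)
            ss = np.sum((y - y.mean()) ** 2)
            lin_r2 = 1.0 if ss == 0 else 1 - np.sum((y - lin_pred) ** 2) / ss
            quad_r2 = 1.0 if ss == 0 else 1 - np.sum((y - quad_pred) ** 2) / ss
            if rng_ < 0.25 and lin_r2 > 0.70:
                return "constant"
            if rng_ > 0.50 and quad_r2 > 0.90 and quad_coef[0] < 0:
                return "non_monotonic"
            if rng_ > 0.50 and quad_r2 > 0.90 and quad_coef[0] > 0:
                return "nonlinear_upward"
            if rng_ > 0.50 and lin_r2 > 0.90:
                return "linear"
            return "unclassified"

        for _ in range(1000):
            y = rng.random(7)
            assert classify_constancy_pattern(y) == brute(y)


class TestDecileSelection:
    def test_200_candidates_select_ranks_20_to_200(self):
        deltas = np.arange(1, 201, dtype=float)
        idx = select_percentile_pairs(deltas)
        np.testing.assert_array_equal(np.sort(deltas[idx]),
                                      [20, 40, 60, 80, 100, 120, 140, 160, 180, 200])

    def test_exactly_ten_candidates_all_selected(self):
        idx = select_percentile_pairs(np.array([5, 1, 3, 2, 4, 9, 7, 6, 8, 0]))
        assert sorted(idx.tolist()) == list(range(10))

    def test_constructed_values_match_decile_convention(self):
        deltas = np.arange(1, 101, dtype=float)
        idx = select_percentile_pairs(deltas)
        np.testing.assert_array_equal(deltas[idx], np.arange(10, 101, 10))

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_percentile_pairs(np.arange(5))


class TestTransforms:
    def test_unit_range_normalization(self):
        np.testing.assert_allclose(normalize_unit_range([2, 4, 6]), [0, 0.5, 1])
        with pytest.warns(UserWarning):
            out = normalize_unit_range([3, 3, 3])
        np.testing.assert_allclose(out, 0.5)
        v = np.array([0.3, -1.2, 2.2, 0.0, 1.1])
        expected = (v - v.min()) / (v.max() - v.min())
        np.testing.assert_allclose(normalize_unit_range(v), expected, atol=1e-12)

    def test_pair_design_centering(self):
        t = pd.DataFrame([
            {"observer": 0, "pair": 0, "a": 0, "b": 1, "n_a": 8, "n_b": 0},
            {"observer": 0, "pair": 1, "a": 2, "b": 3, "n_a": 4, "n_b": 4},
        ])
        out = choices_to_proportions(ChoiceDataset(t), "pair")
        assert out.loc[0, "centered_proportion"] == pytest.approx(0.5)
        assert out.loc[1, "centered_proportion"] == pytest.approx(0.0)

    def test_sequence_design_matches_enumeration(self):
        # 3 images, 2 repetitions; image 0 always wins, 1 beats 2
        rows = []
        for rep in range(2):
            rows += [
                {"observer": 0, "pair": 0, "a": 0, "b": 1, "n_a": 1, "n_b": 0},
                {"observer": 0, "pair": 1, "a": 0, "b": 2, "n_a": 1, "n_b": 0},
                {"observer": 0, "pair": 2, "a": 1, "b": 2, "n_a": 1, "n_b": 0},
            ]
        t = pd.DataFrame(rows)
        profs = choices_to_proportions(ChoiceDataset(t), "sequence")
        np.testing.assert_allclose(profs[0].proportions, [1.0, 0.5, 0.0])

    def test_incomplete_pairing_flagged(self):
        t = pd.DataFrame([
            {"observer": 0, "pair": 0, "a": 0, "b": 1, "n_a": 1, "n_b": 0},
            {"observer": 0, "pair": 1, "a": 0, "b": 2, "n_a": 1, "n_b": 0},
        ])
        with pytest.raises(ValueError):
            choices_to_proportions(ChoiceDataset(t), "sequence")

    def test_model_delta_scaling(self):
        out = model_delta_for_pairs([3.0, 0.0, 1.0], [1.0, 2.0, 0.5])
        np.testing.assert_allclose(out, [0.5, -0.5, 0.125])
        with pytest.raises(ValueError):
            model_delta_for_pairs([1.0, 1.0], [1.0, 1.0])

    def test_ranks_to_positions(self):
        same = np.tile(np.arange(1, 6), (4, 1))
        np.testing.assert_allclose(ranks_to_positions(same), np.arange(1, 6))
        mixed = np.vstack([np.arange(1, 6), np.arange(5, 0, -1)])
        np.testing.assert_allclose(ranks_to_positions(mixed), 3.0)
        hand = np.array([[1, 2, 3, 4, 5], [2, 1, 3, 5, 4], [1, 3, 2, 4, 5]])
        np.testing.assert_allclose(ranks_to_positions(hand), hand.mean(axis=0))
        with pytest.raises(ValueError):
            ranks_to_positions(np.array([[1, 1, 3, 4, 5]]))


class TestEvaluation:
    def test_perfect_model_gives_zero_rmse_unit_r2(self):
        human = {0: [1, 2, 3, 4], 1: [1, 2, 3, 4]}
        out = evaluate_predictions([10.0, 20.0, 30.0, 40.0], human)
        assert out["mean_rmse"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0)

    def test_toy_rmse_matches_hand_computation(self):
        model = [0.0, 0.5, 1.0, 0.25, 0.75]
        human = {0: [0.1, 0.4, 0.9, 0.3, 0.8]}
        out = evaluate_predictions(model, human)
        m = normalize_unit_range(np.array(model))
        h = normalize_unit_range(np.array(human[0]))
        assert out["mean_rmse"] == pytest.approx(
            float(np.sqrt(np.mean((m - h) ** 2))), abs=1e-12)

    def test_logistic_link_recovers_sigmoid_relation(self, rng):
        x = np.linspace(0, 1, 30)
        y = 0.1 + 0.8 / (1 + np.exp(-10 * (x - 0.5)))
        out = evaluate_predictions(x, {0: y, 1: y}, logistic_link=True)
        assert out["logistic_r2"] > 0.999
        assert out["logistic_r2"] >= out["r2"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([1.0, 2.0], {0: [1.0, 2.0, 3.0]})


class TestNoiseCeiling:
    def test_identical_observers_have_zero_ceiling_rmse(self):
        human = {i: [1.0, 2.0, 3.0, 4.0] for i in range(4)}
        out = noise_ceiling(human)
        assert out["mean_rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_observers_have_near_zero_ceiling_correlation(self, rng):
        human = {i: rng.random(100) for i in range(6)}
        out = noise_ceiling(human)
        assert abs(out["mean_correlation"]) < 0.25

    def test_matches_analytic_attenuation_for_shared_signal(self, rng):
        # response = signal + noise(sd); leave-one-out mean has noise sd/sqrt(k-1)
        n_obs, n_stim, sd = 10, 4000, 0.5
        signal = rng.random(n_stim)
        human = {i: signal + rng.normal(0, sd, n_stim) for i in range(n_obs)}
        out = noise_ceiling(human)
        var_s = np.var(signal)
        expected_r = var_s / np.sqrt(
            (var_s + sd**2) * (var_s + sd**2 / (n_obs - 1)))
        assert out["mean_correlation"] == pytest.approx(expected_r, abs=0.05)

    def test_requires_three_observers(self):
        with pytest.raises(ValueError):
            noise_ceiling({0: [1, 2], 1: [1, 2]})


class TestSyntheticObserver:
    def test_infinite_beta_reproduces_deterministic_2afc(self):
        gloss = np.array([0.1, 0.9, 0.4])
        params = ObserverParams(beta=np.inf, lapse=0.0, seed=0)
        ds = synthetic_observer(gloss, params, "choice", repetitions=4)
        profs = choices_to_proportions(ds, "sequence")
        np.testing.assert_allclose(profs[0].proportions,
                                   simulate_2afc(gloss).proportions)

    def test_zero_beta_gives_chance_proportions(self):
        gloss = np.linspace(0, 1, 6)
        params = ObserverParams(beta=0.0, lapse=0.0, seed=1)
        ds = synthetic_observer(gloss, params, "choice", repetitions=200)
        t = ds.table
        p = (t["n_a"] / (t["n_a"] + t["n_b"])).mean()
        assert abs(p - 0.5) < 0.05

    def test_ratings_respect_scale_and_monotonicity(self):
        gloss = np.linspace(0, 1, 20)
        params = ObserverParams(beta=2.0, rating_noise_sd=0.05, seed=2)
        ds = synthetic_observer(gloss, params, "rating", repetitions=3)
        t = ds.table
        assert t["rating"].between(1, 6).all()
        means = t.groupby("image")["rating"].mean()
        assert np.corrcoef(means.index, means.values)[0, 1] > 0.9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(beta=-1.0)
        with pytest.raises(ValueError):
            ObserverParams(beta=1.0, criteria=(0.0, -1.0, 1.0, 2.0, 3.0))


class TestObserverFit:
    def test_lapse_free_fit_matches_logistic_regression(self, rng):
        gloss = rng.random(12)
        params = ObserverParams(beta=3.0, lapse=0.0, seed=4)
        ds = synthetic_observer(gloss, params, "choice", repetitions=50)
        est = fit_observer_params(ds, gloss, fix_lapse=0.0)
        # reference: sklearn logistic regression on expanded trials, no intercept
        from sklearn.linear_model import LogisticRegression

        t = ds.table
        deltas, ys = [], []
        for _, row in t.iterrows():
            d = gloss[row["a"]] - gloss[row["b"]]
            deltas += [d] * int(row["n_a"] + row["n_b"])
            ys += [1] * int(row["n_a"]) + [0] * int(row["n_b"])
        ref = LogisticRegression(fit_intercept=False, C=1e6).fit(
            np.array(deltas)[:, None], ys)
        assert est.beta == pytest.approx(float(ref.coef_[0, 0]), rel=0.02)

    def test_parameter_recovery_within_stated_tolerances(self):
        # 20 observers x 8 repetitions on a known gloss spread wide enough
        # to reach the psychometric asymptotes (identifies beta and lapse)
        rng = np.random.default_rng(10)
        gloss = rng.uniform(0, 3, 10)
        beta_true, lapse_true = 2.0, 0.05
        tables = []
        for obs in range(20):
            params = ObserverParams(beta=beta_true, lapse=lapse_true,
                                    seed=int(rng.integers(2**31)))
            ds = synthetic_observer(gloss, params, "choice", repetitions=8,
                                    observer_id=obs)
            tables.append(ds.table)
        pooled = ChoiceDataset(pd.concat(tables, ignore_index=True))
        est = fit_observer_params(pooled, gloss)
        assert abs(est.beta - beta_true) / beta_true < 0.20
        assert abs(est.lapse - lapse_true) < 0.05

    def test_zero_trials_rejected(self):
        empty = ChoiceDataset(pd.DataFrame(columns=["observer", "pair", "a", "b",
                                                    "n_a", "n_b"]))
        with pytest.raises(ValueError):
            fit_observer_params(empty, np.array([0.1, 0.9]))


class TestObserverPopulation:
    def test_population_is_seeded_and_in_bounds(self):
        pop1 = default_observer_population(20, seed=5)
        pop2 = default_observer_population(20, seed=5)
        assert len(pop1) == 20
        for a, b in zip(pop1, pop2):
            assert a.beta == b.beta and a.lapse == b.lapse
            assert 0 <= a.lapse <= 0.1
            assert np.all(np.diff(a.criteria) > 0)
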