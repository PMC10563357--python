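import itertools
import math

import numpy as np
import pandas as pd
import pytest

from akibench.explain import (
    breakdown_attribution,
    confusion_partition,
    global_importance,
    shapley_attribution,
)


def linear_model(coefs, intercept=0.0):
    c = np.asarray(coefs, float)

    def predict(X):
        return intercept + np.asarray(X, float) @ c

    return predict


def interaction_model(X):
    X = np.asarray(X, float)
    return X[:, 0] * X[:, 1] + 0.5 * X[:, 2]


def exact_shapley(predict, instance, background):
    """Independent subset-enumeration oracle for small p.

    phi_j = sum_S |S|!(p-|S|-1)!/p! * [v(S u {j}) - v(S)], with the value
    function v(S) evaluated by its own brute-force loop.
    """
    p = background.shape[1]

    def v(subset):
        Xm = background.copy()
        for j in subset:
            Xm[:, j] = instance[j]
        return float(np.mean(predict(Xm)))

    phi = np.zeros(p)
    features = list(range(p))
    for j in features:
        others = [f for f in features if f != j]
        for r in range(p):
            for S in itertools.combinations(others, r):
                w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
                phi[j] += w * (v(set(S) | {j}) - v(set(S)))
    return phi


@pytest.fixture()
def small_problem(rng):
    p = 4
    bg = pd.DataFrame(rng.normal(0, 1, (40, p)), columns=[f"f{i}" for i in range(p)])
    x = pd.Series(rng.normal(0, 1, p), index=bg.columns)
    return bg, x


class TestConfusionPartition:
    def test_exhaustive_disjoint_and_counts(self, rng):
        pred = (rng.random(200) < 0.4).astype(int)
        lab = (rng.random(200) < 0.3).astype(int)
        parts = confusion_partition(pred, lab)
        assert sum(len(v) for v in parts.values()) == 200
        all_ids = np.concatenate(list(parts.values()))
        assert len(np.unique(all_ids)) == 200

    def test_all_correct_has_no_errors(self):
        lab = np.array([0, 1, 1, 0])
        parts = confusion_partition(lab, lab)
        assert len(parts["FP"]) == 0 and len(parts["FN"]) == 0

    def test_threshold_zero_no_negative_predictions(self):
        parts = confusion_partition(np.ones(5, int), np.array([0, 1, 0, 1, 1]))
        assert len(parts["TN"]) == 0 and len(parts["FN"]) == 0


class TestBreakdown:
    def test_linear_model_closed_form_any_ordering(self, small_problem, rng):
        bg, x = small_problem
        coefs = np.array([1.5, -2.0, 0.7, 0.0])
        predict = linear_model(coefs, intercept=0.3)
        expected = coefs * (x.to_numpy() - bg.mean().to_numpy())
        for _ in range(5):
            ordering = list(rng.permutation(bg.columns))
            rep = breakdown_attribution(predict, x, ordering, bg)
            got = rep.contributions.reindex(bg.columns).to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-10)
            assert rep.additivity_gap() < 1e-10

    def test_instance_at_background_mean_zero_contributions(self, rng):
        bg = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("abc"))
        x = bg.mean()
        rep = breakdown_attribution(linear_model([1.0, 2.0, 3.0]), x, list("abc"), bg)
        np.testing.assert_allclose(rep.contributions.to_numpy(), 0.0, atol=1e-10)

    def test_interaction_makes_orderings_disagree(self, rng):
        bg = pd.DataFrame(rng.normal(1, 1, (50, 3)), columns=list("abc"))
        x = pd.Series([2.0, -1.0, 0.5], index=list("abc"))
        r1 = breakdown_attribution(interaction_model, x, ["a", "b", "c"], bg)
        r2 = breakdown_attribution(interaction_model, x, ["b", "a", "c"], bg)
        assert abs(r1.contributions["a"] - r2.contributions["a"]) > 1e-3
        assert r1.additivity_gap() < 1e-10 and r2.additivity_gap() < 1e-10

    def test_unknown_feature_rejected(self, small_problem):
        bg, x = small_problem
        with pytest.raises(ValueError):
            breakdown_attribution(linear_model(np.ones(4)), x, ["nope"] * 4, bg)


class TestShapley:
    def test_matches_exhaustive_enumeration(self, small_problem):
        bg, x = small_problem
        exact = exact_shapley(interaction_model, x.to_numpy(), bg.to_numpy())
        # deterministic check: averaging break-down over every ordering
        # reproduces the subset-enumeration oracle to machine precision
        acc = np.zeros(len(bg.columns))
        perms = list(itertools.permutations(bg.columns))
        for perm in perms:
            r = breakdown_attribution(interaction_model, x, list(perm), bg)
            acc += r.contributions.reindex(bg.columns).to_numpy()
        np.testing.assert_allclose(acc / len(perms), exact, atol=1e-10)
        # sampled estimate agrees within Monte-Carlo error
        rep = shapley_attribution(interaction_model, x, bg, n_orderings=3000, seed=0)
        np.testing.assert_allclose(rep.contributions.to_numpy(), exact, atol=0.08)
        assert rep.additivity_gap() < 1e-8

    def test_linear_matches_breakdown_closed_form(self, small_problem):
        bg, x = small_problem
        coefs = np.array([1.0, -1.0, 2.0, 0.5])
        rep = shapley_attribution(linear_model(coefs), x, bg, n_orderings=10, seed=1)
        expected = coefs * (x.to_numpy() - bg.mean().to_numpy())
        np.testing.assert_allclose(rep.contributions.to_numpy(), expected, atol=1e-8)

    def test_exchangeable_features_get_equal_attribution(self, rng):
        bg = pd.DataFrame(
            np.tile(rng.normal(0, 1, (60, 1)), (1, 2)), columns=["u", "v"]
        )  # identical columns
        x = pd.Series([1.3, 1.3], index=["u", "v"])

        def sym(X):
            X = np.asarray(X, float)
            return X[:, 0] + X[:, 1]

        rep = shapley_attribution(sym, x, bg, n_orderings=500, seed=2)
        assert rep.contributions["u"] == pytest.approx(rep.contributions["v"], abs=1e-6)

    def test_monte_carlo_error_halves_with_4x_orderings(self, small_problem):
        bg, x = small_problem
        exact = exact_shapley(interaction_model, x.to_numpy(), bg.to_numpy())

        def rmse(n_ord, n_rep=12):
            errs = []
            for s in range(n_rep):
                rep = shapley_attribution(interaction_model, x, bg, n_ord, seed=100 + s)
                errs.append(np.mean((rep.contributions.to_numpy() - exact) ** 2))
            return np.sqrt(np.mean(errs))

        # quadrupling the orderings should halve the MC error (sqrt(2) slack)
        assert rmse(64) <= rmse(16) / 2 * 1.5


class TestGlobalImportance:
    def test_ignored_feature_near_zero(self, rng):
        bg = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        inst = pd.DataFrame(rng.normal(0, 1, (5, 3)), columns=list("abc"))
        imp = global_importance(linear_model([2.0, 1.0, 0.0]), inst, bg, n_orderings=20)
        assert imp["c"] == pytest.approx(0.0, abs=1e-10)

    def test_dominant_feature_ranked_first(self, rng):
        bg = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        inst = pd.DataFrame(rng.normal(0, 1, (8, 3)), columns=list("abc"))
        imp = global_importance(linear_model([5.0, 0.5, 0.1]), inst, bg, n_orderings=30)
        assert imp.index[0] == "a"

    def test_ranking_stable_across_seeds(self, rng):
        bg = pd.DataFrame(rng.normal(0, 1, (30, 5)), columns=list("abcde"))
        inst = pd.DataFrame(rng.normal(0, 1, (6, 5)), columns=list("abcde"))
        predict = linear_model([3.0, 2.0, 1.0, 0.5, 0.1])
        r1 = global_importance(predict, inst, bg, n_orderings=200, seed=1)
        r2 = global_importance(predict, inst, bg, n_orderings=200, seed=2)
        assert list(r1.index) == list(r2.index)
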