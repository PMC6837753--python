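"""Ranking SVM, concordance index and its tests, aggregation, screening."""

import numpy as np
import pandas as pd
import pytest

from ithbench.survival_eval import (
    SurvivalDataset,
    bh_correct,
    comparable_pairs,
    compare_ci_paired,
    concordance_index,
    cross_validated_ci,
    fisher_aggregate,
    fit_rank_svm,
    noether_ci_test,
    predict_risk,
    select_clinical_variables,
)

import oracles


class TestComparablePairs:
    def test_all_events_enumeration(self):
        pairs = set(map(tuple, comparable_pairs([5, 3, 1], [1, 1, 1])))
        assert pairs == {(0, 1), (0, 2), (1, 2)}

    def test_censoring_removes_pairs(self):
        pairs = set(map(tuple, comparable_pairs([5, 3, 1], [1, 0, 1])))
        assert pairs == {(0, 2), (1, 2)}

    def test_no_events_no_pairs(self):
        assert len(comparable_pairs([5, 3, 1], [0, 0, 0])) == 0


class TestConcordance:
    def test_pair_enumeration_example(self):
        result = concordance_index(
            np.array([1.0, 4.0, 2.0]), np.array([5, 3, 1]), np.array([1, 1, 1])
        )
        assert result.ci == pytest.approx(2 / 3)
        assert result.n_pairs == 3

    def test_perfect_risk_order(self, rng):
        y = rng.uniform(1, 100, size=50)
        result = concordance_index(-y, y, np.ones(50, int))
        assert result.ci == 1.0

    def test_constant_scores_give_half(self, rng):
        y = rng.uniform(1, 100, size=30)
        result = concordance_index(np.zeros(30), y, np.ones(30, int))
        assert result.ci == 0.5

    def test_complement_identity_on_tie_free_data(self, rng):
        y = rng.permutation(60).astype(float) + 1
        s = rng.normal(size=60)
        d = np.ones(60, int)
        assert concordance_index(s, y, d).ci + concordance_index(-s, y, d).ci == 1.0

    def test_monotone_transform_invariance(self, rng):
        y = rng.uniform(1, 50, 40)
        d = (rng.random(40) < 0.7).astype(int)
        s = rng.normal(size=40)
        a = concordance_index(s, y, d).ci
        b = concordance_index(np.exp(s), y, d).ci
        assert a == pytest.approx(b)

    def test_matches_bruteforce(self, rng):
        y = rng.uniform(1, 30, 25)
        d = (rng.random(25) < 0.6).astype(int)
        d[0] = 1
        s = rng.normal(size=25)
        got = concordance_index(s, y, d).ci
        assert got == pytest.approx(oracles.brute_concordance(s, y, d), abs=1e-12)


class TestNoetherTest:
    def test_chance_concordance_gives_half(self):
        # tie-free scores with exactly 3 of 6 pairs concordant
        y = np.array([4.0, 3.0, 2.0, 1.0])
        s = np.array([3.0, 1.0, 4.0, 2.0])
        result = concordance_index(s, y, np.ones(4, int))
        assert result.ci == 0.5
        assert noether_ci_test(result) == pytest.approx(0.5)

    def test_power_under_true_signal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            risk = rng.normal(size=200)
            # latent survival correlated with risk -> concordance ~0.7
            y = -risk + rng.normal(scale=1.05, size=200)
            y = y - y.min() + 0.1
            result = concordance_index(risk, y, np.ones(200, int))
            if result.p_one_sided < 0.01:
                rejections += 1
        assert rejections >= 95

    def test_agrees_with_permutation_null(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 50, 80)
        d = (rng.random(80) < 0.7).astype(int)
        d[:5] = 1
        s = rng.normal(size=80) - 0.02 * y  # weak signal
        result = concordance_index(s, y, d)
        analytic = result.p_one_sided
        perm = np.array(
            [
                concordance_index(rng.permutation(s), y, d).ci
                for _ in range(1000)
            ]
        )
        perm_p = (1 + np.sum(perm >= result.ci)) / 1001
        assert abs(perm_p - analytic) < 0.05


class TestRankSvm:
    def test_perfect_single_feature_reaches_ci_one(self, rng):
        y = rng.uniform(1, 100, size=100)
        data = SurvivalDataset((-y).reshape(-1, 1), y, np.ones(100, int))
        model = fit_rank_svm(data)
        s = predict_risk(model, data.features)
        assert concordance_index(s, data.time, data.event).ci == 1.0

    def test_all_zero_features_give_zero_weights(self, rng):
        y = rng.uniform(1, 100, size=50)
        data = SurvivalDataset(np.zeros((50, 3)), y, np.ones(50, int))
        model = fit_rank_svm(data)
        assert np.allclose(model.w, 0.0)
        s = predict_risk(model, data.features)
        assert concordance_index(s, data.time, data.event).ci == 0.5

    def test_objective_value_matches_sksurv_solver(self, rng):
        """Independent solver cross-check on the identical objective."""
        from sksurv.svm import FastSurvivalSVM

        x = rng.normal(size=(150, 4))
        y = rng.exponential(scale=np.exp(-x[:, 0]), size=150) + 0.01
        d = (rng.random(150) < 0.8).astype(int)
        data = SurvivalDataset(x, y, d)
        model = fit_rank_svm(data, alpha=1.0)
        xs = model.standardize(x)
        structured = np.array(
            [(bool(e), t) for e, t in zip(d, y)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        sk = FastSurvivalSVM(alpha=1.0, rank_ratio=1.0, fit_intercept=False,
                             max_iter=200, tol=1e-10)
        sk.fit(xs, structured)
        assert np.allclose(model.w, sk.coef_, atol=1e-3)

    def test_doubling_alpha_shrinks_hinge_loss(self, rng):
        x = rng.normal(size=(80, 3))
        y = rng.uniform(1, 50, 80)
        data = SurvivalDataset(x, y, np.ones(80, int))
        pairs = comparable_pairs(y, data.event)

        def hinge(model):
            xs = model.standardize(x)
            diff = xs[pairs[:, 0]] @ model.w - xs[pairs[:, 1]] @ model.w
            return np.sum(np.maximum(0, 1 - diff) ** 2)

        assert hinge(fit_rank_svm(data, alpha=2.0)) <= hinge(
            fit_rank_svm(data, alpha=1.0)
        ) + 1e-8

    def test_empty_pairs_rejected(self):
        data = SurvivalDataset(np.ones((3, 1)), [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="comparable"):
            fit_rank_svm(data)

    def test_dimension_mismatch_rejected(self, rng):
        y = rng.uniform(1, 10, 20)
        data = SurvivalDataset(rng.normal(size=(20, 3)), y, np.ones(20, int))
        model = fit_rank_svm(data)
        with pytest.raises(ValueError, match="features"):
            predict_risk(model, rng.normal(size=(5, 4)))


class TestCrossValidation:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(100, 3))
        y = rng.uniform(1, 50, 100)
        data = SurvivalDataset(x, y, np.ones(100, int))
        a = cross_validated_ci(data, k=5, seed=3)
        b = cross_validated_ci(data, k=5, seed=3)
        assert [r.ci for r in a] == [r.ci for r in b]

    def test_too_many_folds_rejected(self, rng):
        data = SurvivalDataset(
            rng.normal(size=(4, 2)), rng.uniform(1, 5, 4), np.ones(4, int)
        )
        with pytest.raises(ValueError, match="folds"):
            cross_validated_ci(data, k=10, seed=0)


class TestAggregation:
    def test_fisher_all_ones(self):
        assert fisher_aggregate([1.0] * 5) == pytest.approx(1.0)

    def test_fisher_five_halves(self):
        assert fisher_aggregate([0.5] * 5) == pytest.approx(0.7320, abs=1e-3)

    def test_fisher_single_p_identity(self):
        assert fisher_aggregate([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_fisher_rejects_invalid(self):
        with pytest.raises(ValueError):
            fisher_aggregate([0.0, 0.5])

    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [True, True, True, True]),
            ([0.5, 0.9], [False, False]),
            ([0.04], [True]),
            ([0.06], [False]),
        ],
    )
    def test_bh_stepup_decisions(self, pvals, expected):
        reject, adjusted = bh_correct(pvals, fdr=0.05)
        assert list(reject) == expected
        assert list(reject) == oracles.brute_bh(pvals, 0.05)
        assert np.all(np.diff(adjusted[np.argsort(pvals)]) >= -1e-12)

    def test_bh_empty_input(self):
        reject, adjusted = bh_correct([])
        assert len(reject) == 0 and len(adjusted) == 0

    def test_paired_t_identical_folds(self):
        assert compare_ci_paired([0.6, 0.7, 0.65], [0.6, 0.7, 0.65]) == 1.0

    def test_paired_t_constant_shift_significant(self, rng):
        a = 0.6 + rng.normal(scale=1e-4, size=5)
        b = a + 0.1 + rng.normal(scale=1e-4, size=5)
        assert compare_ci_paired(a, b) < 0.01

    def test_paired_t_matches_formula(self, rng):
        a = rng.uniform(0.4, 0.8, size=5)
        b = rng.uniform(0.4, 0.8, size=5)
        assert compare_ci_paired(a, b) == pytest.approx(
            oracles.brute_paired_t_pvalue(a, b), abs=1e-10
        )


class TestClinicalSelection:
    def _survival(self, rng, n, signal=None):
        risk = signal if signal is not None else np.zeros(n)
        t = rng.exponential(np.exp(-risk)) + 0.01
        return t, np.ones(n, int)

    def test_small_complement_level_dropped(self, rng):
        n = 100
        clinical = pd.DataFrame({"stage": ["I"] * 60 + ["II"] * 40})
        t, d = self._survival(rng, n)
        selected = select_clinical_variables(clinical, t, d)
        assert selected.shape[1] == 0

    def test_balanced_levels_survive_size_rule(self):
        rng = np.random.default_rng(5)
        n = 110
        stage = np.array(["I"] * 60 + ["II"] * 50)
        signal = np.where(stage == "I", -1.0, 1.0)
        t, d = self._survival(rng, n, signal)
        selected = select_clinical_variables(pd.DataFrame({"stage": stage}), t, d)
        assert set(selected.columns) == {"stage=I", "stage=II"}

    def test_numeric_with_missing_value_dropped(self, rng):
        n = 120
        age = rng.uniform(40, 80, n)
        col = age.copy()
        col[3] = np.nan
        t, d = self._survival(rng, n, (age - age.mean()) / age.std())
        clinical = pd.DataFrame({"age_complete": age, "age_missing": col})
        selected = select_clinical_variables(clinical, t, d)
        assert "age_missing" not in selected.columns
        assert "age_complete" in selected.columns

    def test_uninformative_numeric_screened_out_by_cox(self, rng):
        n = 200
        t, d = self._survival(rng, n)
        clinical = pd.DataFrame({"noise": rng.normal(size=n)})
        with pytest.warns(UserWarning):
            selected = select_clinical_variables(clinical, t, d)
        assert selected.shape[1] == 0
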