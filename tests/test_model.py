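"""Two-step model: splits, fitting, prediction rule, CV, metrics, controls."""

import numpy as np
import pandas as pd
import pytest

from chromtx.model import (
    SplitPlan,
    TwoStepExpressionModel,
    crossvalidate,
    evaluate,
    fit_two_step,
    make_split,
    randomization_test,
    to_log2_with_zeros,
)

IDS = [f"g{i}" for i in range(90)]


class TestSplit:
    def test_sizes_and_folds(self):
        plan = make_split(IDS, seed=0)
        assert len(plan.d1_ids) == 30 and len(plan.d2_ids) == 60
        assert all(len(f) == 6 for f in plan.folds)

    def test_deterministic_under_seed(self):
        a, b = make_split(IDS, seed=5), make_split(IDS, seed=5)
        assert list(a.d1_ids) == list(b.d1_ids)
        assert all(list(x) == list(y) for x, y in zip(a.folds, b.folds))

    def test_different_seeds_differ(self):
        assert list(make_split(IDS, seed=1).d1_ids) != list(make_split(IDS, seed=2).d1_ids)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            make_split(IDS[:20], seed=0)

    def test_partition_validated(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(np.array(["a"]), np.array(["a", "b"]), [np.array(["a", "b"])], 0)


def toy_design(n=200, seed=0, zero_frac=0.3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 3)), columns=list("abc"), index=[f"g{i}" for i in range(n)]
    )
    logit = 2.0 * X["a"].to_numpy() + rng.normal(0, 0.5, n)
    on = logit > np.quantile(logit, zero_frac)
    y_log = 1.0 + 1.5 * X["b"].to_numpy() + 0.5 * X["c"].to_numpy()
    y = np.where(on, np.exp2(y_log + rng.normal(0, 0.3, n)), 0.0)
    return X, pd.Series(y, index=X.index)


class TestFit:
    def test_exact_linear_recovery(self):
        """Noiseless log-linear expression is reproduced exactly by OLS."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = np.exp2(1.0 + 2.0 * X["a"] - 0.5 * X["b"])
        with pytest.warns(UserWarning, match="constant 1"):  # no off genes here
            res = fit_two_step(X, y, method="linear", seed=0)
        assert res.params["a"] == pytest.approx(2.0, abs=1e-8)
        assert res.params["b"] == pytest.approx(-0.5, abs=1e-8)
        assert res.rsquared == pytest.approx(1.0)
        ev = res.evaluate(X, y)
        assert ev.pcc_r == pytest.approx(1.0, abs=1e-9)

    def test_all_on_degenerates_to_regression(self):
        X, y = toy_design(zero_frac=0.0)
        y[y == 0] = 1.0
        with pytest.warns(UserWarning, match="constant 1"):
            res = fit_two_step(X, y, seed=0, n_estimators=20)
        assert (res.predict_proba(X) == 1.0).all()
        assert np.allclose(res.predict(X), res.predict_level(X))

    def test_no_on_genes_errors(self):
        X, _ = toy_design()
        with pytest.raises(ValueError, match="on"):
            fit_two_step(X, pd.Series(0.0, index=X.index))

    def test_same_seed_same_forest(self):
        X, y = toy_design()
        r1 = fit_two_step(X, y, seed=9, n_estimators=30)
        r2 = fit_two_step(X, y, seed=9, n_estimators=30)
        assert np.array_equal(r1.predict_proba(X), r2.predict_proba(X))

    def test_mars_unavailable(self):
        X, y = toy_design()
        with pytest.raises(NotImplementedError, match="MARS"):
            TwoStepExpressionModel(X, y, method="mars")

    def test_summary_mentions_fit(self):
        X, y = toy_design()
        res = fit_two_step(X, y, seed=0, n_estimators=20)
        s = res.summary()
        assert "Two-step" in s and "coef" in s


class TestPredictRule:
    def test_off_prediction_is_exactly_zero(self):
        X, y = toy_design(seed=2)
        res = fit_two_step(X, y, seed=0, n_estimators=50)
        pred = res.predict(X)
        off = res.predict_proba(X) < 0.5
        assert (pred[off] == 0.0).all()
        assert np.allclose(pred[~off], res.predict_level(X)[~off])

    def test_feature_mismatch_rejected(self):
        X, y = toy_design()
        res = fit_two_step(X, y, seed=0, n_estimators=10)
        with pytest.raises(ValueError, match="feature mismatch"):
            res.predict(X[["b", "a", "c"]])


class TestEvaluate:
    def test_rmse_formula_oracle(self):
        ev = evaluate(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        assert ev.rmse == pytest.approx(np.sqrt(2 / 3))
        assert np.isnan(ev.pcc_r)  # zero-variance predictions: undefined, not 0

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        ev = evaluate(y, y)
        assert ev.pcc_r == pytest.approx(1.0) and ev.rmse == 0.0

    def test_perfect_separation_auc(self):
        ev = evaluate(
            np.array([3.0, 2.0, 0.0, 0.0]),
            np.array([3.0, 2.0, 0.0, 0.0]),
            proba=np.array([0.9, 0.8, 0.2, 0.1]),
            labels=np.array([True, True, False, False]),
        )
        assert ev.auc == 1.0 and ev.classification_accuracy == 1.0

    def test_range_normalized_rmse_option(self):
        y = np.array([0.0, 4.0])
        ev = evaluate(y, np.array([1.0, 3.0]), rmse_normalize="range")
        assert ev.rmse == pytest.approx(1.0 / 4.0)

    def test_log_target_keeps_zeros(self):
        assert to_log2_with_zeros(np.array([0.0, 4.0])).tolist() == [0.0, 2.0]


class TestCrossValidation:
    def test_each_d2_gene_predicted_once(self):
        X, y = toy_design(n=300, seed=1)
        plan = make_split(list(X.index), seed=0)
        cv = crossvalidate(X, y, plan, seed=0, n_estimators=30)
        assert sorted(cv.predictions.index) == sorted(plan.d2_ids)
        assert cv.predictions.index.is_unique

    def test_deterministic_under_seed(self):
        X, y = toy_design(n=300, seed=1)
        plan = make_split(list(X.index), seed=0)
        a = crossvalidate(X, y, plan, seed=4, n_estimators=30)
        b = crossvalidate(X, y, plan, seed=4, n_estimators=30)
        assert a.result.pcc_r == b.result.pcc_r
        assert np.array_equal(a.predictions, b.predictions)


class TestRandomization:
    def test_swap_preserves_row_multisets(self):
        """Label swapping permutes columns, leaving each gene's value multiset."""
        X, y = toy_design(n=300, seed=3)
        plan = make_split(list(X.index), seed=0)
        # the derangement used internally never maps a column to itself
        from chromtx.model import _derangement

        perm = _derangement(3, np.random.default_rng(0))
        assert sorted(perm) == [0, 1, 2] and (perm != np.arange(3)).all()

    def test_shuffle_x_preserves_marginals(self):
        X, y = toy_design(n=100, seed=4)
        rng = np.random.default_rng(0)
        Xp = X.copy()
        for col in Xp.columns:
            Xp[col] = Xp[col].to_numpy()[rng.permutation(len(Xp))]
        for col in X.columns:
            assert sorted(X[col]) == sorted(Xp[col])

    def test_shuffle_y_destroys_signal(self):
        X, y = toy_design(n=400, seed=5)
        plan = make_split(list(X.index), seed=0)
        ev = randomization_test(X, y, "shuffle_y", plan, seed=1, n_estimators=30)
        intact = crossvalidate(X, y, plan, seed=1, n_estimators=30).result
        assert abs(ev.pcc_r) < 0.25 < intact.pcc_r

    def test_unknown_mode(self):
        X, y = toy_design()
        plan = make_split(list(X.index), seed=0)
        with pytest.raises(ValueError, match="unknown randomization"):
            randomization_test(X, y, "nope", plan)
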