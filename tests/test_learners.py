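import numpy as np
import pandas as pd
import pytest

from itersurv.learners import (
    LearnerSpec,
    VariableImportance,
    fit_base_learner,
    fit_ensemble,
    mean_vi_select,
    predict_ensemble,
    prediction_specs,
    selection_specs,
    variable_importance,
)
from itersurv.rrf import RegularizedRandomForest, regularized_split_gain


def _linear_data(n=120, p=4, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = 6.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1] + noise * rng.standard_normal(n)
    return X, y


class TestLearnerSpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            LearnerSpec("GRADIENT_BOOST")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="hyperparameters"):
            LearnerSpec("PLS", {"mtry": 2})

    def test_shipped_specs_are_valid(self):
        assert len(prediction_specs("loop")) == 5
        assert len(prediction_specs("final")) == 5
        assert len(selection_specs()) == 3


class TestBaseLearners:
    @pytest.mark.parametrize("spec", prediction_specs("final"), ids=lambda s: s.kind)
    def test_constant_target_predicted(self, spec):
        X = np.random.default_rng(0).standard_normal((40, 3))
        y = np.full(40, 5.5)
        model = fit_base_learner(spec, X, y, seed=1)
        assert np.allclose(model.predict(X), 5.5, atol=1e-6)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_base_learner(LearnerSpec("PLS", {"ncomp": 1}), [[1.0]], [2.0])

    def test_pls_two_components_matches_least_squares_on_rank_two_design(self):
        # exactly collinear design of rank 2: PLS-2 spans the full column
        # space, so in-sample predictions equal the OLS fit
        rng = np.random.default_rng(1)
        base = rng.standard_normal((60, 2))
        X = np.column_stack([base, base @ np.array([[1.0, 2.0], [0.5, -1.0]])])
        y = 1.0 + base @ np.array([0.7, -0.4])
        model = fit_base_learner(LearnerSpec("PLS", {"ncomp": 2}), X, y)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(60), X]), y, rcond=None)
        ols_pred = np.column_stack([np.ones(60), X]) @ coef
        assert np.allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_quantile_forest_predicts_its_quantile(self):
        # y depends on nothing: the median-quantile forest should predict
        # close to the sample median everywhere
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 2))
        y = rng.exponential(1.0, 200)
        model = fit_base_learner(
            LearnerSpec("QUANTILE_FOREST", {"mtry": 2, "n_trees": 50}), X, y, seed=0
        )
        pred = model.predict(X[:20])
        assert np.all(np.abs(pred - np.median(y)) < np.quantile(y, 0.75))


class TestRegularizedForest:
    def test_split_gain_penalty_rules(self):
        assert regularized_split_gain(1.0, 3, set(), 0.9) == pytest.approx(0.9)
        assert regularized_split_gain(1.0, 3, {3}, 0.9) == pytest.approx(1.0)
        assert regularized_split_gain(2.0, 1, set(), 1.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            regularized_split_gain(-1.0, 0, set(), 0.9)

    def test_fit_is_deterministic_given_seed(self):
        X, y = _linear_data(noise=0.3)
        a = RegularizedRandomForest(n_trees=10, seed=5).fit(X, y).predict(X)
        b = RegularizedRandomForest(n_trees=10, seed=5).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_regularization_shrinks_feature_set(self):
        wins = 0
        for seed in range(8):
            X, y = _linear_data(n=150, p=8, seed=seed, noise=0.5)
            full = RegularizedRandomForest(n_trees=25, mtry=3, coef_reg=1.0, seed=seed)
            reg = RegularizedRandomForest(n_trees=25, mtry=3, coef_reg=0.9, seed=seed)
            full.fit(X, y)
            reg.fit(X, y)
            wins += len(reg.features_used_) <= len(full.features_used_)
        assert wins >= 7

    def test_learns_linear_signal(self):
        X, y = _linear_data(n=300, noise=0.1)
        model = RegularizedRandomForest(n_trees=40, mtry=2, seed=0).fit(X, y)
        resid = model.predict(X) - y
        assert np.sqrt(np.mean(resid**2)) < np.std(y) * 0.6


class TestVariableImportance:
    def test_min_max_scaling(self):
        vi = VariableImportance.from_raw({"a": 2.0, "b": 4.0, "c": 6.0}, "X")
        assert vi.scores == {"a": 0.0, "b": 50.0, "c": 100.0}

    def test_all_equal_raw_scores_zero(self):
        vi = VariableImportance.from_raw({"a": 1.0, "b": 1.0}, "X")
        assert set(vi.scores.values()) == {0.0}

    def test_single_feature_gets_full_score(self):
        assert VariableImportance.from_raw({"only": 0.37}, "X").scores == {"only": 100.0}

    def test_informative_feature_ranks_top(self):
        X, y = _linear_data(n=250, p=5, seed=3, noise=0.2)
        Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(5)])
        spec = LearnerSpec("REGULARIZED_FOREST", {"mtry": 2, "n_trees": 30})
        model = fit_base_learner(spec, X, y, seed=3)
        vi = variable_importance(model, spec, Xdf, y)
        assert max(vi.scores, key=vi.scores.get) in {"x0", "x1"}

    def test_null_importance_not_persistently_maximal(self):
        # with y independent of X, no feature should dominate across seeds
        top = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 4))
            y = rng.standard_normal(150)
            Xdf = pd.DataFrame(X, columns=list("abcd"))
            spec = LearnerSpec("REGULARIZED_FOREST", {"mtry": 2, "n_trees": 25})
            model = fit_base_learner(spec, X, y, seed=seed)
            vi = variable_importance(model, spec, Xdf, y)
            top.append(max(vi.scores, key=vi.scores.get))
        assert len(set(top)) > 1


class TestSelection:
    def test_gamma_threshold_and_ordering(self):
        vis = [VariableImportance({"f1": 30.0, "f2": 20.0, "f3": 25.0}, "X")]
        assert mean_vi_select(vis, gamma=24.0) == ["f1", "f3"]

    def test_gamma_zero_keeps_positive_scores(self):
        vis = [VariableImportance({"f1": 10.0, "f2": 0.0}, "X")]
        assert mean_vi_select(vis, gamma=0.0) == ["f1"]

    def test_empty_selection_falls_back(self):
        vis = [VariableImportance({f"f{j}": 0.0 for j in range(10)}, "X")]
        chosen = mean_vi_select(vis, gamma=50.0)
        assert len(chosen) == 5

    def test_informative_feature_survives_selection(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 250
            X = rng.standard_normal((n, 6))
            y = 6.0 + 1.0 * X[:, 0] + 0.3 * rng.standard_normal(n)
            Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(6)])
            fit = fit_ensemble(Xdf, y, prediction_specs("final")[:1], gamma=24.0, seed=seed)
            hits += "x0" in fit.selected_features
        assert hits >= 5


class TestEnsemble:
    def test_prediction_models_use_selected_features_only(self):
        X, y = _linear_data(n=100, p=6, seed=1, noise=0.3)
        Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(6)])
        fit = fit_ensemble(Xdf, y, prediction_specs("loop"), gamma=24.0, seed=1)
        assert set(fit.selected_features) <= set(Xdf.columns)
        # prediction works from a frame holding exactly the selected columns
        log_preds, days = predict_ensemble(fit, Xdf[fit.selected_features])
        assert log_preds.shape == (100, 5)
        assert np.all(days > 0)

    def test_geometric_mean_on_day_scale(self):
        class Fixed:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        from itersurv.learners import EnsembleFit

        fit = EnsembleFit(["x0"], [Fixed(np.log(100.0)), Fixed(np.log(400.0))], [])
        X = pd.DataFrame({"x0": [0.0, 1.0]})
        _, days = predict_ensemble(fit, X)
        assert np.allclose(days, 200.0)

    def test_missing_feature_column_named(self):
        X, y = _linear_data(n=60, p=3, seed=2, noise=0.2)
        Xdf = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        fit = fit_ensemble(Xdf, y, prediction_specs("loop")[:1], gamma=0.0, seed=0)
        bad = Xdf.drop(columns=[fit.selected_features[0]])
        with pytest.raises(ValueError, match=fit.selected_features[0]):
            predict_ensemble(fit, bad)

    def test_empty_input_gives_empty_output(self):
        X, y = _linear_data(n=60, p=3, seed=2, noise=0.2)
        Xdf = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        fit = fit_ensemble(Xdf, y, prediction_specs("loop")[:1], gamma=0.0, seed=0)
        log_preds, days = predict_ensemble(fit, Xdf.iloc[:0])
        assert log_preds.shape == (0, 1) and len(days) == 0

    def test_rmse_shrinks_with_sample_size_on_noiseless_data(self):
        def ens_rmse(n):
            X, y = _linear_data(n=n, p=3, seed=9, noise=0.0)
            Xdf = pd.DataFrame(X, columns=["x0", "x1", "x2"])
            half = n // 2
            fit = fit_ensemble(
                Xdf.iloc[:half], y[:half], prediction_specs("final"), gamma=0.0, seed=9
            )
            _, days = predict_ensemble(fit, Xdf.iloc[half:])
            return np.sqrt(np.mean((np.log(days) - y[half:]) ** 2))

        assert ens_rmse(800) < ens_rmse(100)
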