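"""Scaling, splitting, cross-validation, training, and importance tests."""

import numpy as np
import pandas as pd
import pytest

from gaitfall import classification as cls
from gaitfall import synthetic
from gaitfall.classification import (
    ModelConfig,
    cross_validate,
    default_config_grid,
    feature_columns,
    feature_importance_ranking,
    minmax_scale_apply,
    minmax_scale_fit,
    predict_risk,
    split_train_test,
    train_model,
)
from gaitfall.errors import DataError, ParameterError, SchemaError


class TestModelConfig:
    @pytest.mark.parametrize("kwargs", [
        {"train_fraction": 1.0},
        {"train_fraction": 0.0},
        {"cv_folds": 1},
        {"leaf_penalty": -0.1},
        {"n_trees": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelConfig(**kwargs)


class TestMinMaxScaler:
    def test_affine_map(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaler = minmax_scale_fit(train)
        out = minmax_scale_apply(scaler, train)
        np.testing.assert_allclose(out["x"], [0.0, 0.5, 1.0])

    def test_constant_feature_flagged_and_zeroed(self):
        train = pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [0.0, 1.0, 2.0]})
        scaler = minmax_scale_fit(train)
        assert scaler.constant_features == ("x",)
        out = minmax_scale_apply(scaler, train)
        np.testing.assert_allclose(out["x"], 0.0)

    def test_extrapolation_not_clipped(self):
        scaler = minmax_scale_fit(pd.DataFrame({"x": [1.0, 3.0]}))
        out = minmax_scale_apply(scaler, pd.DataFrame({"x": [4.0]}))
        assert out["x"].iloc[0] == pytest.approx(1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            minmax_scale_fit(pd.DataFrame({"x": []}))

    def test_missing_feature_named(self):
        scaler = minmax_scale_fit(pd.DataFrame({"x": [1.0, 2.0]}))
        with pytest.raises(SchemaError, match="x"):
            minmax_scale_apply(scaler, pd.DataFrame({"y": [1.0]}))


class TestSplit:
    def test_stratified_counts(self, default_cohort):
        train, test = split_train_test(default_cohort, 0.7, seed=0)
        assert abs(len(train) - 522) <= 1
        assert abs(len(test) - 224) <= 1
        assert len(train) + len(test) == 746
        # label proportions preserved to within one record
        assert abs(train.risk_label.sum() - round(0.7 * 290)) <= 1
        assert abs(test.risk_label.sum() - round(0.3 * 290)) <= 1

    def test_disjoint_exhaustive(self, default_cohort):
        train, test = split_train_test(default_cohort, 0.7, seed=3)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(default_cohort.index)

    def test_seed_reproducibility(self, default_cohort):
        a = split_train_test(default_cohort, 0.7, seed=5)
        b = split_train_test(default_cohort, 0.7, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_fraction_one_rejected(self, default_cohort):
        with pytest.raises(ParameterError):
            split_train_test(default_cohort, 1.0)

    def test_tiny_cohort_rejected(self, default_cohort):
        with pytest.raises(DataError):
            split_train_test(default_cohort.head(5), 0.7)


def _toy_table(n, rng, informative=True):
    x = rng.standard_normal((n, 3))
    y = rng.integers(0, 2, size=n)
    table = pd.DataFrame(x, columns=["a", "b", "c"])
    if informative:
        table["a"] = y + 0.01 * rng.standard_normal(n)  # separable
    table["risk_label"] = y
    return table


class TestCrossValidate:
    def test_separable_data_gives_auc_one(self, rng):
        table = _toy_table(100, rng)
        config = ModelConfig(n_trees=30, cv_folds=5, seed=0)
        result = cross_validate(table, config, ["a", "b", "c"])
        assert result["selected_mean_auc"] == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self, default_cohort, rng):
        shuffled = default_cohort.copy()
        shuffled["risk_label"] = rng.permutation(shuffled["risk_label"].values)
        train, _ = split_train_test(shuffled, 0.7, seed=0)
        config = ModelConfig(n_trees=50, cv_folds=10, seed=0)
        result = cross_validate(train, config, feature_columns("preferred"))
        assert 0.4 <= result["selected_mean_auc"] <= 0.6

    def test_more_folds_than_records_rejected(self, rng):
        table = _toy_table(9, rng)
        with pytest.raises(ParameterError):
            cross_validate(table, ModelConfig(cv_folds=10), ["a", "b", "c"])

    def test_tie_break_prefers_simpler_model(self, rng):
        table = _toy_table(100, rng)  # separable: every config ties at 1.0
        configs = [ModelConfig(n_trees=n, max_depth=d, cv_folds=5, seed=0)
                   for n in (30, 60) for d in (2, 3)]
        result = cross_validate(table, configs, ["a", "b", "c"])
        assert result["selected"].n_trees == 30
        assert result["selected"].max_depth == 2

    def test_grid_has_documented_shape(self):
        assert len(default_config_grid()) == 4


class TestTrainModel:
    def test_single_informative_feature_ranks_first(self, rng):
        n = 400
        y = rng.integers(0, 2, size=n)
        table = pd.DataFrame({
            "stride_length": y + 0.1 * rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
            "risk_label": y,
        })
        model = train_model(table, ModelConfig(n_trees=50, seed=0),
                            ["stride_length", "noise1", "noise2"])
        ranking = feature_importance_ranking(model)
        assert ranking[0][0] == "stride_length"

    def test_zero_variance_feature_zero_importance(self, rng):
        table = _toy_table(200, rng)
        table["flat"] = 1.0
        model = train_model(table, ModelConfig(n_trees=30, seed=0),
                            ["a", "b", "c", "flat"])
        assert model.importances["flat"] == 0.0

    def test_seeded_reproducibility(self, rng):
        table = _toy_table(200, rng)
        m1 = train_model(table, ModelConfig(seed=4), ["a", "b", "c"])
        m2 = train_model(table, ModelConfig(seed=4), ["a", "b", "c"])
        x = table[["a", "b", "c"]]
        np.testing.assert_array_equal(m1.predict_scores(x),
                                      m2.predict_scores(x))

    def test_single_class_rejected(self, rng):
        table = _toy_table(50, rng)
        table["risk_label"] = 1
        with pytest.raises(DataError):
            train_model(table, ModelConfig(), ["a", "b", "c"])

    def test_missing_feature_named(self, rng):
        table = _toy_table(50, rng)
        with pytest.raises(SchemaError, match="zzz"):
            train_model(table, ModelConfig(), ["a", "zzz"])


@pytest.fixture(scope="module")
def model_and_table():
    rng = np.random.default_rng(1)
    table = _toy_table(300, rng)
    model = train_model(table, ModelConfig(n_trees=50, seed=1),
                        ["a", "b", "c"])
    return model, table


class TestPredictRisk:
    def test_scores_in_unit_interval(self, model_and_table):
        model, table = model_and_table
        scores, labels = predict_risk(model, table[["a", "b", "c"]])
        assert np.all((scores >= 0) & (scores <= 1))
        assert set(labels) <= {0, 1}

    def test_threshold_convention(self, model_and_table):
        model, table = model_and_table
        scores, labels = predict_risk(model, table[["a", "b", "c"]])
        np.testing.assert_array_equal(labels, (scores >= 0.5).astype(int))

    def test_calibration_near_prevalence(self, rng):
        n = 600
        y = (rng.standard_normal(n) + 0.3 * rng.standard_normal(n) > 0.4).astype(int)
        table = pd.DataFrame({"a": y + rng.standard_normal(n),
                              "b": rng.standard_normal(n),
                              "risk_label": y})
        model = train_model(table, ModelConfig(n_trees=100, seed=0), ["a", "b"])
        scores, _ = predict_risk(model, table[["a", "b"]])
        assert scores.mean() == pytest.approx(y.mean(), abs=0.05)

    def test_column_order_irrelevant(self, model_and_table):
        model, table = model_and_table
        a, _ = predict_risk(model, table[["a", "b", "c"]])
        b, _ = predict_risk(model, table[["c", "a", "b"]])
        np.testing.assert_array_equal(a, b)

    def test_missing_feature_named(self, model_and_table):
        model, table = model_and_table
        with pytest.raises(SchemaError, match="c"):
            predict_risk(model, table[["a", "b"]])


class TestImportanceRanking:
    def test_top_k_limits(self, rng):
        table = _toy_table(100, rng)
        model = train_model(table, ModelConfig(n_trees=20, seed=0),
                            ["a", "b", "c"])
        assert len(feature_importance_ranking(model, top_k=2)) == 2
        assert len(feature_importance_ranking(model, top_k=10)) == 3

    def test_normalized_scores_sum_to_one(self, rng):
        table = _toy_table(100, rng)
        model = train_model(table, ModelConfig(n_trees=20, seed=0),
                            ["a", "b", "c"])
        ranked = feature_importance_ranking(model, normalize=True)
        assert sum(v for _, v in ranked) == pytest.approx(1.0)

    def test_descending_order(self, rng):
        table = _toy_table(100, rng)
        model = train_model(table, ModelConfig(n_trees=20, seed=0),
                            ["a", "b", "c"])
        scores = [v for _, v in feature_importance_ranking(model)]
        assert scores == sorted(scores, reverse=True)


class TestProperties:
    def test_separability_monotone_in_group_gap(self):
        """Widening the between-group walking-speed gap raises mean test AUC."""
        from gaitfall.evaluation import roc_auc

        gaps = [0.0, -0.15, -0.35]  # shift of the high-risk preferred speed mean
        mean_aucs = []
        cols = feature_columns("preferred")
        for gap in gaps:
            aucs = []
            for seed in range(10):
                spec = synthetic.default_cohort_spec(n_participants=400,
                                                     seed=seed)
                spec = synthetic.with_mean_shift(spec,
                                                 "preferred_walking_speed",
                                                 gap, group="high")
                cohort = synthetic.simulate_cohort(spec)
                train, test = split_train_test(cohort, 0.7, seed=seed)
                model = train_model(
                    train, ModelConfig(n_trees=60, max_depth=2, seed=seed),
                    cols)
                scores, _ = predict_risk(model, test[cols])
                aucs.append(roc_auc(scores, test.risk_label.to_numpy())["auc"])
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] < mean_aucs[1] < mean_aucs[2]

    def test_no_leakage_from_test_set(self, default_cohort):
        cols = feature_columns("slower")
        train, test = split_train_test(default_cohort, 0.7, seed=0)
        model = train_model(train, ModelConfig(n_trees=50, seed=0), cols)
        shuffled_test = test.copy()
        shuffled_test["risk_label"] = np.random.default_rng(0).permutation(
            shuffled_test["risk_label"].values)
        model2 = train_model(train, ModelConfig(n_trees=50, seed=0), cols)
        np.testing.assert_array_equal(model.predict_scores(test[cols]),
                                      model2.predict_scores(test[cols]))
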