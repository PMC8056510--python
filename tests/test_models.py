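"""Grids, tree and neural training, the sweep, and the stacked ensemble."""

import numpy as np
import pytest

from genopheno import (
    EnsembleConfig,
    HyperParams,
    ModelGrid,
    build_stacked_ensemble,
    default_grid,
    evaluate_model,
    hyperparameter_sweep,
    predict_proba,
    train_neural_model,
    train_tree_model,
)
from genopheno.models import DEFAULT_NEURAL_GRID_AXES, DEFAULT_RF_GRID, DEFAULT_XGB_GRID

SMALL_RF_GRID = ModelGrid(
    "rf", {"criterion": ["gini"], "n_estimators": [100], "max_depth": [None, 4]}
)


class TestGridFidelity:
    def test_random_forest_axes_match_printed_lists(self):
        assert DEFAULT_RF_GRID.axes == {
            "criterion": ["gini", "entropy"],
            "min_samples_split": [0.01, 0.015, 0.02, 0.025],
            "max_depth": [None, 4, 5],
            "min_samples_leaf": [0.0025, 0.005, 0.01, 0.015],
            "max_features": ["sqrt", 0.3, 0.4, 0.5],
            "n_estimators": [500, 1000, 3000],
        }

    def test_xgboost_axes_match_printed_lists(self):
        assert DEFAULT_XGB_GRID.axes["min_child_weight"] == [1, 5, 10]
        assert DEFAULT_XGB_GRID.axes["gamma"] == [0.5, 1, 1.5, 2, 5]
        assert DEFAULT_XGB_GRID.axes["subsample"] == [0.6, 0.8, 1.0]
        assert DEFAULT_XGB_GRID.axes["colsample_bytree"] == [0.6, 0.8, 1.0]
        assert DEFAULT_XGB_GRID.axes["max_depth"] == [3, 4, 5]
        assert DEFAULT_XGB_GRID.axes["booster"] == ["gbtree", "gblinear", "dart"]
        assert DEFAULT_XGB_GRID.axes["objective"] == [
            "binary:hinge", "binary:logistic", "binary:logitraw",
        ]

    def test_neural_sweep_axes_match_printed_lists(self):
        assert DEFAULT_NEURAL_GRID_AXES == {
            "activation": ["sigmoid", "relu", "softmax"],
            "dropout_rate": [0.2, 0.3, 0.5],
            "optimizer": ["adam", "sgd", "rmsprop"],
            "batch_size": [1, 10, 15, 20],
            "validation_split": [0.2, 0.3, 0.4],
            "epochs": [10, 20, 50, 100],
        }

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ModelGrid("rf", {})
        with pytest.raises(ValueError):
            ModelGrid("rf", {"criterion": []})
        with pytest.raises(ValueError):
            default_grid("svm")


class TestTreeModels:
    def test_random_forest_fits_separable_cohort(self, small_split):
        model = train_tree_model(small_split, "rf", SMALL_RF_GRID, seed=0)
        train_acc = (
            model.estimator.predict(small_split.train.features)
            == small_split.train.labels
        ).mean()
        assert train_acc >= 0.95
        assert model.hyperparams["criterion"] == "gini"

    def test_xgboost_fits_separable_cohort(self, small_split):
        grid = ModelGrid(
            "xgb", {"max_depth": [3], "objective": ["binary:logistic"], "gamma": [0.5, 1.5]}
        )
        model = train_tree_model(small_split, "xgb", grid, seed=0)
        assert model.validation_accuracy >= 0.9

    def test_wrong_kind_rejected(self, small_split):
        with pytest.raises(ValueError):
            train_tree_model(small_split, "ann", SMALL_RF_GRID)


class TestNeuralModels:
    @pytest.mark.parametrize("kind", ["ann", "cnn1d", "lstm", "gru", "bilstm"])
    def test_all_kinds_produce_a_trained_model(self, small_split, kind):
        model = train_neural_model(
            small_split, kind, HyperParams(epochs=2, batch_size=20, seed=0)
        )
        assert model.kind == kind
        assert 0 <= model.validation_accuracy <= 1
        assert len(model.history["loss"]) == 2

    def test_seed_reproducibility(self, small_split):
        hp = HyperParams(epochs=3, seed=4)
        a = train_neural_model(small_split, "ann", hp)
        b = train_neural_model(small_split, "ann", hp)
        assert a.validation_accuracy == b.validation_accuracy

    def test_swept_hyperparameters_accepted(self, small_split):
        hp = HyperParams(
            activation="relu", dropout_rate=0.3, optimizer="rmsprop",
            batch_size=15, epochs=2, validation_split=0.3, seed=1,
        )
        model = train_neural_model(small_split, "ann", hp)
        assert model.hyperparams["batch_size"] == 15


class TestSweep:
    def test_two_point_grid_returns_two_ranked_models(self, small_split):
        grid = ModelGrid("ann", {"epochs": [2, 3]})
        ranked = hyperparameter_sweep(small_split, "ann", grid, seed=0)
        assert len(ranked) == 2
        accs = [m.validation_accuracy for m in ranked]
        assert accs == sorted(accs, reverse=True)

    def test_sweep_best_at_least_single_config(self, small_split):
        grid = ModelGrid("ann", {"epochs": [2, 3], "batch_size": [10, 20]})
        ranked = hyperparameter_sweep(small_split, "ann", grid, seed=0)
        single = train_neural_model(
            small_split, "ann", HyperParams(epochs=2, batch_size=10, seed=0)
        )
        assert ranked[0].validation_accuracy >= single.validation_accuracy

    def test_journal_resume_skips_completed_combos(self, small_split, tmp_path):
        journal = tmp_path / "sweep.jsonl"
        grid = ModelGrid("ann", {"epochs": [2, 3]})
        first = hyperparameter_sweep(small_split, "ann", grid, seed=0, journal_path=journal)
        assert journal.exists() and len(journal.read_text().splitlines()) == 2
        resumed = hyperparameter_sweep(small_split, "ann", grid, seed=0, journal_path=journal)
        assert {m.validation_accuracy for m in resumed} == {
            m.validation_accuracy for m in first
        }
        assert all(m.estimator is None for m in resumed)  # reloaded, not retrained


class TestStackedEnsemble:
    def test_threshold_includes_and_excludes(self, small_split):
        strong = train_neural_model(small_split, "ann", HyperParams(epochs=15, seed=0))
        weak = train_neural_model(small_split, "ann", HyperParams(epochs=1, seed=1))
        weak.validation_accuracy = 0.91
        strong.validation_accuracy = 0.93
        ensemble = build_stacked_ensemble(
            [weak, strong], small_split, EnsembleConfig(val_acc_threshold=0.92)
        )
        assert ensemble.hyperparams["n_base_models"] == 1

    def test_meta_head_defaults_to_ten_epochs(self, small_split):
        strong = train_neural_model(small_split, "ann", HyperParams(epochs=15, seed=0))
        strong.validation_accuracy = 0.95
        ensemble = build_stacked_ensemble([strong], small_split)
        assert ensemble.hyperparams["meta_epochs"] == 10
        assert len(ensemble.history["loss"]) == 10

    def test_base_parameters_frozen_during_meta_training(self, small_split):
        base = train_neural_model(small_split, "ann", HyperParams(epochs=10, seed=0))
        base.validation_accuracy = 0.99
        before = base.estimator.parameter_snapshot()
        build_stacked_ensemble([base], small_split)
        after = base.estimator.parameter_snapshot()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_no_qualifying_candidate_raises_naming_threshold(self, small_split):
        weak = train_neural_model(small_split, "ann", HyperParams(epochs=1, seed=2))
        weak.validation_accuracy = 0.5
        with pytest.raises(ValueError, match="0.92"):
            build_stacked_ensemble([weak], small_split)

    def test_fallback_top_k_admits_best_models(self, small_split):
        weak = train_neural_model(small_split, "ann", HyperParams(epochs=2, seed=2))
        weak.validation_accuracy = 0.5
        ensemble = build_stacked_ensemble(
            [weak], small_split, EnsembleConfig(fallback_top_k=1)
        )
        assert ensemble.hyperparams["n_base_models"] == 1


class TestPredictProba:
    def test_rows_sum_to_one_and_argmax_consistent(self, small_split):
        model = train_neural_model(small_split, "ann", HyperParams(epochs=3, seed=0))
        p = predict_proba(model, small_split.test.features)
        assert p.shape == (small_split.test.n_samples, 2)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p.argmax(axis=1), (p[:, 1] > p[:, 0]).astype(int))

    def test_width_mismatch_is_fatal(self, small_split):
        model = train_neural_model(small_split, "ann", HyperParams(epochs=1, seed=0))
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, model.n_features + 1)))
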