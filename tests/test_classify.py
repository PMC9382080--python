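"""Forest training, splitting, evaluation metrics and importances."""

import numpy as np
import pandas as pd
import pytest

from ambiclass.classify import (
    ModelConfig,
    ResidueClassForest,
    evaluate_classifier,
    feature_importance,
    predict_classes,
    round_half_up,
    split_dataset,
    train_classifier,
)
from ambiclass.features import FEATURE_COLUMNS
from ambiclass.synthetic import SyntheticConfig, gen_class_features


def _separable_table(n=120, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    data = {col: rng.uniform(0, 1, size=n) for col in FEATURE_COLUMNS}
    data["disorder"] = np.concatenate(
        [rng.uniform(0.0, 0.4, half), rng.uniform(0.6, 1.0, n - half)]
    )
    table = pd.DataFrame(data)
    table["label"] = ["order"] * half + ["disorder"] * (n - half)
    return table


class TestSplitDataset:
    def test_test_size_is_rounded_fraction(self, class_features):
        n = len(class_features)
        train, test = split_dataset(class_features, 0.10, seed=0)
        assert len(test) == round(n * 0.10)
        assert len(train) + len(test) == n

    def test_disjoint_and_stratified(self):
        table = _separable_table(n=100)
        table["row_id"] = range(100)
        train, test = split_dataset(table, 0.3, seed=1)
        assert len(test) == 30
        assert set(train["row_id"]).isdisjoint(test["row_id"])
        # stratification keeps the 50/50 class balance in the test split
        assert sorted(test["label"].value_counts()) == [15, 15]

    def test_deterministic_under_seed(self, class_features):
        a_train, a_test = split_dataset(class_features, 0.2, seed=7)
        b_train, b_test = split_dataset(class_features, 0.2, seed=7)
        pd.testing.assert_frame_equal(a_train, b_train)
        pd.testing.assert_frame_equal(a_test, b_test)

    def test_tiny_class_rejected(self):
        table = _separable_table(n=40)
        table.loc[0, "label"] = "rare"
        with pytest.raises(ValueError, match="rare"):
            split_dataset(table, 0.3, seed=0)


class TestTrainClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        table = _separable_table()
        model = train_classifier(table, ModelConfig(seed=0))
        assert (model.predict(table) == table["label"]).all()

    def test_model_card_echoes_hyperparameters(self):
        config = ModelConfig(n_estimators=75, max_depth=15, min_samples_split=5,
                             min_samples_leaf=1, bootstrap=False, seed=3)
        model = train_classifier(_separable_table(), config)
        hp = model.model_card_["hyperparameters"]
        assert hp == {"n_estimators": 75, "max_depth": 15, "min_samples_split": 5,
                      "min_samples_leaf": 1, "bootstrap": False}
        assert model.model_card_["seed"] == 3

    def test_single_class_rejected(self):
        table = _separable_table()
        table["label"] = "order"
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(table, ModelConfig())

    def test_grid_search_selects_by_cv(self):
        table = _separable_table(n=60)
        model = ResidueClassForest(seed=0, cv_folds=3,
                                   param_grid={"n_estimators": [5, 10]})
        model.fit(table, table["label"].to_numpy())
        cv = model.model_card_["cv"]
        assert cv["best_params"]["n_estimators"] in (5, 10)
        assert 0.0 <= cv["best_mean_cv_macro_f1"] <= 1.0

    def test_heldout_macro_f1_on_default_separations(self, class_features):
        table = class_features.iloc[:3000]
        train, test = split_dataset(table, 0.3, seed=0)
        model = train_classifier(train, ModelConfig(seed=0))
        metrics = evaluate_classifier(model, test)
        assert np.mean(list(metrics.f1.values())) >= 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_estimators=0)
        with pytest.raises(ValueError):
            ModelConfig(test_fraction=1.5)


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        table = _separable_table()
        model = train_classifier(table, ModelConfig(seed=0))
        metrics = evaluate_classifier(model, table)
        for cls in metrics.classes:
            assert metrics.precision[cls] == metrics.recall[cls] == metrics.f1[cls] == 1.0

    def test_formulas_from_confusion_counts(self):
        # TP=3, FP=1, FN=2 for the positive class
        y_true = ["a"] * 5 + ["b"] * 4
        y_pred = ["a", "a", "a", "b", "b", "a", "b", "b", "b"]

        class Stub:
            classes_ = np.array(["a", "b"])

            def predict(self, X):
                return np.array(y_pred)

        test = pd.DataFrame({"label": y_true})
        metrics = evaluate_classifier(Stub(), test)
        assert metrics.precision["a"] == pytest.approx(0.75)
        assert metrics.recall["a"] == pytest.approx(0.60)
        assert metrics.f1["a"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_confusion_conservation(self, class_features):
        table = class_features.iloc[:1500]
        train, test = split_dataset(table, 0.3, seed=2)
        model = train_classifier(train, ModelConfig(seed=2))
        metrics = evaluate_classifier(model, test)
        assert metrics.confusion.sum() == len(test)
        for i, cls in enumerate(metrics.classes):
            assert metrics.confusion[i].sum() == metrics.support[cls]

    def test_f1_is_harmonic_mean(self, class_features):
        table = class_features.iloc[:1500]
        train, test = split_dataset(table, 0.3, seed=3)
        metrics = evaluate_classifier(train_classifier(train, ModelConfig(seed=3)), test)
        for cls in metrics.classes:
            p, r = metrics.precision[cls], metrics.recall[cls]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert metrics.f1[cls] == pytest.approx(expected, abs=1e-9)

    def test_empty_test_rejected(self):
        model = train_classifier(_separable_table(), ModelConfig(seed=0))
        with pytest.raises(ValueError):
            evaluate_classifier(model, _separable_table().iloc[0:0])

    def test_determinism(self, class_features):
        table = class_features.iloc[:1000]

        def run():
            train, test = split_dataset(table, 0.3, seed=5)
            return evaluate_classifier(train_classifier(train, ModelConfig(seed=5)), test)

        a, b = run(), run()
        assert a.f1 == b.f1 and a.precision == b.precision
        assert (a.confusion == b.confusion).all()


class TestFeatureImportance:
    def test_sorted_nonnegative_sums_to_one(self, class_features):
        model = train_classifier(class_features.iloc[:1000], ModelConfig(seed=0))
        imp = feature_importance(model)
        values = list(imp.values())
        assert all(v >= 0 for v in values)
        assert sum(values) == pytest.approx(1.0, abs=1e-9)
        assert values == sorted(values, reverse=True)

    def test_single_informative_feature_ranked_first(self):
        table = _separable_table(n=400, seed=1)  # only disorder carries signal
        model = train_classifier(table, ModelConfig(seed=1))
        imp = feature_importance(model)
        assert next(iter(imp)) == "disorder"
        assert imp["disorder"] > 0.5

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            feature_importance(ResidueClassForest())


class TestPredictClasses:
    def test_pure_order_table(self):
        cfg = SyntheticConfig(
            seed=9, n_proteins=10,
            class_priors={"order": 1.0, "ambiguous": 0.0, "disorder": 0.0},
        )
        pure = gen_class_features(cfg)
        mixed = gen_class_features(SyntheticConfig(seed=10, n_proteins=30))
        model = train_classifier(mixed, ModelConfig(seed=9))
        _, fractions = predict_classes(model, pure)
        assert fractions["order"] >= 0.9

    def test_fractions_sum_to_one(self, class_features):
        model = train_classifier(class_features.iloc[:800], ModelConfig(seed=4))
        _, fractions = predict_classes(model, class_features.iloc[800:1200])
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_empty_table_flagged(self, class_features):
        model = train_classifier(class_features.iloc[:500], ModelConfig(seed=4))
        predictions, fractions = predict_classes(model, class_features.iloc[0:0])
        assert len(predictions) == 0 and fractions is None


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.625) == 0.63
    assert round_half_up(0.375) == 0.38
    assert round_half_up(0.5715) == 0.57
    assert round_half_up(-0.625) == -0.63
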