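"""Random-forest residue classifiers.

Three model presets mirror the three study datasets:

* ``folding_upon_binding`` -- the three raw classes O / T / D from the
  combined disorder-to-order dataset (n_estimators=75, max_depth=15,
  min_samples_split=5, min_samples_leaf=1, bootstrap=False; 90/10 split),
* ``foldswitch`` -- the two-class S / C fold-switch model (same
  hyperparameters and split as the first model),
* ``combined`` -- the merged order / ambiguous / disorder classes
  (n_estimators=25, max_depth=15, min_samples_split=5,
  min_samples_leaf=5, bootstrap=True; 70/30 split).

The estimator follows the scikit-learn contract (``fit`` / ``predict`` /
``get_params``) so it composes with pipelines and model selection; the
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.utils.validation import check_is_fitted

from ambiclass.features import FEATURE_COLUMNS

#: Default grid searched when hyperparameter selection is requested.
DEFAULT_GRID = {
    "n_estimators": [25, 50, 75, 100],
    "max_depth": [5, 10, 15, None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 5],
    "bootstrap": [True, False],
}


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters, split fraction and seed for one model."""

    n_estimators: int = 75
    max_depth: int = 15
    min_samples_split: int = 5
    min_samples_leaf: int = 1
    bootstrap: bool = False
    cv_folds: int = 3
    test_fraction: float = 0.10
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_estimators", "max_depth", "min_samples_split",
                     "min_samples_leaf", "cv_folds"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")


#: Preset configurations for the three study models.
MODEL_CONFIGS = {
    "disprot_codnas": ModelConfig(),
    "foldswitch": ModelConfig(),
    "combined": ModelConfig(
        n_estimators=25, min_samples_leaf=5, bootstrap=True, test_fraction=0.30
    ),
}


class ResidueClassForest(BaseEstimator, ClassifierMixin):
    """Random forest over the seven biophysical features.

    A thin scikit-learn estimator around :class:`RandomForestClassifier`
    that accepts feature tables (DataFrames with the seven feature
    columns) or plain arrays, records a JSON-serializable model card on
    fit, and optionally selects hyperparameters by 3-fold CV macro-F1
    over a grid.
    """

    def __init__(
        self,
        n_estimators: int = 75,
        max_depth: int | None = 15,
        min_samples_split: int = 5,
        min_samples_leaf: int = 1,
        bootstrap: bool = False,
        cv_folds: int = 3,
        seed: int = 42,
        param_grid: dict | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.bootstrap = bootstrap
        self.cv_folds = cv_folds
        self.seed = seed
        self.param_grid = param_grid

    @classmethod
    def from_config(cls, config: ModelConfig, param_grid: dict | None = None):
        return cls(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            min_samples_leaf=config.min_samples_leaf,
            bootstrap=config.bootstrap,
            cv_folds=config.cv_folds,
            seed=config.seed,
            param_grid=param_grid,
        )

    def _as_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"feature table missing columns: {missing}")
            matrix = X[FEATURE_COLUMNS].to_numpy(dtype=float)
            names = list(FEATURE_COLUMNS)
        else:
            matrix = np.asarray(X, dtype=float)
            if matrix.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = [f"f{i}" for i in range(matrix.shape[1])]
        if not np.isfinite(matrix).all():
            raise ValueError("features contain missing or non-finite values")
        return matrix, names

    def fit(self, X, y):
        matrix, names = self._as_matrix(X)
        y = np.asarray(y)
        if len(y) != len(matrix):
            raise ValueError("X and y have different lengths")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data must contain at least two classes")
        base = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
            random_state=self.seed,
        )
        cv_summary = None
        if self.param_grid is not None:
            search = GridSearchCV(
                base, self.param_grid, cv=self.cv_folds, scoring="f1_macro", n_jobs=1
            )
            search.fit(matrix, y)
            self.model_ = search.best_estimator_
            cv_summary = {
                "best_params": search.best_params_,
                "best_mean_cv_macro_f1": float(search.best_score_),
            }
        else:
            self.model_ = base.fit(matrix, y)
        self.classes_ = self.model_.classes_
        self.feature_names_ = names
        self.n_features_in_ = matrix.shape[1]
        self.model_card_ = {
            "hyperparameters": {
                "n_estimators": self.model_.n_estimators,
                "max_depth": self.model_.max_depth,
                "min_samples_split": self.model_.min_samples_split,
                "min_samples_leaf": self.model_.min_samples_leaf,
                "bootstrap": self.model_.bootstrap,
            },
            "seed": self.seed,
            "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
            "cv": cv_summary,
            "feature_names": names,
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        matrix, _ = self._as_matrix(X)
        return self.model_.predict(matrix)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        matrix, _ = self._as_matrix(X)
        return self.model_.predict_proba(matrix)

    @property
    def feature_importances_(self):
        check_is_fitted(self, "model_")
        return self.model_.feature_importances_


@dataclass
class ClassMetrics:
    """Per-class precision / recall / F1 with supports and confusion counts."""

    classes: list[str]
    support: dict[str, int]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        """Report-style table with half-up rounding to ``ndigits``."""
        rows = []
        for c in self.classes:
            rows.append(
                {
                    "label": c,
                    "number": self.support[c],
                    "precision": round_half_up(self.precision[c], ndigits),
                    "recall": round_half_up(self.recall[c], ndigits),
                    "f1": round_half_up(self.f1[c], ndigits),
                }
            )
        return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.625 -> 0.63 at 2 dp)."""
    factor = 10**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def split_dataset(table: pd.DataFrame, test_fraction: float, seed: int,
                  label_column: str = "label"):
    """Stratified train/test split of a labeled feature table.

    The test-set size is ``round(n * test_fraction)``; the partition is
    disjoint, exhaustive, stratified by class, and identical for identical
    seeds.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = table[label_column]
    counts = y.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 records cannot be split: {small}")
    n_test = int(round(len(table) * test_fraction))
    n_test = max(n_test, counts.size)  # stratification needs one test row per class
    train, test = train_test_split(
        table, test_size=n_test, random_state=seed, stratify=y, shuffle=True
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_classifier(train: pd.DataFrame, config: ModelConfig,
                     label_column: str = "label",
                     param_grid: dict | None = None) -> ResidueClassForest:
    """Fit a :class:`ResidueClassForest` on a labeled feature table."""
    model = ResidueClassForest.from_config(config, param_grid=param_grid)
    return model.fit(train, train[label_column].to_numpy())


def evaluate_classifier(model: ResidueClassForest, test: pd.DataFrame,
                        label_column: str = "label") -> ClassMetrics:
    """Per-class precision/recall/F1 and the confusion matrix on a test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    y_true = test[label_column].to_numpy()
    y_pred = model.predict(test)
    classes = [str(c) for c in model.classes_]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
    for c, p in zip(classes, precision):
        if p == 0.0 and (y_pred == c).sum() == 0:
            warnings.warn(f"class {c!r} has zero predicted positives; precision set to 0")
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return ClassMetrics(
        classes=classes,
        support={c: int(s) for c, s in zip(classes, support)},
        precision={c: float(p) for c, p in zip(classes, precision)},
        recall={c: float(r) for c, r in zip(classes, recall)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        confusion=cm,
    )


def feature_importance(model: ResidueClassForest) -> dict[str, float]:
    """Impurity-decrease feature importances, sorted descending (sum to 1)."""
    check_is_fitted(model, "model_")
    pairs = sorted(
        zip(model.feature_names_, model.feature_importances_),
        key=lambda kv: kv[1],
        reverse=True,
    )
    return {name: float(value) for name, value in pairs}


def predict_classes(model: ResidueClassForest, table: pd.DataFrame):
    """Predict per-residue classes and the class-fraction summary.

    Returns ``(predictions, fractions)``; on an empty table the fractions
    are ``None`` (undefined) rather than zeros.
    """
    if len(table) == 0:
        return np.array([], dtype=object), None
    predictions = model.predict(table)
    values, counts = np.unique(predictions, return_counts=True)
    fractions = {str(v): float(c) / len(predictions) for v, c in zip(values, counts)}
    return predictions, fractions
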