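"""RBF-SVM and SVM+gradient-boosting fusion classifiers.

The modelling surface follows the statsmodels convention: build a
:class:`SeaweedClassifier` from a feature table, call :meth:`fit`, and get
a :class:`ClassificationResults` object carrying the selected kernel
parameters, the cross-validation accuracy surface, prediction methods and
a ``summary()`` table.

The SVM is a soft-margin RBF support vector classifier with kernel width
``g`` (gamma) and penalty ``c``, tuned by exhaustive grid search with
stratified k-fold cross-validation (default 4 folds) on standardized
features; standardization statistics come from the training data only.
The fusion model soft-votes the tuned SVM with a gradient-boosted tree
classifier (fixed defaults: 300 trees, depth 3, learning rate 0.1):
ensemble probability = unweighted mean of the members' class
probabilities, predicted label = argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import VotingClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import OPTIMAL_SUBSET_8
from . import evaluate as _evaluate

__all__ = [
    "SplitSpec",
    "GridConfig",
    "SeaweedClassifier",
    "ClassificationResults",
    "split_train_test",
    "grid_search_svm",
    "train_fusion",
    "predict",
]

#: Fixed gradient-boosting hyperparameters (reported values do not exist,
#: so these are untuned library-style defaults).
BOOST_PARAMS = dict(n_estimators=300, max_depth=3, learning_rate=0.1)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 3:1, stratified by class)."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GridConfig:
    """Grid-search space over (g, c) and the CV fold count."""

    g_values: tuple[float, ...]
    c_values: tuple[float, ...]
    cv_folds: int = 4

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.g_values) or any(v <= 0 for v in self.c_values):
            raise ValueError("grid values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def coarse(cls, cv_folds: int = 4) -> "GridConfig":
        vals = tuple(np.round(np.arange(0.05, 10.0 + 1e-9, 0.25), 2))
        return cls(g_values=vals, c_values=vals, cv_folds=cv_folds)

    @classmethod
    def fine(cls, cv_folds: int = 4) -> "GridConfig":
        vals = tuple(np.round(np.arange(0.05, 10.0 + 1e-9, 0.05), 2))
        return cls(g_values=vals, c_values=vals, cv_folds=cv_folds)

    @classmethod
    def small(cls, cv_folds: int = 4) -> "GridConfig":
        """Tiny grid for quick subset evaluation inside elimination loops."""
        vals = (0.5, 1.0, 2.0, 4.0)
        return cls(g_values=vals, c_values=vals, cv_folds=cv_folds)


def split_train_test(
    table: pd.DataFrame,
    spec: SplitSpec = SplitSpec(),
    label_col: str = "species",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split of a feature table.

    Per-class train sizes are within 1 of ``train_fraction`` times the class
    count; membership is reproducible from ``spec.seed``.
    """
    counts = table[label_col].value_counts()
    if (counts < 2).any():
        singletons = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {singletons}")
    strat = table[label_col] if spec.stratified else None
    train, test = train_test_split(
        table,
        train_size=spec.train_fraction,
        stratify=strat,
        random_state=spec.seed,
        shuffle=True,
    )
    return train, test


def _svc(g: float, c: float, seed: int, probability: bool = False) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                SVC(
                    kernel="rbf",
                    gamma=g,
                    C=c,
                    probability=probability,
                    random_state=seed,
                    decision_function_shape="ovr",
                ),
            ),
        ]
    )


def grid_search_svm(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    grid: GridConfig,
    seed: int = 0,
) -> tuple[float, float, Pipeline, pd.DataFrame]:
    """Exhaustive (g, c) grid search by mean stratified-CV accuracy.

    Returns ``(best_g, best_c, fitted_model, cv_surface)`` where the model
    is refit on all supplied data with probability outputs enabled and the
    surface is a tidy DataFrame with columns ``g, c, cv_accuracy`` (%).
    Ties prefer the smallest ``c``, then the smallest ``g``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=grid.cv_folds, shuffle=False)
    rows = []
    best = None  # (score, c, g)
    for c in sorted(grid.c_values):
        for g in sorted(grid.g_values):
            scores = cross_val_score(_svc(g, c, seed), X, y, cv=cv, n_jobs=1)
            acc = 100.0 * float(np.mean(scores))
            rows.append({"g": g, "c": c, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, c, g)
    _, best_c, best_g = best
    model = _svc(best_g, best_c, seed, probability=True)
    model.fit(X, y)
    return float(best_g), float(best_c), model, pd.DataFrame(rows)


def train_fusion(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    g: float,
    c: float,
    seed: int = 0,
    boost_params: dict | None = None,
) -> Pipeline:
    """Soft-voting fusion of the tuned RBF-SVM and a gradient-boosted tree model."""
    params = dict(BOOST_PARAMS)
    if boost_params:
        params.update(boost_params)
    svm = SVC(
        kernel="rbf", gamma=g, C=c, probability=True, random_state=seed,
        decision_function_shape="ovr",
    )
    xgb = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **params)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", VotingClassifier([("svm", svm), ("xgb", xgb)], voting="soft")),
        ]
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model


def predict(
    model: Pipeline,
    X: np.ndarray | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class-probability matrix (rows sum to 1).

    Labels are the argmax of the probabilities; ties resolve to the
    smallest class index.  If ``feature_names`` is given and ``X`` is a
    DataFrame, the named columns are selected (extra columns are ignored;
    missing ones raise ``KeyError``).
    """
    if isinstance(X, pd.DataFrame) and feature_names is not None:
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = X[list(feature_names)]
    proba = model.predict_proba(np.asarray(X, dtype=float))
    classes = model.classes_
    labels = classes[np.argmax(proba, axis=1)]
    return labels, proba


class SeaweedClassifier:
    """Spectral-feature classifier model (statsmodels-style).

    Parameters
    ----------
    table : DataFrame
        Feature table with one row per sample (as produced by
        ``features.build_feature_table``); must contain ``label_col`` and
        the columns in ``feature_subset``.
    label_col : str
        ``"species"`` (6 classes) or ``"phylum"`` (3 classes).
    feature_subset : sequence of str, optional
        Input variables; defaults to the 8-variable optimal subset.
    kind : str
        ``"svm"`` or ``"fusion"``.
    grid : GridConfig, optional
        Grid-search space; defaults to the coarse grid (0.05-10 step 0.25,
        CV=4).
    seed : int
        Seeds CV shuffling-free fold assignment, probability calibration
        and the boosting member.

    Examples
    --------
    >>> model = SeaweedClassifier(train_table, label_col="phylum")
    >>> res = model.fit()
    >>> report = res.evaluate(test_table)
    >>> print(res.summary())
    """

    def __init__(
        self,
        table: pd.DataFrame,
        label_col: str = "species",
        feature_subset: Sequence[str] | None = None,
        kind: str = "svm",
        grid: GridConfig | None = None,
        seed: int = 0,
        boost_params: dict | None = None,
    ) -> None:
        if kind not in ("svm", "fusion"):
            raise ValueError(f"kind must be 'svm' or 'fusion', got {kind!r}")
        self.feature_subset = tuple(feature_subset or OPTIMAL_SUBSET_8)
        missing = [f for f in self.feature_subset if f not in table.columns]
        if missing:
            raise KeyError(f"feature table lacks columns: {missing}")
        if label_col not in table.columns:
            raise KeyError(f"feature table lacks label column {label_col!r}")
        complete = table[list(self.feature_subset)].notna().all(axis=1)
        self.table = table.loc[complete].reset_index(drop=True)
        self.n_dropped = int((~complete).sum())
        self.label_col = label_col
        self.kind = kind
        self.grid = grid or GridConfig.coarse()
        self.seed = seed
        self.boost_params = boost_params

    @property
    def endog(self) -> np.ndarray:
        return self.table[self.label_col].to_numpy()

    @property
    def exog(self) -> np.ndarray:
        return self.table[list(self.feature_subset)].to_numpy(dtype=float)

    def fit(self) -> "ClassificationResults":
        """Grid-search, refit on all training data, return results."""
        y = self.endog
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        g, c, model, surface = grid_search_svm(self.exog, y, self.grid, seed=self.seed)
        if self.kind == "fusion":
            model = train_fusion(
                self.exog, y, g=g, c=c, seed=self.seed, boost_params=self.boost_params
            )
        return ClassificationResults(model=self, g=g, c=c, estimator=model, cv_surface=surface)


@dataclass
class ClassificationResults:
    """Fitted classifier: tuned parameters, CV surface, prediction methods."""

    model: SeaweedClassifier
    g: float
    c: float
    estimator: Pipeline
    cv_surface: pd.DataFrame = field(repr=False)

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    @property
    def cv_accuracy(self) -> float:
        """Best mean CV accuracy (%) on the grid."""
        return float(self.cv_surface["cv_accuracy"].max())

    @property
    def standardization(self) -> dict[str, list[float]]:
        scaler: StandardScaler = self.estimator.named_steps["scale"]
        return {
            "mean": list(map(float, scaler.mean_)),
            "scale": list(map(float, scaler.scale_)),
        }

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        labels, _ = predict(self.estimator, table, feature_names=self.model.feature_subset)
        return labels

    def predict_proba(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        _, proba = predict(self.estimator, table, feature_names=self.model.feature_subset)
        return proba

    def evaluate(
        self, table: pd.DataFrame, y_true: Sequence | None = None
    ) -> "_evaluate.ClassifierReport":
        """Confusion matrix, accuracy and ROC report on held-out data."""
        if y_true is None:
            y_true = table[self.model.label_col].to_numpy()
        labels, proba = predict(self.estimator, table, feature_names=self.model.feature_subset)
        return _evaluate.classifier_report(
            np.asarray(y_true), labels, proba, class_order=list(self.classes_)
        )

    def summary(self) -> str:
        lines = [
            "Seaweed spectral classifier",
            "===========================",
            f"kind:            {self.model.kind}",
            f"label space:     {self.model.label_col} ({len(self.classes_)} classes)",
            f"features ({len(self.model.feature_subset)}):   "
            + ", ".join(self.model.feature_subset),
            f"n training:      {len(self.model.table)}"
            + (f" ({self.model.n_dropped} dropped incomplete)" if self.model.n_dropped else ""),
            f"best g (gamma):  {self.g:g}",
            f"best c (C):      {self.c:g}",
            f"CV accuracy:     {self.cv_accuracy:.2f}% "
            f"({self.model.grid.cv_folds}-fold, {len(self.cv_surface)} grid points)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.model.kind,
            "label_col": self.model.label_col,
            "classes": [str(c) for c in self.classes_],
            "feature_subset": list(self.model.feature_subset),
            "g": self.g,
            "c": self.c,
            "cv_accuracy": self.cv_accuracy,
            "cv_folds": self.model.grid.cv_folds,
            "seed": self.model.seed,
            "standardization": self.standardization,
        }
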