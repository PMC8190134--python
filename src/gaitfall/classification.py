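"""Per-speed fall-risk classification with a gradient-boosted tree ensemble.

The learner minimizes a logistic loss over an additive tree ensemble with a
per-leaf split penalty; it is provided by scikit-learn's
``GradientBoostingClassifier`` (staged additive trees, logistic deviance,
impurity-gain importances).  The leaf-count penalty maps to
``min_impurity_decrease``; an L2 leaf-weight penalty is not exposed by this
backend and is recorded but inert (see ``ModelConfig.l2_leaf_penalty``).

Protocol: stratified 70/30 train/holdout split; 10-fold cross-validation on
the training split only for model selection; min-max scaling fit on training
data; demographic covariates (age, sex, BMI, education, physical activity)
enter every model alongside the nine gait variables of one speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from gaitfall.errors import DataError, ParameterError, SchemaError
from gaitfall.synthetic import GAIT_VARIABLES

COVARIATES = ("age", "sex", "bmi", "education_level", "pa_met_min_wk")
LABEL_COLUMN = "risk_label"


def feature_columns(speed: str) -> list[str]:
    """The 14 predictors of one speed's model: 9 gait variables + covariates."""
    return [f"{speed}_{v}" for v in GAIT_VARIABLES] + list(COVARIATES)


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    leaf_penalty: float = 0.0        # gamma: per-split gain threshold
    l2_leaf_penalty: float = 1.0     # lambda: recorded; not used by backend
    train_fraction: float = 0.7
    cv_folds: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.leaf_penalty < 0 or self.l2_leaf_penalty < 0:
            raise ParameterError("penalties must be non-negative")
        if self.n_trees < 1 or self.max_depth < 1:
            raise ParameterError("n_trees and max_depth must be >= 1")


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MinMaxScaler:
    """Per-feature affine map to [0, 1] fit on training data.  Constant
    features are flagged and mapped to 0; test values may leave [0, 1]."""

    feature_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    @property
    def constant_features(self) -> tuple[str, ...]:
        return tuple(n for n, lo, hi in
                     zip(self.feature_names, self.minima, self.maxima)
                     if hi == lo)


def minmax_scale_fit(train: pd.DataFrame) -> MinMaxScaler:
    if len(train) == 0:
        raise DataError("cannot fit a scaler on an empty table")
    values = train.to_numpy(dtype=float)
    return MinMaxScaler(feature_names=tuple(train.columns),
                        minima=values.min(axis=0), maxima=values.max(axis=0))


def minmax_scale_apply(scaler: MinMaxScaler, features: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in scaler.feature_names if c not in features.columns]
    if missing:
        raise SchemaError(f"missing feature(s): {', '.join(missing)}")
    x = features[list(scaler.feature_names)].to_numpy(dtype=float)
    span = scaler.maxima - scaler.minima
    safe = np.where(span == 0, 1.0, span)
    scaled = (x - scaler.minima) / safe
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, columns=scaler.feature_names,
                        index=features.index)


# ---------------------------------------------------------------------------
# split / cross-validate / train
# ---------------------------------------------------------------------------


def split_train_test(cohort: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int = 0, stratified: bool = True,
                     label_column: str = LABEL_COLUMN
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/holdout partition, stratified by label."""
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie in (0, 1)")
    if len(cohort) < 10:
        raise DataError("cohort too small to split (need >= 10 records)")
    stratify = cohort[label_column] if stratified else None
    train, test = train_test_split(cohort, train_size=train_fraction,
                                   random_state=seed, stratify=stratify)
    return train, test


@dataclass(frozen=True)
class TrainedModel:
    estimator: GradientBoostingClassifier
    scaler: MinMaxScaler
    config: ModelConfig
    feature_names: tuple[str, ...]
    importances: dict[str, float]

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        scaled = minmax_scale_apply(self.scaler, features)
        return self.estimator.predict_proba(scaled.to_numpy())[:, 1]


def _make_estimator(config: ModelConfig) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        min_impurity_decrease=config.leaf_penalty,
        random_state=config.seed,
    )


def train_model(train: pd.DataFrame, config: ModelConfig,
                feature_names: Sequence[str],
                label_column: str = LABEL_COLUMN) -> TrainedModel:
    """Fit scaler + ensemble on the training table; importances are gain."""
    missing = [c for c in feature_names if c not in train.columns]
    if missing:
        raise SchemaError(f"missing feature(s): {', '.join(missing)}")
    y = train[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise DataError("training set contains a single class")
    scaler = minmax_scale_fit(train[list(feature_names)])
    x = minmax_scale_apply(scaler, train).to_numpy()
    est = _make_estimator(config).fit(x, y)
    importances = dict(zip(feature_names, est.feature_importances_))
    return TrainedModel(estimator=est, scaler=scaler, config=config,
                        feature_names=tuple(feature_names),
                        importances=importances)


def cross_validate(train: pd.DataFrame,
                   configs: ModelConfig | Iterable[ModelConfig],
                   feature_names: Sequence[str],
                   label_column: str = LABEL_COLUMN) -> dict:
    """K-fold CV (training data only) over candidate configs; selects the
    best mean AUC, breaking ties toward fewer trees, then shallower."""
    if isinstance(configs, ModelConfig):
        configs = [configs]
    configs = list(configs)
    folds = configs[0].cv_folds
    if len(train) < folds:
        raise ParameterError(
            f"cv_folds={folds} exceeds the {len(train)} training records")
    y = train[label_column].to_numpy()
    results = []
    for config in configs:
        kf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                             random_state=config.seed)
        aucs = []
        for tr_idx, va_idx in kf.split(train, y):
            tr, va = train.iloc[tr_idx], train.iloc[va_idx]
            model = train_model(tr, config, feature_names, label_column)
            scores = model.predict_scores(va[list(feature_names)])
            aucs.append(roc_auc_score(va[label_column], scores))
        results.append({"config": config, "mean_auc": float(np.mean(aucs)),
                        "sd_auc": float(np.std(aucs, ddof=1)),
                        "fold_aucs": [float(a) for a in aucs]})
    best = max(results,
               key=lambda r: (r["mean_auc"], -r["config"].n_trees,
                              -r["config"].max_depth))
    return {"candidates": results, "selected": best["config"],
            "selected_mean_auc": best["mean_auc"]}


def predict_risk(model: TrainedModel, features: pd.DataFrame
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted probabilities and labels (1 = high risk at score >= threshold)."""
    scores = model.predict_scores(features)
    labels = (scores >= model.config.threshold).astype(int)
    return scores, labels


def feature_importance_ranking(model: TrainedModel, top_k: int | None = None,
                               normalize: bool = False
                               ) -> list[tuple[str, float]]:
    """Features ordered by descending gain; alphabetical tie-break."""
    items = sorted(model.importances.items(), key=lambda kv: (-kv[1], kv[0]))
    if normalize:
        total = sum(v for _, v in items)
        if total > 0:
            items = [(k, v / total) for k, v in items]
    return items[:top_k] if top_k is not None else items


def default_config_grid(seed: int = 0) -> list[ModelConfig]:
    """Small documented hyperparameter grid searched by cross-validation."""
    grid = []
    for n_trees in (100, 200):
        for max_depth in (2, 3):
            grid.append(ModelConfig(n_trees=n_trees, max_depth=max_depth,
                                    seed=seed))
    return grid
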