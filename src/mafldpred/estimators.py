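"""Shared classifier/regressor registries and default hyperparameter grids.

Two classifier families are used in the pipeline: the eight *missingness*
classifiers (predicting whether a cell is missing from the other columns) and
the eight *outcome* classifiers (predicting MAFLD).  The families overlap but
are not identical — the missingness family includes random forest and
AdaBoost, the outcome family includes gradient boosting and LightGBM.

Grids are compact, literature-standard defaults and are overridable through
every public entry point that consumes them.
"""

from __future__ import annotations

import warnings
from typing import Mapping

from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

try:  # both are in the declared dependencies; guard only for lazy import cost
    from xgboost import XGBClassifier, XGBRegressor
except ImportError:  # pragma: no cover
    XGBClassifier = XGBRegressor = None
try:
    from lightgbm import LGBMClassifier
except ImportError:  # pragma: no cover
    LGBMClassifier = None

# probability=True remains the uniform way to expose SVC scores across the
# classifier registry; silence sklearn's deprecation chatter at fit time
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated", category=FutureWarning
)


class UnknownMethodError(KeyError):
    pass


def _scaled(est) -> Pipeline:
    # distance/margin-based models need standardized inputs
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def make_classifier(classifier_id: str, seed: int = 0, **params):
    """Instantiate a classifier by id with sensible fixed settings."""
    if classifier_id == "logistic_regression":
        return _scaled(LogisticRegression(max_iter=2000, random_state=seed, **params))
    if classifier_id == "k_nearest_neighbors":
        return _scaled(KNeighborsClassifier(**params))
    if classifier_id == "support_vector_machine":
        return _scaled(SVC(probability=True, random_state=seed, **params))
    if classifier_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if classifier_id == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if classifier_id == "extra_trees":
        params.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=seed, **params)
    if classifier_id == "adaptive_boosting":
        return AdaBoostClassifier(random_state=seed, **params)
    if classifier_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if classifier_id == "extreme_gradient_boosting":
        params.setdefault("n_estimators", 100)
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
            n_jobs=1,
            **params,
        )
    if classifier_id == "light_gradient_boosting":
        params.setdefault("n_estimators", 100)
        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **params)
    raise UnknownMethodError(classifier_id)


#: the eight candidate models for per-column missingness prediction
MISSINGNESS_CLASSIFIERS = (
    "logistic_regression",
    "k_nearest_neighbors",
    "support_vector_machine",
    "decision_tree",
    "random_forest",
    "extra_trees",
    "adaptive_boosting",
    "extreme_gradient_boosting",
)

#: the eight outcome classifiers (four basic + four ensemble)
OUTCOME_CLASSIFIERS = (
    "logistic_regression",
    "k_nearest_neighbors",
    "support_vector_machine",
    "decision_tree",
    "extra_trees",
    "gradient_boosting",
    "extreme_gradient_boosting",
    "light_gradient_boosting",
)

#: compact default grids, shared by both families where ids overlap
DEFAULT_GRIDS: Mapping[str, list[dict]] = {
    "logistic_regression": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "k_nearest_neighbors": [{"n_neighbors": k} for k in (3, 5, 11)],
    "support_vector_machine": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "decision_tree": [{"max_depth": d} for d in (3, 5, 10)],
    "random_forest": [
        {"n_estimators": 100, "max_depth": d} for d in (5, 10, None)
    ],
    "extra_trees": [{"n_estimators": 100, "max_depth": d} for d in (5, 10, None)],
    "adaptive_boosting": [{"n_estimators": n} for n in (50, 100)],
    "gradient_boosting": [
        {"n_estimators": 100, "max_depth": d} for d in (2, 3)
    ],
    "extreme_gradient_boosting": [
        {"n_estimators": 100, "max_depth": d, "learning_rate": 0.1}
        for d in (3, 5)
    ],
    "light_gradient_boosting": [
        {"n_estimators": 100, "max_depth": d} for d in (3, 5, -1)
    ],
}

#: single-configuration grids for quick runs (count/shape checks, demos)
TINY_GRIDS: Mapping[str, list[dict]] = {
    "logistic_regression": [{"C": 1.0}],
    "k_nearest_neighbors": [{"n_neighbors": 5}],
    "support_vector_machine": [{"C": 1.0}],
    "decision_tree": [{"max_depth": 5}],
    "random_forest": [{"n_estimators": 30, "max_depth": 5}],
    "extra_trees": [{"n_estimators": 30, "max_depth": 5}],
    "adaptive_boosting": [{"n_estimators": 30}],
    "gradient_boosting": [{"n_estimators": 30, "max_depth": 2}],
    "extreme_gradient_boosting": [{"n_estimators": 30, "max_depth": 3}],
    "light_gradient_boosting": [{"n_estimators": 30, "max_depth": 3}],
}


def make_regressor(estimator_id: str, seed: int = 0, **params):
    """Regressor families used inside chained-equations imputation."""
    if estimator_id == "ridge":
        return Ridge(**params)
    if estimator_id == "svm":
        params.setdefault("kernel", "rbf")
        return SVR(**params)
    if estimator_id == "tree":
        params.setdefault("max_depth", 10)
        return DecisionTreeRegressor(random_state=seed, **params)
    if estimator_id == "random_forest":
        params.setdefault("n_estimators", 30)
        params.setdefault("max_depth", 10)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if estimator_id == "extra_trees":
        params.setdefault("n_estimators", 30)
        params.setdefault("max_depth", 10)
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    if estimator_id == "adaboost":
        params.setdefault("n_estimators", 30)
        return AdaBoostRegressor(random_state=seed, **params)
    if estimator_id == "gbdt":
        params.setdefault("n_estimators", 50)
        params.setdefault("max_depth", 3)
        return XGBRegressor(random_state=seed, verbosity=0, n_jobs=1, **params)
    raise UnknownMethodError(estimator_id)
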