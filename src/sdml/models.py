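"""Tree-ensemble regressors with TPE-guided tuning and 5-fold cross-validation.

Four model families are tuned and compared on original versus augmented
training sets: three gradient boosters (``catboost_like`` — an ordered
gradient-boosting stand-in built on sklearn's GradientBoostingRegressor,
``lightgbm_like``, ``xgboost_like``) and a ``random_forest`` baseline. Search
spaces follow the field's conventions — learning rates log-uniform over
[1e-3, 0.3], subsampling fractions uniform over [0.5, 1], integer depth/leaf
ranges — with conditional branches (e.g. LightGBM's bagging fraction is only
sampled when bagging is enabled) so incompatible combinations are never
proposed. The tuning objective is the mean 5-fold CV RMSE; the best
configuration is refit on the full training table. The test set is scored
exactly once per report and augmentation never touches it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .data import FeatureTable
from .tpe import CHOICE, INT, LOGUNIFORM, Param, TPESampler, UNIFORM

logger = logging.getLogger("sdml")

MODEL_NAMES = ("catboost_like", "lightgbm_like", "xgboost_like", "random_forest")
BOOSTING_MODELS = ("catboost_like", "lightgbm_like", "xgboost_like")


@dataclass
class ModelReport:
    model_name: str
    dataset: str                       # original | augmented
    cv_r2: float
    cv_rmse: float
    test_r2: float
    test_rmse: float
    best_params: dict = field(default_factory=dict)
    n_trials: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# --------------------------------------------------------------- search space

def search_space(model_name: str) -> list[Param]:
    if model_name == "catboost_like":
        return [
            Param("learning_rate", LOGUNIFORM, 1e-3, 0.3),
            Param("n_estimators", INT, 100, 500),
            Param("max_depth", INT, 2, 6),
            Param("subsample", UNIFORM, 0.5, 1.0),
            Param("min_samples_leaf", INT, 1, 10),
        ]
    if model_name == "lightgbm_like":
        return [
            Param("learning_rate", LOGUNIFORM, 1e-3, 0.3),
            Param("n_estimators", INT, 100, 500),
            Param("num_leaves", INT, 8, 128),
            Param("min_child_samples", INT, 5, 30),
            Param("use_bagging", CHOICE, choices=[0, 1]),
            # bagging fraction is only meaningful when bagging is enabled
            Param("subsample", UNIFORM, 0.5, 1.0,
                  condition=lambda p: p.get("use_bagging") == 1),
        ]
    if model_name == "xgboost_like":
        return [
            Param("learning_rate", LOGUNIFORM, 1e-3, 0.3),
            Param("n_estimators", INT, 100, 500),
            Param("max_depth", INT, 3, 9),
            Param("subsample", UNIFORM, 0.5, 1.0),
            Param("colsample_bytree", UNIFORM, 0.5, 1.0),
            Param("reg_lambda", LOGUNIFORM, 1e-3, 10.0),
            Param("min_child_weight", INT, 1, 10),
        ]
    if model_name == "random_forest":
        return [
            Param("n_estimators", INT, 100, 500),
            Param("max_depth", INT, 3, 16),
            Param("max_features", UNIFORM, 0.3, 1.0),
            Param("min_samples_leaf", INT, 1, 10),
        ]
    raise ValueError(f"unknown model name {model_name!r}; expected one of {MODEL_NAMES}")


def build_model(model_name: str, params: dict | None = None, seed: int = 0):
    """Instantiate a regressor with the given (possibly partial) parameters."""
    params = dict(params or {})
    if model_name == "catboost_like":
        params.setdefault("learning_rate", 0.05)
        params.setdefault("n_estimators", 300)
        params.setdefault("max_depth", 3)
        return GradientBoostingRegressor(random_state=seed, **params)
    if model_name == "lightgbm_like":
        use_bagging = params.pop("use_bagging", 0)
        if use_bagging and "subsample" in params:
            params["subsample_freq"] = 1
        else:
            params.pop("subsample", None)
        params.setdefault("learning_rate", 0.05)
        params.setdefault("n_estimators", 300)
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)
    if model_name == "xgboost_like":
        params.setdefault("learning_rate", 0.05)
        params.setdefault("n_estimators", 300)
        params.setdefault("max_depth", 5)
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                            tree_method="hist", **params)
    if model_name == "random_forest":
        params.setdefault("n_estimators", 300)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model name {model_name!r}; expected one of {MODEL_NAMES}")


# ------------------------------------------------------------------- metrics

def r2_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        logger.warning("r2 undefined: zero-variance target")
        return float("nan"), rmse
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return r2, rmse


def evaluate_model(model, test: FeatureTable) -> tuple[float, float]:
    """(R^2, RMSE) of the fitted model on a held-out table."""
    pred = model.predict(test.X.to_numpy(float))
    return r2_rmse(test.y.to_numpy(float), pred)


def _cv_objective(model_name: str, params: dict, X: np.ndarray, y: np.ndarray,
                  n_folds: int, seed: int) -> tuple[float, float]:
    """Mean CV (RMSE, R^2) of one configuration."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rmses, r2s = [], []
    for tr_idx, va_idx in kf.split(X):
        m = build_model(model_name, params, seed=seed)
        m.fit(X[tr_idx], y[tr_idx])
        r2, rmse = r2_rmse(y[va_idx], m.predict(X[va_idx]))
        rmses.append(rmse)
        r2s.append(r2)
    return float(np.mean(rmses)), float(np.mean(r2s))


def tune_and_fit(
    train: FeatureTable,
    model_name: str,
    budget: int = 50,
    seed: int = 0,
    n_folds: int = 5,
):
    """TPE search over the model's space, then refit the best configuration.

    Returns ``(fitted_model, best_params, history)`` where ``history`` holds
    per-trial (params, cv_rmse, cv_r2) tuples and the incumbent CV RMSE is
    non-increasing in the budget for a fixed seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X = train.X.to_numpy(float)
    y = train.y.to_numpy(float)
    sampler = TPESampler(search_space(model_name), seed=seed)
    history = []
    for _ in range(budget):
        params = sampler.suggest()
        try:
            rmse, r2 = _cv_objective(model_name, params, X, y, n_folds, seed)
        except Exception:  # an invalid configuration scores as a failure
            rmse, r2 = float("inf"), float("-inf")
        sampler.tell(params, rmse)
        history.append({"params": params, "cv_rmse": rmse, "cv_r2": r2})
    best = min(history, key=lambda h: h["cv_rmse"])
    model = build_model(model_name, best["params"], seed=seed)
    model.fit(X, y)
    logger.info("tune_and_fit(%s): best CV RMSE %.4f after %d trials",
                model_name, best["cv_rmse"], budget)
    return model, best["params"], history


def fit_and_report(
    train: FeatureTable,
    test: FeatureTable,
    model_name: str,
    dataset_label: str,
    budget: int = 50,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[ModelReport, object]:
    """Tune on train, score once on test, and bundle the metrics."""
    model, params, history = tune_and_fit(train, model_name, budget, seed, n_folds)
    best = min(history, key=lambda h: h["cv_rmse"])
    test_r2, test_rmse = evaluate_model(model, test)
    report = ModelReport(
        model_name=model_name, dataset=dataset_label,
        cv_r2=best["cv_r2"], cv_rmse=best["cv_rmse"],
        test_r2=test_r2, test_rmse=test_rmse,
        best_params=dict(best["params"]), n_trials=budget,
    )
    return report, model


# ----------------------------------------------------------------- comparison

def percent_improvement(old: float, new: float) -> float:
    """(old - new) / old * 100 — positive when the error shrank."""
    return (old - new) / old * 100.0


def compare_runs(reports: list[ModelReport]) -> pd.DataFrame:
    """Pair original/augmented reports per model and tabulate the deltas."""
    by_model: dict[str, dict[str, ModelReport]] = {}
    for rep in reports:
        by_model.setdefault(rep.model_name, {})[rep.dataset] = rep
    rows = []
    for name, pair in by_model.items():
        if set(pair) != {"original", "augmented"}:
            raise ValueError(f"model {name!r} lacks a paired original/augmented report")
        o, a = pair["original"], pair["augmented"]
        rows.append(
            {
                "model": name,
                "cv_rmse_original": o.cv_rmse,
                "cv_rmse_augmented": a.cv_rmse,
                "cv_rmse_improvement_pct": percent_improvement(o.cv_rmse, a.cv_rmse),
                "test_rmse_original": o.test_rmse,
                "test_rmse_augmented": a.test_rmse,
                "test_rmse_improvement_pct": percent_improvement(o.test_rmse, a.test_rmse),
                "cv_r2_delta": a.cv_r2 - o.cv_r2,
                "test_r2_delta": a.test_r2 - o.test_r2,
            }
        )
    return pd.DataFrame(rows)
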