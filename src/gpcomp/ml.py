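"""Grid-search-tuned machine-learning regressors behind one interface.

Methods: support vector regression (``svr``), random forest (``rf``),
kernel ridge regression (``krr``), and gradient-boosted trees (``xgb``).
Tuning is an explicit inner 5-fold loop scored by Pearson correlation on
the training fold only, so the outer validation fold is never touched
during model selection.

The gradient-boosting method is backed by scikit-learn's
HistGradientBoostingRegressor (same algorithm family as XGBoost,
available offline).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from gpcomp.errors import ConfigurationError, ConsistencyError, InputError

logger = logging.getLogger(__name__)

METHODS = ("svr", "rf", "krr", "xgb")


@dataclass
class MLConfig:
    method: str = "krr"
    grid: dict = field(default_factory=dict)  # empty -> default grid
    inner_cv_folds: int = 5
    seed: int = 0
    selection_metric: str = "pearson"  # or "neg_mse"

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown method {self.method!r}; choose from {METHODS}"
            )
        if self.inner_cv_folds < 2:
            raise ConfigurationError("inner_cv_folds must be >= 2")
        defaults = default_grids()[self.method]
        merged = dict(defaults)
        merged.update(self.grid or {})
        unknown = set(merged) - set(defaults)
        if unknown:
            raise ConfigurationError(f"unknown grid keys {sorted(unknown)}")
        if any(len(v) == 0 for v in merged.values()):
            raise ConfigurationError("grid lists must be non-empty")
        self.grid = merged


def default_grids() -> dict[str, dict[str, list]]:
    """Per-method hyperparameter grids (the tuned search space)."""
    return {
        "svr": {
            "C": [0.1, 1.0, 10.0],
            "gamma": ["scale", 0.01],
            "epsilon": [0.01, 0.1],
        },
        "rf": {
            "n_estimators": [200, 500],
            "max_depth": [None, 10],
            "max_features": [0.3, "sqrt"],
        },
        "krr": {
            "alpha": [0.01, 0.1, 1.0, 10.0],
            "kernel": ["linear", "rbf"],
        },
        "xgb": {
            "learning_rate": [0.05, 0.1],
            "max_depth": [3, 6],
            "max_iter": [200, 400],
        },
    }


def _make_estimator(method: str, params: dict, seed: int):
    if method == "svr":
        return SVR(**params)
    if method == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if method == "krr":
        return KernelRidge(**params)
    if method == "xgb":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    raise ConfigurationError(f"unknown method {method!r}")


def _score(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    if metric == "neg_mse":
        return -float(np.mean((y_true - y_pred) ** 2))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return -np.inf  # constant predictions cannot win on correlation
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def tune(
    cfg: MLConfig, train_features: np.ndarray, train_y: np.ndarray
) -> tuple[dict, list[dict]]:
    """Inner-CV grid search on the training fold; returns (best, log)."""
    keys = sorted(cfg.grid)
    candidates = [
        dict(zip(keys, combo))
        for combo in itertools.product(*(cfg.grid[k] for k in keys))
    ]
    kf = KFold(n_splits=cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(kf.split(train_features))
    log: list[dict] = []
    best: tuple[float, dict] | None = None
    for params in candidates:
        scores = []
        try:
            for tr, va in splits:
                est = _make_estimator(cfg.method, params, cfg.seed)
                est.fit(train_features[tr], train_y[tr])
                scores.append(
                    _score(train_y[va], est.predict(train_features[va]),
                           cfg.selection_metric)
                )
            mean_score = float(np.mean(scores))
        except Exception as exc:  # a bad grid point is logged, not fatal
            logger.warning("grid point %s failed: %s", params, exc)
            log.append({"params": params, "error": str(exc)})
            continue
        log.append({"params": params, "score": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, params)
    if best is None:
        raise ConfigurationError("every grid point failed")
    return best[1], log


def fit_predict(
    cfg: MLConfig,
    train_features: np.ndarray,
    train_y: np.ndarray,
    predict_features: np.ndarray,
) -> np.ndarray:
    """Tune on the training fold, refit the winner, predict new rows."""
    train_features = np.asarray(train_features, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    predict_features = np.asarray(predict_features, dtype=float)
    if train_features.shape[1] != predict_features.shape[1]:
        raise ConsistencyError("train and predict feature widths differ")
    if np.isnan(train_features).any() or np.isnan(train_y).any():
        raise InputError("missing values in training data")
    if np.var(train_y) == 0:
        raise InputError("training phenotype has zero variance")
    best_params, _ = tune(cfg, train_features, train_y)
    est = _make_estimator(cfg.method, best_params, cfg.seed)
    est.fit(train_features, train_y)
    return np.asarray(est.predict(predict_features), dtype=float)
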