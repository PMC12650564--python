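"""Prediction metrics and repeated k-fold cross-validation.

Metrics on a validation fold: accuracy (Pearson correlation between
phenotype and GEBV), bias (absolute deviation from 1 of the regression
of phenotype on GEBV), mean squared error, and mean absolute error.
Aggregation is per-fold-then-averaged by default; pooled values over the
concatenated validation predictions are reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from gpcomp.errors import ConfigurationError, ConsistencyError, InputError

METRIC_NAMES = ("accuracy", "bias", "mse", "mae")


def accuracy(y: np.ndarray, gebv: np.ndarray) -> float:
    """Sample Pearson correlation between phenotype and GEBV."""
    y, gebv = _check_pair(y, gebv)
    if y.size < 3:
        raise InputError("need at least 3 pairs for a correlation")
    # ptp catches exactly-constant vectors whose float std may not be 0
    if np.ptp(y) == 0 or np.ptp(gebv) == 0 or np.std(y) == 0 or np.std(gebv) == 0:
        raise InputError("accuracy undefined: zero variance input")
    return float(np.corrcoef(y, gebv)[0, 1])


def bias(y: np.ndarray, gebv: np.ndarray) -> float:
    """|1 - cov(y, gebv)/var(gebv)|: dispersion bias of the GEBVs."""
    y, gebv = _check_pair(y, gebv)
    var_g = float(np.var(gebv, ddof=1))
    if var_g == 0 or np.ptp(gebv) == 0:
        raise InputError("bias undefined: GEBV variance is zero")
    cov = float(np.cov(y, gebv, ddof=1)[0, 1])
    return abs(1.0 - cov / var_g)


def mse(y: np.ndarray, gebv: np.ndarray) -> float:
    y, gebv = _check_pair(y, gebv)
    return float(np.mean((y - gebv) ** 2))


def mae(y: np.ndarray, gebv: np.ndarray) -> float:
    y, gebv = _check_pair(y, gebv)
    return float(np.mean(np.abs(y - gebv)))


def coefficient_of_variation(mean: float, sd: float, ndigits: int = 3) -> float:
    """100 * sd / mean, rounded; summary-statistic helper."""
    if mean == 0:
        raise InputError("coefficient of variation undefined for zero mean")
    return round(100.0 * sd / mean, ndigits)


def _check_pair(y, gebv) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    gebv = np.asarray(gebv, dtype=float).ravel()
    if y.size != gebv.size:
        raise ConsistencyError(f"length mismatch: {y.size} vs {gebv.size}")
    return y, gebv


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVScheme:
    """Repeated k-fold assignment; folds depend only on (seed, repeat)."""

    k_folds: int = 5
    repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2 or self.repeats < 1:
            raise ConfigurationError("need k_folds >= 2 and repeats >= 1")

    def assignments(self, n_individuals: int) -> np.ndarray:
        """repeats x n array of fold ids in [0, k_folds)."""
        if n_individuals < self.k_folds:
            raise ConfigurationError("fewer individuals than folds")
        out = np.empty((self.repeats, n_individuals), dtype=np.int64)
        for rep in range(self.repeats):
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, rep]))
            base = np.arange(n_individuals) % self.k_folds
            out[rep] = rng.permutation(base)
        return out


class FoldPredictor(Protocol):
    """Fit on training individuals, predict the validation individuals.

    Called once per (repeat, fold) with row indices into the full data;
    must return predictions aligned to ``test_idx``.  GBLUP-style
    predictors may use all genotypes and mask only phenotypes.
    """

    def __call__(
        self, features: np.ndarray, y: np.ndarray,
        train_idx: np.ndarray, test_idx: np.ndarray,
    ) -> np.ndarray: ...


def supervised_predictor(
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
) -> FoldPredictor:
    """Adapt a plain fit(X, y) -> predict(X') function to the fold contract."""

    def _predict(features, y, train_idx, test_idx):
        return fit_predict(features[train_idx], y[train_idx], features[test_idx])

    return _predict


@dataclass
class MetricsReport:
    """Per-fold metric table plus per-fold-averaged and pooled summaries."""

    folds: pd.DataFrame  # columns: repeat, fold, accuracy, bias, mse, mae
    pooled: pd.DataFrame  # per-repeat metrics over concatenated predictions
    predictor: str = ""
    config: dict = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = self.folds[name].dropna()
            out[name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "pooled_mean": float(self.pooled[name].mean()),
            }
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictor": self.predictor,
                "config": self.config,
                "summary": self.summary(),
                "n_folds": int(len(self.folds)),
            },
            indent=2,
        )


def cross_validate(
    predictor: FoldPredictor,
    features: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme | None = None,
    predictor_name: str = "",
) -> MetricsReport:
    """Repeated k-fold CV of any fold predictor.

    Each repeat partitions individuals into ``k_folds`` validation
    folds; metrics are computed per fold and also pooled per repeat.  A
    fold where accuracy/bias are undefined (constant predictions)
    records NaN for those metrics rather than failing the run.
    """
    scheme = scheme or CVScheme()
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if features.shape[0] != y.size:
        raise ConsistencyError("features and phenotypes are misaligned")
    if np.isnan(y).any():
        raise InputError("cross-validation requires complete phenotypes")
    n = y.size
    assign = scheme.assignments(n)
    if min(np.bincount(assign[0], minlength=scheme.k_folds)) < 3:
        raise ConfigurationError("a fold has fewer than 3 validation individuals")

    rows = []
    pooled_rows = []
    for rep in range(scheme.repeats):
        rep_pred = np.empty(n)
        for fold in range(scheme.k_folds):
            test_idx = np.flatnonzero(assign[rep] == fold)
            train_idx = np.flatnonzero(assign[rep] != fold)
            yhat = np.asarray(
                predictor(features, y, train_idx, test_idx), dtype=float
            )
            if yhat.shape != (test_idx.size,):
                raise ConsistencyError("predictor returned wrong-length output")
            rep_pred[test_idx] = yhat
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    **_fold_metrics(y[test_idx], yhat),
                }
            )
        pooled_rows.append({"repeat": rep, **_fold_metrics(y, rep_pred)})
    return MetricsReport(
        pd.DataFrame(rows), pd.DataFrame(pooled_rows), predictor_name,
        {"k_folds": scheme.k_folds, "repeats": scheme.repeats, "seed": scheme.seed},
    )


def _fold_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {"mse": mse(y, yhat), "mae": mae(y, yhat)}
    try:
        out["accuracy"] = accuracy(y, yhat)
    except InputError:
        out["accuracy"] = float("nan")
    try:
        out["bias"] = bias(y, yhat)
    except InputError:
        out["bias"] = float("nan")
    return out
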