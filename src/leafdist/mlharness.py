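"""Regression-mode classifiers over distribution profiles, with 10-fold CV.

Four scikit-learn families are run in regression mode against 0/1 nitrogen
treatment labels: AdaBoost, logistic regression (its class-1 probability is
the continuous prediction), PLSR, and random forest.  One hyperparameter per
family is grid-searched by cross-validated RMSE (ties break to the smallest
candidate, preferring the simpler model), and out-of-fold continuous
predictions are retained — they feed the downstream t-test, so they are never
thresholded.  Folds come from a seeded shuffle; every sample is validated
exactly once and fold sizes differ by at most one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from .profile import CohortDataset

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "TUNED_PARAMS",
    "ModelSpec",
    "CVResult",
    "assign_folds",
    "grid_search",
    "crossval_predict",
    "fit_predict",
]

FAMILIES = ("adaboost", "logistic", "plsr", "random_forest")

# One searched hyperparameter per family: the dominant capacity knob.
TUNED_PARAMS = {
    "adaboost": "n_estimators",
    "logistic": "C",
    "plsr": "n_components",
    "random_forest": "max_depth",
}
DEFAULT_GRIDS = {
    "adaboost": [10, 25, 50, 100, 200],
    "logistic": [0.01, 0.1, 1.0, 10.0, 100.0],
    "plsr": list(range(1, 11)),
    "random_forest": list(range(1, 11)),
}


@dataclass
class ModelSpec:
    family: str
    tuned_param: str | None = None
    grid: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.tuned_param is None:
            self.tuned_param = TUNED_PARAMS[self.family]
        if not self.grid:
            self.grid = list(DEFAULT_GRIDS[self.family])


@dataclass
class CVResult:
    oof_predictions: np.ndarray
    fold_assignment: np.ndarray
    rmse_per_fold: np.ndarray
    mean_rmse: float
    best_param: float
    family: str = ""
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "family": self.family,
                "seed": self.seed,
                "best_param": self.best_param,
                "mean_rmse": self.mean_rmse,
                "rmse_per_fold": list(map(float, self.rmse_per_fold)),
                "fold_assignment": list(map(int, self.fold_assignment)),
                "oof_predictions": list(map(float, self.oof_predictions)),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _make_model(family: str, value, seed: int):
    if family == "random_forest":
        return RandomForestRegressor(max_depth=int(value), random_state=seed)
    if family == "adaboost":
        return AdaBoostRegressor(n_estimators=int(value), random_state=seed)
    if family == "plsr":
        return PLSRegression(n_components=int(value))
    return LogisticRegression(C=float(value), max_iter=1000)


def _predict(family: str, model, X: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return model.predict_proba(X)[:, 1]
    return np.asarray(model.predict(X), dtype=np.float64).ravel()


def assign_folds(
    n: int,
    folds: int = 10,
    seed: int = 0,
    labels: np.ndarray | None = None,
    stratify: bool = False,
) -> np.ndarray:
    """Fold id in 0..folds-1 per sample, from a seeded shuffle.

    Plain (unstratified) assignment by default; with ``stratify=True`` the
    round-robin runs within each label class, keeping class balance per fold.
    """
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=int)
    if stratify and labels is not None:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            fold_id[perm] = np.arange(perm.size) % folds
    else:
        perm = rng.permutation(n)
        fold_id[perm] = np.arange(n) % folds
    return fold_id


def _check_data(data: CohortDataset, folds: int) -> None:
    if data.n < folds:
        raise ValueError(f"cohort of {data.n} samples cannot be split into {folds} folds")
    if np.unique(data.labels).size < 2:
        raise ValueError("degenerate single-class labels: cannot train a classifier")


def _oof_rmse(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    value,
    fold_id: np.ndarray,
    folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions and per-fold RMSE for one candidate value."""
    oof = np.empty(y.size, dtype=np.float64)
    rmse = np.empty(folds, dtype=np.float64)
    for f in range(folds):
        val = fold_id == f
        model = _make_model(family, value, seed)
        model.fit(X[~val], y[~val])
        oof[val] = _predict(family, model, X[val])
        rmse[f] = float(np.sqrt(np.mean((oof[val] - y[val]) ** 2)))
    return oof, rmse


def grid_search(
    data: CohortDataset,
    spec: ModelSpec,
    folds: int = 10,
    stratify: bool = False,
) -> tuple[float, dict]:
    """Pick the candidate with the lowest k-fold CV RMSE (ties -> smallest).

    Returns ``(best_value, mean_rmse_by_candidate)``.
    """
    _check_data(data, folds)
    fold_id = assign_folds(data.n, folds, spec.seed, data.labels, stratify)
    scores: dict = {}
    best_value, best_rmse = None, np.inf
    for value in sorted(spec.grid):
        _, rmse = _oof_rmse(data.features, data.labels, spec.family, value,
                            fold_id, folds, spec.seed)
        mean_rmse = float(rmse.mean())
        scores[value] = mean_rmse
        if mean_rmse < best_rmse:
            best_value, best_rmse = value, mean_rmse
    return best_value, scores


def crossval_predict(
    data: CohortDataset,
    spec: ModelSpec,
    best_param=None,
    folds: int = 10,
    seed: int | None = None,
    stratify: bool = False,
) -> CVResult:
    """Out-of-fold continuous predictions at ``best_param`` (grid-searched if None)."""
    _check_data(data, folds)
    if best_param is None:
        best_param, _ = grid_search(data, spec, folds, stratify)
    seed = spec.seed if seed is None else seed
    fold_id = assign_folds(data.n, folds, seed, data.labels, stratify)
    oof, rmse = _oof_rmse(data.features, data.labels, spec.family, best_param,
                          fold_id, folds, spec.seed)
    return CVResult(
        oof_predictions=oof,
        fold_assignment=fold_id,
        rmse_per_fold=rmse,
        mean_rmse=float(rmse.mean()),
        best_param=best_param,
        family=spec.family,
        seed=seed,
    )


def fit_predict(
    data: CohortDataset,
    spec: ModelSpec,
    param,
    newX: np.ndarray,
) -> np.ndarray:
    """Fit on the full cohort and predict continuous scores for new leaves."""
    newX = np.asarray(newX, dtype=np.float64)
    if newX.ndim != 2 or newX.shape[1] != data.k:
        raise ValueError(
            f"new data has {newX.shape[1] if newX.ndim == 2 else 'non-2D'} columns, "
            f"expected {data.k}"
        )
    if np.unique(data.labels).size < 2:
        raise ValueError("degenerate single-class labels: cannot train a classifier")
    model = _make_model(spec.family, param, spec.seed)
    model.fit(data.features, data.labels)
    return _predict(spec.family, model, newX)
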