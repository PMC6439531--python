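"""Growth-prediction models: gradient boosting and RBF support-vector
regression with grid-search tuning, plus grouped feature importance.

The workflow follows the standard recipe: a seeded 7:3 train/test split,
exhaustive grid search with 5-fold cross-validation scored by R^2, Pearson
correlation between observed and predicted harvest weights on the held-out
set, and (for gradient boosting) per-feature importances summed within the
named feature groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .features import FEATURE_GROUPS, FEATURE_NAMES, FEATURE_SUBGROUPS

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "default_gbr_grid",
    "default_svr_grid",
    "split_dataset",
    "scale_minmax",
    "tune_model",
    "evaluate",
    "grouped_importance",
]

# Reference hyperparameter grids. The full SVR grid spans 2^a for
# a = -20..20 on C, gamma and epsilon (41^3 combinations); the reduced grid
# keeps the same geometric spacing at desk scale.
GBR_GRID_FULL = {
    "min_samples_split": [10, 30, 50, 70],
    "max_depth": [4, 6, 8, 10],
    "subsample": [0.7, 0.8, 0.9, 1.0],
    "learning_rate": [0.01, 0.05, 0.1],
}
GBR_GRID_REDUCED = {
    "min_samples_split": [10, 30],
    "max_depth": [4, 6],
    "subsample": [0.8, 1.0],
    "learning_rate": [0.05, 0.1],
}
_SVR_EXPONENTS_FULL = tuple(range(-20, 21))
_SVR_EXPONENTS_REDUCED = (-10, -5, 0, 5, 10)


def default_gbr_grid(reduced: bool = True) -> dict:
    return {k: list(v) for k, v in (GBR_GRID_REDUCED if reduced else GBR_GRID_FULL).items()}


def default_svr_grid(reduced: bool = True) -> dict:
    exps = _SVR_EXPONENTS_REDUCED if reduced else _SVR_EXPONENTS_FULL
    vals = [2.0**a for a in exps]
    return {"svr__C": list(vals), "svr__gamma": list(vals), "svr__epsilon": list(vals)}


@dataclass
class ModelSpec:
    """Which model to fit and how to tune it."""

    kind: str = "gbr"  # "gbr" or "svr"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gbr", "svr"):
            raise ValueError("kind must be 'gbr' or 'svr'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            self.grid = default_gbr_grid() if self.kind == "gbr" else default_svr_grid()
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid values must be non-empty")


@dataclass
class EvaluationReport:
    kind: str
    test_correlation: float
    best_params: dict
    cv_r2: list[float]  # per-fold R^2 of the selected configuration
    grouped_importances: dict | None = None  # GBR only

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "test_correlation": self.test_correlation,
            "best_params": self.best_params,
            "cv_r2": list(self.cv_r2),
            "grouped_importances": self.grouped_importances,
        }


def split_dataset(
    n_samples: int, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split; test size = ceil(n * fraction). 338 -> 236/102."""
    if n_samples < 2:
        raise ValueError("need at least two samples to split")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = math.ceil(n_samples * test_fraction)
    perm = np.random.default_rng(seed).permutation(n_samples)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def scale_minmax(train: np.ndarray) -> MinMaxScaler:
    """Min-max scaler fitted on the training matrix only.

    Training columns map onto [0, 1]; a constant column maps to 0; test data
    transformed with the same scaler may fall outside [0, 1].
    """
    scaler = MinMaxScaler()
    scaler.fit(np.asarray(train, dtype=float))
    return scaler


def _estimator(spec: ModelSpec):
    if spec.kind == "gbr":
        return GradientBoostingRegressor(random_state=spec.seed)
    return Pipeline([("scale", MinMaxScaler()), ("svr", SVR(kernel="rbf"))])


def tune_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Exhaustive grid search with seeded K-fold CV scored by R^2.

    Returns ``(fitted_best_model, best_params, per_fold_r2)``. Ties are
    broken by first-in-grid order. The SVR estimator bundles its min-max
    scaler in a pipeline so scaling is refit inside every fold (no leakage).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < spec.cv_folds:
        raise ValueError("fewer training samples than CV folds")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; nothing to learn")
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _estimator(spec), spec.grid, scoring="r2", cv=cv, refit=True, n_jobs=1
    )
    search.fit(X, y)
    idx = search.best_index_
    folds = [
        float(search.cv_results_[f"split{i}_test_score"][idx])
        for i in range(spec.cv_folds)
    ]
    return search.best_estimator_, dict(search.best_params_), folds


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Pearson correlation between observed and predicted targets."""
    if len(X_test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(np.asarray(X_test, dtype=float))
    if np.ptp(pred) == 0:
        warnings.warn("constant predictions; correlation undefined", stacklevel=2)
        return math.nan
    return float(stats.pearsonr(np.asarray(y_test, dtype=float), pred).statistic)


def _importances(model) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=float)
    raise TypeError(
        "grouped importance requires a model exposing feature_importances_ "
        "(gradient boosting); SVR does not provide per-feature importances"
    )


def grouped_importance(
    model,
    grouping: dict[str, slice] | dict[str, list[int]] | None = None,
) -> dict[str, float]:
    """Per-feature importances summed within named groups.

    Defaults to the canonical feature groups; pass ``FEATURE_SUBGROUPS`` (or
    any partition of the columns) for the finer sub-group breakdown
    (pca-ang, ang-dd-diff, ...). For a grouping that partitions all columns
    the sums add to the total importance (1 for gradient boosting).
    """
    imp = _importances(model)
    grouping = dict(grouping) if grouping is not None else dict(FEATURE_GROUPS)
    out: dict[str, float] = {}
    for name, sel in grouping.items():
        idx = np.arange(len(imp))[sel] if isinstance(sel, slice) else np.asarray(sel)
        out[name] = float(imp[idx].sum())
    return out


def train_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    *,
    test_fraction: float = 0.3,
    split_seed: int | None = None,
) -> tuple[EvaluationReport, object]:
    """Convenience wrapper: split, tune, evaluate, and (GBR) group importances."""
    split_seed = spec.seed if split_seed is None else split_seed
    train_idx, test_idx = split_dataset(len(X), test_fraction, split_seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    model, best, folds = tune_model(spec, X[train_idx], y[train_idx])
    corr = evaluate(model, X[test_idx], y[test_idx])
    grouped = None
    if spec.kind == "gbr" and X.shape[1] == len(FEATURE_NAMES):
        grouped = grouped_importance(model)
    report = EvaluationReport(
        kind=spec.kind, test_correlation=corr, best_params=best,
        cv_r2=folds, grouped_importances=grouped,
    )
    return report, model
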