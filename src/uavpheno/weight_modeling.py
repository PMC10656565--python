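"""Harvest-weight prediction experiments.

Five linear/ensemble regressors (PLS, lasso, ridge, linear SVM, random
forest) are tuned by exhaustive grid search under five-fold cross-validation
on a 90/10 train/test split. Features can be drawn from a single flight date
or cumulatively from all selected dates up to a cutoff; dates are selected by
one of five temporal-resolution schemes (all dates, 7/15/30-day greedy
intervals, or the hand-picked growth-stage anchors 12/34/56/80/101 DAT).
Feature selection is available as exhaustive subset search, sequential
forward selection, and random-forest impurity importance.

Metrics: R^2 = 1 - SS_res/SS_tot and RMSE = sqrt(mean squared error),
reported in the units of the weights (g/plant).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .phenotype_features import FeatureTable

__all__ = [
    "ModelSpec",
    "TemporalScheme",
    "EvaluationResult",
    "GROWTH_PATTERN_ANCHORS",
    "split_data",
    "cross_validate",
    "exhaustive_selection",
    "sfs_forward",
    "rf_importance",
    "select_timepoints",
    "build_design",
    "r_squared",
    "rmse",
    "prior_to_harvest_sweep",
]

MODEL_FAMILIES = ("PLS", "lasso", "ridge", "SVM-linear", "RF")

#: Growth-stage anchor dates (days after transplanting).
GROWTH_PATTERN_ANCHORS = (12, 34, 56, 80, 101)

SCHEME_NAMES = ("all_tps", "interval_7d", "interval_15d", "interval_30d",
                "growth_pattern")


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must share a length of at least 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error in the units of y."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("y and y_hat must share a non-zero length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class ModelSpec:
    """One regressor family with its hyperparameter grid and seed."""

    family: str
    grid: Optional[Dict[str, Sequence]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )

    def default_grid(self, n_features: int, n_rows: int) -> Dict[str, Sequence]:
        if self.grid is not None:
            return self.grid
        if self.family in ("lasso", "ridge"):
            return {"model__alpha": np.logspace(-3, 3, 13)}
        if self.family == "PLS":
            upper = max(1, min(20, n_features, n_rows - 2))
            return {"model__n_components": list(range(1, upper + 1))}
        if self.family == "SVM-linear":
            return {"model__C": np.logspace(-2, 2, 7)}
        # RF
        p = max(1, n_features)
        mf = sorted({max(1, math.ceil(p / 3)), max(1, math.ceil(math.sqrt(p)))})
        return {"model__max_features": mf, "model__min_samples_leaf": [1, 5]}

    def make_estimator(self) -> Pipeline:
        if self.family == "lasso":
            model = Lasso(max_iter=50000)
        elif self.family == "ridge":
            model = Ridge()
        elif self.family == "PLS":
            model = PLSRegression()
        elif self.family == "SVM-linear":
            model = SVR(kernel="linear", epsilon=0.1)
        else:
            model = RandomForestRegressor(n_estimators=500, random_state=self.seed)
        return Pipeline([("scale", StandardScaler()), ("model", model)])


@dataclass
class TemporalScheme:
    """Rule selecting which flight dates feed a model.

    ``mode`` 'single_tp' uses only the date at the cutoff; 'cumulative'
    concatenates all selected dates up to the cutoff.
    """

    name: str
    mode: str = "cumulative"
    cutoff_dat: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.mode not in ("single_tp", "cumulative"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def interval_days(self) -> Optional[int]:
        if self.name.startswith("interval_"):
            return int(self.name.split("_")[1].rstrip("d"))
        return None


@dataclass
class EvaluationResult:
    """Cross-validation and test metrics for one (scheme, model) experiment."""

    family: str
    fold_r2: np.ndarray
    fold_rmse: np.ndarray
    best_params: Dict
    estimator: Pipeline
    n: int
    oof_predictions: np.ndarray
    scheme: Optional[TemporalScheme] = None
    selected_features: Optional[List[str]] = None
    test_r2: Optional[float] = None
    test_rmse: Optional[float] = None

    @property
    def mean_cv_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def mean_cv_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    def evaluate(self, X_test, y_test) -> "EvaluationResult":
        pred = np.asarray(self.estimator.predict(np.asarray(X_test, float))).ravel()
        y_test = np.asarray(y_test, float)
        self.test_r2 = r_squared(y_test, pred)
        self.test_rmse = rmse(y_test, pred)
        return self


def split_data(
    table: FeatureTable, test_fraction: float = 0.10, seed: int = 0
) -> Tuple[FeatureTable, FeatureTable]:
    """Uniform random train/test split of a feature table (by plant row).

    The test set holds floor(n * test_fraction) rows; train and test are
    disjoint and reproducible under the seed.
    """
    n = len(table.data)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(n * test_fraction))
    test_idx = table.data.index[np.sort(perm[:n_test])]
    train_idx = table.data.index[np.sort(perm[n_test:])]

    def subset(idx):
        return FeatureTable(
            data=table.data.loc[idx].copy(), weights=table.weights.loc[idx].copy()
        )

    return subset(train_idx), subset(test_idx)


def _fold_indices(n: int, k: int, seed: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def cross_validate(
    model: ModelSpec,
    X,
    y,
    k: int = 5,
    folds: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
) -> EvaluationResult:
    """Grid search under k-fold CV, then refit on all rows.

    Standardization is fitted inside each fold (pipeline), so held-out folds
    never leak into the scaler. The grid point maximizing the mean CV R^2
    wins; per-fold R^2/RMSE of the winner and its out-of-fold predictions
    are recorded, and the winning configuration is refitted on all rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < k:
        raise ValueError("fewer rows than folds")
    if np.var(y) == 0:
        raise ValueError("degenerate target: y has zero variance")
    if folds is None:
        folds = _fold_indices(n, k, model.seed)

    grid = list(ParameterGrid(model.default_grid(X.shape[1], n)))
    base = model.make_estimator()

    best = None
    for params in grid:
        fold_r2 = np.empty(len(folds))
        fold_rmse = np.empty(len(folds))
        oof = np.empty(n)
        for fi, (tr, te) in enumerate(folds):
            est = clone(base).set_params(**params)
            est.fit(X[tr], y[tr])
            pred = np.asarray(est.predict(X[te])).ravel()
            oof[te] = pred
            fold_r2[fi] = r_squared(y[te], pred)
            fold_rmse[fi] = rmse(y[te], pred)
        score = fold_r2.mean()
        if best is None or score > best[0]:
            best = (score, params, fold_r2, fold_rmse, oof)

    _, params, fold_r2, fold_rmse, oof = best
    final = clone(base).set_params(**params)
    final.fit(X, y)
    return EvaluationResult(
        family=model.family,
        fold_r2=fold_r2,
        fold_rmse=fold_rmse,
        best_params=params,
        estimator=final,
        n=n,
        oof_predictions=oof,
    )


def _default_selection_estimator() -> Pipeline:
    # lightly regularized lasso as the wrapper scorer
    return make_pipeline(StandardScaler(), Lasso(alpha=1e-3, max_iter=50000))


def _cv_score(estimator, X: np.ndarray, y: np.ndarray, folds) -> float:
    scores = []
    for tr, te in folds:
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        scores.append(r_squared(y[te], np.asarray(est.predict(X[te])).ravel()))
    return float(np.mean(scores))


def exhaustive_selection(
    features: pd.DataFrame,
    y,
    estimator=None,
    max_set_size: Optional[int] = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every non-empty feature subset by mean k-fold CV R^2.

    Returns a tidy frame (size, features, cv_r2, best_in_size) sorted by
    subset size then score. Limited to 15 features; larger problems should
    use :func:`sfs_forward`.
    """
    p = features.shape[1]
    if p > 15:
        raise ValueError(
            f"{p} features give 2^{p}-1 subsets; use sfs_forward instead"
        )
    if max_set_size is None:
        max_set_size = p
    if estimator is None:
        estimator = _default_selection_estimator()
    y = np.asarray(y, dtype=float).ravel()
    Xall = features.to_numpy(dtype=float)
    folds = _fold_indices(len(y), k, seed)
    cols = list(features.columns)

    rows = []
    for size in range(1, max_set_size + 1):
        for subset in itertools.combinations(range(p), size):
            score = _cv_score(estimator, Xall[:, subset], y, folds)
            rows.append(
                {"size": size, "features": tuple(cols[i] for i in subset),
                 "cv_r2": score}
            )
    out = pd.DataFrame(rows)
    out["best_in_size"] = False
    for size, grp in out.groupby("size"):
        out.loc[grp["cv_r2"].idxmax(), "best_in_size"] = True
    return out.sort_values(["size", "cv_r2"], ascending=[True, False]).reset_index(
        drop=True
    )


def sfs_forward(
    features: pd.DataFrame,
    y,
    estimator=None,
    n_select: Optional[int] = None,
    k: int = 5,
    seed: int = 0,
) -> List[str]:
    """Greedy sequential forward selection by mean k-fold CV R^2.

    Returns the selection path (ordered feature names); prefixes of the path
    are the smaller selections.
    """
    p = features.shape[1]
    if n_select is None:
        n_select = p
    if n_select > p:
        raise ValueError("n_select exceeds the number of features")
    if estimator is None:
        estimator = _default_selection_estimator()
    y = np.asarray(y, dtype=float).ravel()
    Xall = features.to_numpy(dtype=float)
    folds = _fold_indices(len(y), k, seed)
    cols = list(features.columns)

    selected: List[int] = []
    remaining = list(range(p))
    while len(selected) < n_select:
        best_idx, best_score = None, -np.inf
        for j in remaining:
            score = _cv_score(estimator, Xall[:, selected + [j]], y, folds)
            if score > best_score:
                best_idx, best_score = j, score
        selected.append(best_idx)
        remaining.remove(best_idx)
    return [cols[i] for i in selected]


def rf_importance(features: pd.DataFrame, y, seed: int = 0) -> pd.Series:
    """Random-forest mean-decrease-in-impurity feature ranking.

    Scores are normalized to sum to one and returned sorted descending.
    """
    rf = RandomForestRegressor(n_estimators=500, random_state=seed)
    rf.fit(features.to_numpy(dtype=float), np.asarray(y, dtype=float).ravel())
    imp = rf.feature_importances_
    if imp.sum() == 0:
        imp = np.full_like(imp, 1.0 / len(imp))
    else:
        imp = imp / imp.sum()
    return pd.Series(imp, index=features.columns).sort_values(ascending=False)


def select_timepoints(tp_dat: Sequence[int], scheme: TemporalScheme) -> List[int]:
    """Apply a temporal-resolution scheme to an observed flight calendar.

    all_tps keeps every date; interval_Nd walks greedily from the first date
    taking the earliest date at least N days after the previously selected
    one; growth_pattern takes, for each anchor in 12/34/56/80/101 DAT, the
    nearest available date (ties to the earlier date). The result is then
    truncated at the scheme's cutoff.
    """
    tp_dat = list(tp_dat)
    if tp_dat != sorted(tp_dat):
        raise ValueError("tp_dat must be sorted ascending")
    if scheme.name == "all_tps":
        selected = list(tp_dat)
    elif scheme.interval_days is not None:
        n = scheme.interval_days
        selected = [tp_dat[0]]
        for dat in tp_dat[1:]:
            if dat >= selected[-1] + n:
                selected.append(dat)
    else:  # growth_pattern
        chosen = []
        for anchor in GROWTH_PATTERN_ANCHORS:
            best = min(tp_dat, key=lambda d: (abs(d - anchor), d))
            chosen.append(best)
        selected = sorted(set(chosen))
    if scheme.cutoff_dat is not None:
        selected = [d for d in selected if d <= scheme.cutoff_dat]
    if not selected:
        raise ValueError("no time points remain after applying the cutoff")
    return selected


def build_design(
    table: FeatureTable, scheme: TemporalScheme
) -> Tuple[pd.DataFrame, pd.Series]:
    """Design matrix and target for one temporal scheme.

    cumulative mode concatenates the feature columns of every selected date
    up to the cutoff; single_tp uses only the latest selected date. Rows
    with any missing cell (or missing weight) are dropped.
    """
    selected = select_timepoints(table.tp_dats, scheme)
    if scheme.mode == "single_tp":
        selected = [selected[-1]]
    cols = table.columns_at(selected)
    if not cols:
        raise ValueError("selected time points have no columns in the table")
    X = table.data[cols]
    y = table.weights
    ok = X.notna().all(axis=1) & y.notna()
    dropped = int((~ok).sum())
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "build_design dropped %d rows with missing cells", dropped
        )
    X, y = X.loc[ok], y.loc[ok]
    if len(X) == 0:
        raise ValueError("no rows survive missing-cell filtering")
    return X, y


def prior_to_harvest_sweep(
    table: FeatureTable,
    schemes: Sequence[TemporalScheme],
    harvest_dat: int,
    models: Sequence[ModelSpec],
    test_fraction: float = 0.10,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Days-prior-to-harvest sweep over schemes, cutoffs and model families.

    For each scheme and each of its available cutoff dates, a cumulative (or
    single-date) design is built on a fixed 90/10 split, every model family
    is tuned under k-fold CV and evaluated on the held-out rows. One tidy
    row per (scheme, cutoff, model) is returned.
    """
    if harvest_dat < max(table.tp_dats):
        raise ValueError("harvest_dat precedes the last observed time point")
    train, test = split_data(table, test_fraction=test_fraction, seed=seed)

    rows = []
    for scheme in schemes:
        cutoffs = select_timepoints(
            table.tp_dats,
            TemporalScheme(scheme.name, mode=scheme.mode,
                           cutoff_dat=scheme.cutoff_dat),
        )
        for cutoff in cutoffs:
            sch = TemporalScheme(scheme.name, mode=scheme.mode, cutoff_dat=cutoff)
            X_tr, y_tr = build_design(train, sch)
            X_te, y_te = build_design(test, sch)
            folds = _fold_indices(len(y_tr), k, seed)
            for model in models:
                res = cross_validate(model, X_tr, y_tr, k=k, folds=folds)
                res.scheme = sch
                res.evaluate(X_te, y_te)
                rows.append(
                    {
                        "scheme": scheme.name,
                        "mode": scheme.mode,
                        "cutoff_dat": cutoff,
                        "dph": harvest_dat - cutoff,
                        "model": model.family,
                        "mean_cv_r2": res.mean_cv_r2,
                        "mean_cv_rmse": res.mean_cv_rmse,
                        "test_r2": res.test_r2,
                        "test_rmse": res.test_rmse,
                        "n_train": res.n,
                        "n_test": len(y_te),
                        "n_features": X_tr.shape[1],
                    }
                )
    return pd.DataFrame(rows)
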