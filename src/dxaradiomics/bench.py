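"""Stratified splitting, grid-searched model selection and the benchmark.

Three classifier families are benchmarked: logistic regression (LR),
support vector machines (SVM) and gradient-boosted trees (XGB).  Model
selection is an exhaustive grid search under stratified 5-fold
cross-validation maximising the mean F-score of the degraded (positive)
class; held-out evaluation reports accuracy, sensitivity, precision,
F-score and AUC ROC.  Features are z-scored inside each fold (statistics
fit on the fold-training part only) — essential for the SVM and harmless
for the trees.

The full benchmark crosses the 45 resampled training sets with the three
classifier families: 135 cells, with the best classifier per (dataset,
technique) row flagged by held-out F-score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score, f1_score, precision_score, recall_score, roc_auc_score,
)
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "SplitSpec",
    "FoldDegeneracy",
    "SearchResult",
    "CLASSIFIERS",
    "stratified_split",
    "default_grid",
    "make_estimator",
    "grid_search_cv",
    "evaluate",
    "run_benchmark",
]

CLASSIFIERS: tuple[str, ...] = ("LR", "SVM", "XGB")

POSITIVE = 1  # degraded microarchitecture


class FoldDegeneracy(ValueError):
    """A cross-validation fold lacks one of the classes."""


@dataclass(frozen=True)
class SplitSpec:
    """70/30 stratified train/test partition parameters."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(t: pd.DataFrame, spec: SplitSpec = SplitSpec()
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class floor allocation: each class contributes
    floor(n_class * train_fraction) rows to the training set and the
    remainder to the test set.  Partitions are disjoint, exhaustive and
    deterministic under the seed; input row order is preserved within each
    partition."""
    if "label" not in t.columns:
        raise ValueError("feature table must carry a 'label' column")
    y = t["label"].to_numpy()
    rng = np.random.default_rng(spec.seed)
    in_train = np.zeros(len(t), dtype=bool)
    groups = [np.arange(len(t))] if not spec.stratified else [
        np.flatnonzero(y == c) for c in np.unique(y)]
    for pos in groups:
        n_train = int(np.floor(pos.size * spec.train_fraction))
        chosen = rng.permutation(pos.size)[:n_train]
        in_train[pos[chosen]] = True
    return t.iloc[in_train], t.iloc[~in_train]


def default_grid(classifier: str, reduced: bool = False) -> list[dict]:
    """Hyperparameter grids.

    Full grids: SVM kernels {linear, poly, rbf} with C at integer powers
    of ten in [1e-5, 1e5] and gamma at integer powers of two in
    [2^-2, 2^5] plus 'auto'/'scale'; XGB learning rate {0.01, 0.1, 0.3,
    1.0} x depth {4, 6, 8, 10} x estimators {1, 10, 50, 100, 500}; LR
    penalties {l1, l2, elasticnet} x the same C range x solvers
    {liblinear, saga, lbfgs} (invalid penalty/solver pairs are skipped at
    search time).  ``reduced`` selects small grids for smoke-scale runs.
    """
    c_range = [10.0 ** e for e in range(-5, 6)]
    gamma_range = [2.0 ** e for e in range(-2, 6)] + ["auto", "scale"]
    if classifier == "SVM":
        if reduced:
            return [{"kernel": ["linear", "rbf"],
                     "C": [0.01, 1.0, 100.0], "gamma": ["scale"]}]
        return [{"kernel": ["linear", "poly", "rbf"],
                 "C": c_range, "gamma": gamma_range}]
    if classifier == "LR":
        if reduced:
            return [{"penalty": ["l2"], "C": [0.01, 1.0, 100.0],
                     "solver": ["lbfgs"]}]
        return [{"penalty": ["l1", "l2", "elasticnet"], "C": c_range,
                 "solver": ["liblinear", "saga", "lbfgs"]}]
    if classifier == "XGB":
        if reduced:
            return [{"learning_rate": [0.1, 0.3], "max_depth": [4],
                     "n_estimators": [50]}]
        return [{"learning_rate": [0.01, 0.1, 0.3, 1.0],
                 "max_depth": [4, 6, 8, 10],
                 "n_estimators": [1, 10, 50, 100, 500]}]
    raise ValueError(f"unknown classifier {classifier!r}")


_VALID_LR = {
    "liblinear": {"l1", "l2"},
    "saga": {"l1", "l2", "elasticnet"},
    "lbfgs": {"l2"},
}


def _params_valid(classifier: str, params: dict) -> bool:
    if classifier == "LR":
        return params["penalty"] in _VALID_LR[params["solver"]]
    return True


def make_estimator(classifier: str, params: dict, seed: int = 0):
    """Scaler + classifier pipeline for one hyperparameter combination."""
    if classifier == "LR":
        # penalty names map onto the elastic-net mixing parameter
        l1_ratio = {"l1": 1.0, "l2": 0.0, "elasticnet": 0.5}[params["penalty"]]
        est = LogisticRegression(max_iter=2000, random_state=seed,
                                 C=params["C"], solver=params["solver"],
                                 l1_ratio=l1_ratio)
    elif classifier == "SVM":
        est = SVC(random_state=seed, **params)
    elif classifier == "XGB":
        est = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                            eval_metric="logloss", tree_method="hist",
                            **params)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


@dataclass
class SearchResult:
    classifier: str
    best_params: dict
    cv_mean_f: float
    cv_sd_f: float
    model: Pipeline
    all_results: list[dict] = field(default_factory=list)


def grid_search_cv(train: pd.DataFrame, classifier: str,
                   grid: Sequence[dict] | None = None, folds: int = 5,
                   seed: int = 0, reduced: bool = False) -> SearchResult:
    """Exhaustive grid search with stratified k-fold CV maximising mean
    F-score; ties break by enumeration order.  The winning combination is
    refit on the full training table."""
    if grid is None:
        grid = default_grid(classifier, reduced=reduced)
    x = train.drop(columns="label").to_numpy(dtype=float)
    y = train["label"].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    for tr, va in splits:
        if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
            raise FoldDegeneracy("a fold lacks one of the classes")

    best = None
    results = []
    for params in ParameterGrid(list(grid)):
        if not _params_valid(classifier, params):
            continue
        scores = []
        for tr, va in splits:
            model = make_estimator(classifier, params, seed)
            model.fit(x[tr], y[tr])
            scores.append(f1_score(y[va], model.predict(x[va]),
                                   pos_label=POSITIVE, zero_division=0))
        mean, sd = float(np.mean(scores)), float(np.std(scores))
        results.append({"params": dict(params), "cv_mean_f": mean,
                        "cv_sd_f": sd})
        if best is None or mean > best["cv_mean_f"]:
            best = results[-1]
    if best is None:
        raise ValueError("grid contained no valid hyperparameter combination")
    model = make_estimator(classifier, best["params"], seed)
    model.fit(x, y)
    return SearchResult(classifier=classifier, best_params=best["params"],
                        cv_mean_f=best["cv_mean_f"], cv_sd_f=best["cv_sd_f"],
                        model=model, all_results=results)


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(x)[:, 1]
        except AttributeError:  # e.g. SVC(probability=False) inside pipeline
            pass
    return model.decision_function(x)


def evaluate(model, test: pd.DataFrame) -> dict[str, float]:
    """Held-out metrics with degraded (label 1) as the positive class.

    Sensitivity = TP/(TP+FN), precision = TP/(TP+FP), F-score their
    harmonic mean; AUC is the rank statistic over continuous scores
    (decision-function values where calibrated probabilities are
    unavailable)."""
    x = test.drop(columns="label").to_numpy(dtype=float)
    y = test["label"].to_numpy()
    pred = model.predict(x)
    out = {
        "accuracy": float(accuracy_score(y, pred)),
        "sensitivity": float(recall_score(y, pred, pos_label=POSITIVE,
                                          zero_division=0)),
        "precision": float(precision_score(y, pred, pos_label=POSITIVE,
                                           zero_division=0)),
        "f_score": float(f1_score(y, pred, pos_label=POSITIVE,
                                  zero_division=0)),
    }
    if np.unique(y).size < 2:
        out["auc_roc"] = float("nan")
    else:
        out["auc_roc"] = float(roc_auc_score(y, _scores(model, x)))
    return out


def run_benchmark(resampled: Mapping[tuple[str, str], object],
                  test_tables: Mapping[str, pd.DataFrame],
                  classifiers: Iterable[str] = CLASSIFIERS,
                  grids: Mapping[str, Sequence[dict]] | None = None,
                  folds: int = 5, seed: int = 0,
                  reduced: bool = True) -> pd.DataFrame:
    """Evaluate every (dataset, technique) x classifier cell.

    ``resampled`` maps (dataset, technique) to a ResamplingResult (or a
    plain training DataFrame); ``test_tables`` maps dataset name to its
    untouched test partition.  Returns the Table-1-shaped report: one row
    per cell with CV statistics and held-out metrics, ``best`` flagging
    the top classifier per (dataset, technique) by held-out F-score.
    """
    records = []
    for (ds_name, tech), res in resampled.items():
        train = res.table if hasattr(res, "table") else res
        test = test_tables[ds_name]
        for clf in classifiers:
            grid = grids.get(clf) if grids is not None else None
            sr = grid_search_cv(train, clf, grid=grid, folds=folds,
                                seed=seed, reduced=reduced)
            metrics = evaluate(sr.model, test)
            records.append({
                "dataset": ds_name,
                "technique": tech,
                "classifier": clf,
                "best_params": json.dumps(sr.best_params, sort_keys=True),
                "cv_mean_f": sr.cv_mean_f,
                "cv_sd_f": sr.cv_sd_f,
                **metrics,
            })
    report = pd.DataFrame.from_records(records)
    report["best"] = False
    for _, grp in report.groupby(["dataset", "technique"], sort=False):
        report.loc[grp["f_score"].idxmax(), "best"] = True
    return report
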