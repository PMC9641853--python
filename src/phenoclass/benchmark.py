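"""Model development harness: splits, tuning, calibration, benchmarking.

The evaluation scheme splits each labelled dataset into four stratified
folds (a 50:25:25 train/validation/test ratio: two folds train, one
validates, one tests) and runs twelve iterations — the twelve ordered
(validation, test) fold assignments, which is the exhaustive set for four
folds.  Within each iteration hyper-parameters are tuned on the training
split by grid search with internal fivefold stratified cross-validation
scored by F1, the tuned model's probabilities are calibrated on the
validation split (Platt sigmoid by default, isotonic optional), and the
calibrated classifier is scored on all three splits.  Class predictions
use a 0.5 threshold on the calibrated probability.

Ten classification algorithms are registered: LR, LDA, KNN, CART, NB,
SVM, AB, GBM, RF and ET.  Algorithms sensitive to feature scale (LR,
KNN, SVM) run inside a pipeline whose standard scaler is fit on the
training split only — no statistics leak from validation or test.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier, RandomForestClassifier)
from sklearn.frozen import FrozenEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .labelling import ACTIVE, LabelledDataset
from .metrics import MetricReport, score_predictions

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = ("LR", "LDA", "KNN", "CART", "NB", "SVM", "AB", "GBM", "RF", "ET")
N_FOLDS = 4
N_ITERATIONS = 12   # ordered (validation, test) pairs over 4 folds


def derive_seed(master: int, *context) -> int:
    """Deterministically expand a master seed for a named context (< 2^31)."""
    h = hashlib.sha256(repr((int(master),) + tuple(context)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One registered classifier with its hyper-parameter grid."""

    name: str
    factory: object                 # callable(seed) -> unfitted estimator
    grid: dict
    needs_scaling: bool = False

    def build(self, seed: int):
        est = self.factory(seed)
        if self.needs_scaling:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return est

    def grid_for_build(self) -> dict:
        if self.needs_scaling:
            return {f"model__{k}": v for k, v in self.grid.items()}
        return dict(self.grid)


def default_algorithms(grids: dict[str, dict] | None = None) -> dict[str, AlgorithmSpec]:
    """The ten-algorithm registry with default (config-overridable) grids."""
    g = {
        "LR": {"C": [0.01, 0.1, 1, 10]},
        "LDA": {},
        "KNN": {"n_neighbors": [3, 5, 7, 11, 15]},
        "CART": {"max_depth": [None, 4, 8, 16]},
        "NB": {},
        "SVM": {"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.001]},
        "AB": {"n_estimators": [50, 100, 200]},
        "GBM": {"learning_rate": [0.05, 0.1]},
        "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 8, 16]},
        "ET": {"n_estimators": [100, 300, 500], "max_depth": [None, 8, 16]},
    }
    if grids:
        for name, grid in grids.items():
            if name not in g:
                raise KeyError(f"unknown algorithm {name!r}")
            g[name] = grid
    factories = {
        "LR": lambda s: LogisticRegression(max_iter=2000, random_state=s),
        "LDA": lambda s: LinearDiscriminantAnalysis(),
        "KNN": lambda s: KNeighborsClassifier(),
        "CART": lambda s: DecisionTreeClassifier(random_state=s),
        "NB": lambda s: GaussianNB(),
        "SVM": lambda s: SVC(kernel="rbf", random_state=s),
        "AB": lambda s: AdaBoostClassifier(random_state=s),
        "GBM": lambda s: GradientBoostingClassifier(random_state=s),
        "RF": lambda s: RandomForestClassifier(random_state=s),
        "ET": lambda s: ExtraTreesClassifier(random_state=s),
    }
    scaled = {"LR", "KNN", "SVM"}
    return {n: AlgorithmSpec(n, factories[n], g[n], n in scaled)
            for n in ALGORITHM_NAMES}


@dataclass
class SplitPlan:
    """One train/validation/test role assignment within the fourfold scheme."""

    iteration_index: int                    # 1..12
    fold_assignment: dict[str, int]         # compound_id -> fold 1..4
    validation_fold: int
    test_fold: int
    seed: int

    @property
    def train_folds(self) -> tuple[int, int]:
        return tuple(f for f in range(1, N_FOLDS + 1)
                     if f not in (self.validation_fold, self.test_fold))

    def _ids(self, folds) -> list[str]:
        return [c for c, f in self.fold_assignment.items() if f in folds]

    @property
    def train_ids(self) -> list[str]:
        return self._ids(self.train_folds)

    @property
    def validation_ids(self) -> list[str]:
        return self._ids({self.validation_fold})

    @property
    def test_ids(self) -> list[str]:
        return self._ids({self.test_fold})


def make_splits(dataset: LabelledDataset, seed: int) -> list[SplitPlan]:
    """Twelve split plans sharing one stratified fourfold partition.

    Fold membership is stratified on the active/inactive label and fixed
    by the seed; the twelve iterations enumerate every ordered
    (validation, test) pair of distinct folds, the remaining two folds
    forming the training split (50:25:25).
    """
    ids = [e.compound_id for e in dataset.entries]
    y = np.array([1 if l == ACTIVE else 0 for l in dataset.labels])
    if min(y.sum(), len(y) - y.sum()) < N_FOLDS:
        raise ValueError("each class needs at least 4 compounds to stratify")
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, idx) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        for i in idx:
            assignment[ids[i]] = fold
    plans = []
    for it, (val, test) in enumerate(
            itertools.permutations(range(1, N_FOLDS + 1), 2), start=1):
        plans.append(SplitPlan(iteration_index=it, fold_assignment=assignment,
                               validation_fold=val, test_fold=test, seed=seed))
    return plans


def tune(spec: AlgorithmSpec, X_train: np.ndarray, y_train: np.ndarray,
         seed: int, cv_folds: int = 5):
    """Grid search with internal stratified CV scored by F1; refit on train.

    Returns the refit best estimator and the chosen parameters.  A
    single-point (or empty) grid degenerates to a plain fit.
    """
    grid = spec.grid_for_build()
    est = spec.build(seed)
    if not grid or all(len(v) == 1 for v in grid.values()):
        est.set_params(**{k: v[0] for k, v in grid.items()})
        est.fit(X_train, y_train)
        return est, {k: v[0] for k, v in grid.items()}
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="f1", cv=cv, n_jobs=1, refit=True)
    search.fit(X_train, y_train)
    return search.best_estimator_, dict(search.best_params_)


def _raw_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


class CalibratedModel:
    """A fitted classifier with a monotone probability mapping.

    ``calibrated`` is False when calibration was skipped (single-class
    validation split); probabilities then fall back to the raw scores
    squashed to [0, 1] only if needed for thresholding.
    """

    def __init__(self, model, calibrator=None):
        self.model = model
        self.calibrator = calibrator

    @property
    def calibrated(self) -> bool:
        return self.calibrator is not None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.calibrator is not None:
            return self.calibrator.predict_proba(X)[:, 1]
        raw = _raw_scores(self.model, X)
        if raw.min() < 0 or raw.max() > 1:        # decision-function scores
            raw = 1.0 / (1.0 + np.exp(-raw))
        return raw

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def calibrate(model, X_val: np.ndarray, y_val: np.ndarray,
              method: str = "sigmoid") -> CalibratedModel:
    """Fit a monotone score→probability mapping on the validation split.

    Platt sigmoid by default, isotonic optional.  The fitted model itself
    is frozen — only the mapping is learned here.  A single-class
    validation split cannot support calibration; the raw scores are kept
    with a warning.
    """
    if len(np.unique(y_val)) < 2:
        logger.warning("calibrate: single-class validation split, skipping")
        return CalibratedModel(model, None)
    cal = CalibratedClassifierCV(FrozenEstimator(model), method=method)
    cal.fit(X_val, y_val)
    return CalibratedModel(model, cal)


def _xy(dataset: LabelledDataset, features: FeatureMatrix,
        ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    label_of = {e.compound_id: l for e, l in zip(dataset.entries, dataset.labels)}
    sub = features.subset(ids)
    y = np.array([1 if label_of[c] == ACTIVE else 0 for c in ids])
    return sub.values, y


def _report_to_row(prefix: str, report: MetricReport) -> dict:
    return {f"{prefix}_{k}": v for k, v in report.__dict__.items()}


def run_iteration(dataset: LabelledDataset, features: FeatureMatrix,
                  spec: AlgorithmSpec, plan: SplitPlan, seed: int,
                  calibration: str = "sigmoid") -> dict:
    """Tune → calibrate → score one split plan; returns one result row."""
    X_tr, y_tr = _xy(dataset, features, plan.train_ids)
    X_val, y_val = _xy(dataset, features, plan.validation_ids)
    X_te, y_te = _xy(dataset, features, plan.test_ids)
    model, params = tune(spec, X_tr, y_tr, seed=seed)
    cm = calibrate(model, X_val, y_val, method=calibration)
    row = {"algorithm": spec.name, "iteration": plan.iteration_index,
           "chosen_params": repr(params)}
    for prefix, X, y in (("train", X_tr, y_tr), ("validation", X_val, y_val),
                         ("test", X_te, y_te)):
        prob = cm.predict_proba(X)
        pred = np.where(prob >= 0.5, ACTIVE, "inactive")
        truth = np.where(y == 1, ACTIVE, "inactive")
        row.update(_report_to_row(prefix, score_predictions(truth, pred, prob)))
        row[f"{prefix}_n"] = len(y)
    return row


_METRIC_KEYS = ("accuracy", "precision", "recall", "f1", "mcc", "roc_auc",
                "tnr", "fpr", "fnr", "tpr")


def run_benchmark(
    datasets: dict[str, LabelledDataset],
    feature_sets: dict[str, FeatureMatrix],
    algorithms: dict[str, AlgorithmSpec] | None = None,
    seed: int = 0,
    calibration: str = "sigmoid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark every dataset × feature set × algorithm combination.

    Each combination runs the twelve fourfold iterations (one result row
    per iteration with train/validation/test scores); the summary table
    holds the per-combination mean and standard deviation of every
    metric.  A failing combination is logged and skipped, not fatal.
    Deterministic given ``seed``.
    """
    if algorithms is None:
        algorithms = default_algorithms()
    rows = []
    for ds_name, dataset in datasets.items():
        for fs_name, features in feature_sets.items():
            plans = make_splits(dataset, derive_seed(seed, "split", ds_name))
            for algo_name, spec in algorithms.items():
                for plan in plans:
                    it_seed = derive_seed(seed, "fit", ds_name, fs_name,
                                          algo_name, plan.iteration_index)
                    try:
                        row = run_iteration(dataset, features, spec, plan,
                                            seed=it_seed, calibration=calibration)
                    except Exception:
                        logger.exception(
                            "run_benchmark: %s/%s/%s iteration %d failed; skipped",
                            ds_name, fs_name, algo_name, plan.iteration_index)
                        continue
                    row.update({"dataset": ds_name, "feature_set": fs_name})
                    rows.append(row)
    results = pd.DataFrame(rows)
    summaries = []
    if not results.empty:
        for (ds, fs, algo), grp in results.groupby(
                ["dataset", "feature_set", "algorithm"], sort=False):
            s = {"dataset": ds, "feature_set": fs, "algorithm": algo,
                 "n_iterations": len(grp)}
            for split in ("train", "validation", "test"):
                for m in _METRIC_KEYS:
                    col = grp[f"{split}_{m}"].astype(float)
                    s[f"{split}_{m}_mean"] = col.mean()
                    s[f"{split}_{m}_sd"] = col.std(ddof=0)
            summaries.append(s)
    return results, pd.DataFrame(summaries)
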