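"""Training and evaluating label-revision classifiers.

The benchmark is a heavily imbalanced binary classification (a few hundred
revised pairs among tens of thousands reported), so the headline metric is
the Matthews correlation coefficient (MCC):

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which stays informative when classes are rare; any zero factor under the
root yields 0 by convention.  The module owns dataset splitting (stratified
7:3 by default), stratified k-fold cross-validation with transforms fitted
per fold, exhaustive feature selection (EFS — brute-force evaluation of
feature subsets under cross-validated MCC, with an explicit subset budget
and a greedy forward fallback for larger sizes), seeded random
hyperparameter search over the (C, gamma) box, permutation importance, and
decision-threshold sweeps.  Estimator internals are delegated to standard
libraries: an RBF-kernel SVM plus two pluggable gradient-boosting backends.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import TransformSpec, apply_transform, fit_transform

#: columns of a feature table that are never model inputs
META_COLS = ("drug", "disease", "label", "as_of", "onset_imputed", "dispro_imputed")


def _resolve_features(table, feature_cols, label_col):
    if feature_cols is not None:
        return tuple(feature_cols)
    skip = set(META_COLS) | {label_col}
    return tuple(c for c in table.columns if c not in skip)

DEFAULT_C_RANGE = (0.01, 3000.0)
DEFAULT_GAMMA_RANGE = (0.001, 1000.0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any root factor is zero."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def _precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def _recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def _auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, scores))


@dataclass(frozen=True)
class ModelSpec:
    """An estimator configuration; C/gamma apply to the RBF SVM."""

    kind: str = "rbf_svm"  # rbf_svm | gradient_boosting_a | gradient_boosting_b
    C: float = 10.0
    gamma: float = 0.5
    transform: str = "standardize"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rbf_svm", "gradient_boosting_a", "gradient_boosting_b"):
            raise ValueError(f"unknown estimator kind {self.kind!r}")
        if self.kind == "rbf_svm":
            if not DEFAULT_C_RANGE[0] <= self.C <= DEFAULT_C_RANGE[1]:
                raise ValueError(f"C={self.C} outside the search box {DEFAULT_C_RANGE}")
            if not DEFAULT_GAMMA_RANGE[0] <= self.gamma <= DEFAULT_GAMMA_RANGE[1]:
                raise ValueError(
                    f"gamma={self.gamma} outside the search box {DEFAULT_GAMMA_RANGE}"
                )
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def make_estimator(spec: ModelSpec, probability: bool = False):
    """Instantiate the configured estimator (lazy third-party imports)."""
    if spec.kind == "rbf_svm":
        from sklearn.svm import SVC

        return SVC(C=spec.C, gamma=spec.gamma, kernel="rbf",
                   probability=probability, random_state=spec.seed)
    if spec.kind == "gradient_boosting_a":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200, max_depth=4, learning_rate=0.1,
            random_state=spec.seed, n_jobs=1, verbosity=0, eval_metric="logloss",
        )
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        n_estimators=200, max_depth=-1, learning_rate=0.1,
        random_state=spec.seed, n_jobs=1, verbose=-1,
    )


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# splitting and cross-validation


def split_dataset(
    table: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the label column; deterministic."""
    if not 0 < ratio < 1:
        raise ValueError(f"train ratio must be in (0, 1), got {ratio}")
    labels = table[label_col]
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to split")
    train, test = train_test_split(
        table, train_size=ratio, stratify=labels, random_state=seed, shuffle=True
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _label_array(table: pd.DataFrame, label_col: str) -> np.ndarray:
    labels = table[label_col]
    if labels.dtype == object:
        return (labels == "positive").to_numpy()
    return labels.to_numpy().astype(bool)


@dataclass
class CVResult:
    folds: pd.DataFrame  # one row per fold: mcc, precision, recall, auc

    def mean(self, metric: str) -> float:
        return float(self.folds[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.folds[metric].std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)}
            for m in ("mcc", "precision", "recall", "auc")
        }


def cross_validate(
    spec: ModelSpec,
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    k: int = 5,
    seed: int = 0,
    label_col: str = "label",
    metrics: Sequence[str] = ("mcc", "precision", "recall", "auc"),
) -> CVResult:
    """Stratified k-fold CV; the transform is refitted inside every fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _label_array(table, label_col)
    if y.sum() < k or (~y).sum() < k:
        raise ValueError(
            f"each of the {k} folds needs both classes; "
            f"have {int(y.sum())} positives / {int((~y).sum())} negatives — use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = table[list(feature_cols)]
    rows = []
    for train_idx, valid_idx in skf.split(X, y):
        t_spec, Xt = fit_transform(X.iloc[train_idx], spec.transform)
        Xv = apply_transform(t_spec, X.iloc[valid_idx])
        est = make_estimator(spec)
        est.fit(Xt.to_numpy(dtype=float), y[train_idx])
        pred = est.predict(Xv.to_numpy(dtype=float)).astype(bool)
        c = confusion(y[valid_idx], pred)
        row = {"mcc": mcc(c), "precision": _precision(c), "recall": _recall(c)}
        if "auc" in metrics:
            row["auc"] = _auc(y[valid_idx], _scores(est, Xv.to_numpy(dtype=float)))
        else:
            row["auc"] = float("nan")
        rows.append(row)
    return CVResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# exhaustive feature selection


@dataclass
class EFSResult:
    best_subset: tuple[str, ...]
    best_score: float
    table: pd.DataFrame  # subset (str), size, mean metric


def efs(
    table: pd.DataFrame,
    spec: ModelSpec,
    subset_sizes: Iterable[int],
    feature_cols: Optional[Sequence[str]] = None,
    k: int = 5,
    seed: int = 0,
    budget: int = 100_000,
    label_col: str = "label",
) -> EFSResult:
    """Brute-force evaluation of every feature subset of the requested sizes.

    Scores each subset by cross-validated mean MCC; ties break toward the
    smaller subset and then lexicographic feature order.  Raises if the
    total subset count exceeds `budget`.
    """
    feature_cols = _resolve_features(table, feature_cols, label_col)
    sizes = sorted(set(int(s) for s in subset_sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("subset sizes must be positive integers (empty subset invalid)")
    n = len(feature_cols)
    if sizes[-1] > n:
        raise ValueError(f"subset size {sizes[-1]} exceeds the {n} available features")
    total = sum(math.comb(n, s) for s in sizes)
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the configured budget of {budget}; "
            "reduce subset sizes or use greedy_forward_selection"
        )
    ordered = sorted(feature_cols)
    rows = []
    best: Optional[tuple] = None  # (-score, size, subset)
    for size in sizes:
        for combo in itertools.combinations(ordered, size):
            cv = cross_validate(
                spec, table, combo, k=k, seed=seed, label_col=label_col, metrics=("mcc",)
            )
            score = cv.mean("mcc")
            rows.append({"subset": ",".join(combo), "size": size, "mean_mcc": score})
            key = (-score, size, combo)
            if best is None or key < best:
                best = key
    assert best is not None
    return EFSResult(
        best_subset=best[2], best_score=-best[0],
        table=pd.DataFrame(rows).sort_values("mean_mcc", ascending=False).reset_index(drop=True),
    )


def greedy_forward_selection(
    table: pd.DataFrame,
    spec: ModelSpec,
    max_size: int,
    feature_cols: Optional[Sequence[str]] = None,
    k: int = 5,
    seed: int = 0,
    label_col: str = "label",
) -> EFSResult:
    """Sequential fallback for subset sizes where exhaustive search is infeasible."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    feature_cols = _resolve_features(table, feature_cols, label_col)
    remaining = sorted(feature_cols)
    chosen: list[str] = []
    rows = []
    best_overall: Optional[tuple] = None
    while remaining and len(chosen) < max_size:
        step_best = None
        for f in remaining:
            combo = tuple(sorted(chosen + [f]))
            score = cross_validate(
                spec, table, combo, k=k, seed=seed, label_col=label_col, metrics=("mcc",)
            ).mean("mcc")
            rows.append({"subset": ",".join(combo), "size": len(combo), "mean_mcc": score})
            key = (-score, combo)
            if step_best is None or key < step_best:
                step_best = key
        chosen = list(step_best[1])
        remaining = [f for f in remaining if f not in chosen]
        overall_key = (step_best[0], len(chosen), tuple(chosen))
        if best_overall is None or overall_key < best_overall:
            best_overall = overall_key
    return EFSResult(
        best_subset=best_overall[2], best_score=-best_overall[0],
        table=pd.DataFrame(rows).sort_values("mean_mcc", ascending=False).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# hyperparameter search


def tune_hyperparams(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    base_spec: ModelSpec,
    iterations: int = 50,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    gamma_range: tuple[float, float] = DEFAULT_GAMMA_RANGE,
    k: int = 5,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[ModelSpec, pd.DataFrame]:
    """Seeded random search over log-uniform (C, gamma); best CV-MCC wins.

    Deterministic for a fixed seed.  Returns (best spec, trial table).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not (c_range[0] > 0 and c_range[1] >= c_range[0]):
        raise ValueError(f"empty or invalid C range {c_range}")
    if not (gamma_range[0] > 0 and gamma_range[1] >= gamma_range[0]):
        raise ValueError(f"empty or invalid gamma range {gamma_range}")
    rng = np.random.default_rng(seed)
    rows = []
    best: Optional[tuple] = None
    for i in range(iterations):
        C = float(np.exp(rng.uniform(np.log(c_range[0]), np.log(c_range[1]))))
        gamma = float(np.exp(rng.uniform(np.log(gamma_range[0]), np.log(gamma_range[1]))))
        spec = replace(base_spec, C=C, gamma=gamma)
        score = cross_validate(
            spec, table, feature_cols, k=k, seed=seed, label_col=label_col, metrics=("mcc",)
        ).mean("mcc")
        rows.append({"trial": i, "C": C, "gamma": gamma, "mean_mcc": score})
        key = (-score, i)
        if best is None or key < best:
            best = (key[0], key[1], spec)
    return best[2], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitted models, importance, thresholds


@dataclass
class FittedModel:
    spec: ModelSpec
    transform: TransformSpec
    estimator: object
    feature_cols: tuple[str, ...]

    def proba(self, X: pd.DataFrame) -> np.ndarray:
        Xt = apply_transform(self.transform, X[list(self.feature_cols)])
        return self.estimator.predict_proba(Xt.to_numpy(dtype=float))[:, 1]

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        Xt = apply_transform(self.transform, X[list(self.feature_cols)])
        return _scores(self.estimator, Xt.to_numpy(dtype=float))

    def predict(self, X: pd.DataFrame, threshold: Optional[float] = None) -> np.ndarray:
        thr = self.spec.threshold if threshold is None else threshold
        return self.proba(X) >= thr


def fit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    label_col: str = "label",
) -> FittedModel:
    y = _label_array(table, label_col)
    t_spec, Xt = fit_transform(table[list(feature_cols)], spec.transform)
    est = make_estimator(spec, probability=True)
    est.fit(Xt.to_numpy(dtype=float), y)
    return FittedModel(spec, t_spec, est, tuple(feature_cols))


def evaluate(
    model: FittedModel,
    table: pd.DataFrame,
    label_col: str = "label",
    threshold: Optional[float] = None,
) -> dict:
    y = _label_array(table, label_col)
    pred = model.predict(table, threshold)
    c = confusion(y, pred)
    return {
        "mcc": mcc(c),
        "precision": _precision(c),
        "recall": _recall(c),
        "auc": _auc(y, model.scores(table)),
        "confusion": c.to_dict(),
    }


def permutation_importance(
    model: FittedModel,
    table: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> pd.DataFrame:
    """Mean MCC drop when one feature's column is shuffled; seeded."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = _label_array(table, label_col)
    base = mcc(confusion(y, model.predict(table)))
    rng = np.random.default_rng(seed)
    rows = []
    for feat in model.feature_cols:
        drops = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[feat] = rng.permutation(shuffled[feat].to_numpy())
            drops.append(base - mcc(confusion(y, model.predict(shuffled))))
        rows.append(
            {"feature": feat, "importance": float(np.mean(drops)),
             "sd": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0}
        )
    return pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)


def threshold_sweep(
    model: FittedModel,
    table: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.5),
    label_col: str = "label",
) -> pd.DataFrame:
    """Confusion counts and metrics at each probability threshold."""
    y = _label_array(table, label_col)
    proba = model.proba(table)
    rows = []
    for thr in thresholds:
        if not 0 < thr < 1:
            raise ValueError(f"threshold must be in (0, 1), got {thr}")
        c = confusion(y, proba >= thr)
        rows.append(
            {"threshold": thr, "mcc": mcc(c), "precision": _precision(c),
             "recall": _recall(c), **c.to_dict()}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full benchmark report


@dataclass
class ModelReport:
    spec: ModelSpec
    selected_features: tuple[str, ...]
    cv: dict
    test: dict

    def to_dict(self) -> dict:
        return {
            "model": self.spec.kind,
            "C": self.spec.C,
            "gamma": self.spec.gamma,
            "transform": self.spec.transform,
            "threshold": self.spec.threshold,
            "selected_features": list(self.selected_features),
            "cv": self.cv,
            "test": self.test,
        }


def train_and_evaluate(
    table: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    feature_cols: Optional[Sequence[str]] = None,
    efs_sizes: Optional[Iterable[int]] = (1, 2),
    ratio: float = 0.7,
    k: int = 5,
    tune_iterations: int = 0,
    seed: int = 0,
    label_col: str = "label",
) -> ModelReport:
    """The full benchmark: split, (optionally) EFS, (optionally) tune, fit, test."""
    train, test = split_dataset(table, ratio=ratio, seed=seed, label_col=label_col)
    selected: Sequence[str] = _resolve_features(table, feature_cols, label_col)
    if efs_sizes is not None:
        selected = efs(
            train, spec, efs_sizes, feature_cols=feature_cols, k=k, seed=seed,
            label_col=label_col,
        ).best_subset
    if tune_iterations:
        spec, _ = tune_hyperparams(
            train, selected, spec, iterations=tune_iterations, k=k, seed=seed,
            label_col=label_col,
        )
    cv = cross_validate(spec, train, selected, k=k, seed=seed, label_col=label_col)
    model = fit_model(spec, train, selected, label_col=label_col)
    return ModelReport(
        spec=spec,
        selected_features=tuple(selected),
        cv=cv.summary(),
        test=evaluate(model, test, label_col=label_col),
    )
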