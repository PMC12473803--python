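"""Fixed model-development protocol for PD-vs-Control classification.

The protocol is deliberately rigid so that model comparisons are fair:

1. one participant-level, group-stratified 80/20 train-test split,
   reused identically by every model;
2. per model, greedy sequential forward selection (SFS) of features,
   scored by mean F1 over a stratified 5-fold inner cross-validation of
   the training set, with the subset size ``k`` chosen on a grid
   (ties toward smaller ``k``);
3. a single refit on the complete training set and one evaluation on
   the untouched test set, reporting the confusion matrix, accuracy,
   precision, recall/sensitivity, specificity, F1, ROC-AUC and the ROC
   and precision-recall curves.

Median imputation and (for scale-sensitive models) z-scoring are fitted
on fold-training data only, so no statistic ever leaks from validation
or test rows.  PD codes as the positive class (1).
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .registry import resolve

__all__ = [
    "MODEL_FAMILIES",
    "SplitSpec",
    "SelectionConfig",
    "SelectionResult",
    "EvaluationReport",
    "classification_metrics",
    "build_estimator",
    "make_split",
    "select_features",
    "evaluate",
    "run_benchmark",
    "consensus_features",
]

MODEL_FAMILIES = ("SVM-RBF", "LR", "RF", "k-NN", "Gaussian NB")
_SCALED_FAMILIES = {"SVM-RBF", "LR", "k-NN"}
_INNER_CV_SEED = 42

_NON_FEATURE_COLUMNS = ("group", "scenario")


@dataclass(frozen=True)
class SplitSpec:
    """Participant-level train/test split settings."""

    test_fraction: float = 0.2
    split_seed: int = 0
    stratify_by: str = "group"


@dataclass(frozen=True)
class SelectionConfig:
    """Sequential-forward-selection settings (forward direction, F1)."""

    k_grid: tuple[int, ...] = tuple(range(1, 37))
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.k_grid:
            raise ValueError("k_grid must be non-empty")
        if min(self.k_grid) < 1:
            raise ValueError("k values must be >= 1")


@dataclass
class SelectionResult:
    best_k: int
    features: list[str]
    path: list[str]                  # full greedy order up to max(k_grid)
    cv_curve: pd.DataFrame           # columns: k, mean_f1, sd_f1


@dataclass
class EvaluationReport:
    family: str
    hyperparameters: dict
    scaled: bool
    best_k: int
    selected_features: list[str]
    tn: int
    fp: int
    fn: int
    tp: int
    metrics: dict[str, float]
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    cv_curve: pd.DataFrame = field(default_factory=pd.DataFrame)


@contextmanager
def _quiet_fits():
    """Silence expected benign fit-time warnings.

    Gaussian NB emits divide-by-zero warnings when a candidate feature
    has zero training variance (its likelihood degenerates but the
    prediction is still defined); this sklearn release deprecates the
    ``probability=True`` SVC flag that the fixed hyperparameter table
    prescribes.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module=r"sklearn\.naive_bayes")
        warnings.filterwarnings("ignore", category=FutureWarning,
                                module=r"sklearn\.svm.*")
        yield


def build_estimator(family: str):
    """The fixed hyperparameterization of each model family."""
    if family == "SVM-RBF":
        return SVC(C=1.0, kernel="rbf", gamma="scale", class_weight="balanced",
                   probability=True, random_state=42)
    if family == "LR":
        return LogisticRegression(solver="lbfgs", max_iter=2000,
                                  class_weight="balanced", random_state=42)
    if family == "RF":
        return RandomForestClassifier(n_estimators=100, class_weight="balanced",
                                      random_state=42)
    if family == "k-NN":
        return KNeighborsClassifier(n_neighbors=5, weights="uniform",
                                    metric="minkowski", p=2)
    if family == "Gaussian NB":
        return GaussianNB(var_smoothing=1e-9)
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


def classification_metrics(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """Binary-classification metrics from confusion-matrix counts.

    Recall and sensitivity are synonyms (both reported); undefined
    ratios (zero denominator) are NaN.
    """
    total = tn + fp + fn + tp
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, denom: int) -> float:
        return num / denom if denom > 0 else float("nan")

    accuracy = (tp + tn) / total
    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
    }


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]


def make_split(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified participant-level split; every participant lands in
    exactly one partition and the same partition serves all models."""
    labels = table[spec.stratify_by]
    if labels.nunique() < 2 or labels.value_counts().min() < 2:
        raise ValueError("split requires at least 2 participants per class")
    train_idx, test_idx = train_test_split(
        table.index.to_numpy(),
        test_size=spec.test_fraction,
        stratify=labels,
        random_state=spec.split_seed,
    )
    train, test = table.loc[train_idx], table.loc[test_idx]
    for part, name in ((train, "train"), (test, "test")):
        if part["group"].nunique() < 2:
            raise ValueError(f"class absent from the {name} partition")
    return train, test


# ---------------------------------------------------------------------------
# preprocessing fitted on training data only


def _fit_imputer(X: np.ndarray) -> np.ndarray:
    medians = np.nanmedian(X, axis=0)
    return np.where(np.isnan(medians), 0.0, medians)


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan_rows, nan_cols = np.nonzero(np.isnan(out))
    out[nan_rows, nan_cols] = medians[nan_cols]
    return out


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def _prepare(
    X_fit: np.ndarray, others: list[np.ndarray], scaled: bool
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Median-impute (and optionally z-score) with statistics from X_fit."""
    medians = _fit_imputer(X_fit)
    X_fit = _impute(X_fit, medians)
    others = [_impute(o, medians) for o in others]
    if scaled:
        mean, std = _fit_scaler(X_fit)
        X_fit = (X_fit - mean) / std
        others = [(o - mean) / std for o in others]
    return X_fit, others


def _labels(part: pd.DataFrame) -> np.ndarray:
    return (part["group"] == "PD").to_numpy(dtype=int)


def select_features(
    train: pd.DataFrame, family: str, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Greedy forward selection scored by inner-CV F1.

    One greedy pass grows the subset to ``max(k_grid)``; the per-size
    scores along that path form the selection curve and ``best_k`` is
    the grid size with the highest mean inner-CV F1 (ties resolved
    toward the smallest ``k``; ties in greedy gain toward registry /
    column order).  Imputation and scaling statistics come from each
    fold's training rows only.
    """
    cfg = cfg or SelectionConfig()
    cols = feature_columns(train)
    if max(cfg.k_grid) > len(cols):
        raise ValueError("max(k_grid) exceeds the feature count")
    X = train[cols].to_numpy(dtype=float)
    y = _labels(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    scaled = family in _SCALED_FAMILIES
    base = build_estimator(family)
    splitter = StratifiedKFold(cfg.inner_folds, shuffle=True, random_state=_INNER_CV_SEED)
    folds = []
    for i, (tr, va) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"inner fold {i} is single-class in its training part")
        X_tr, (X_va,) = _prepare(X[tr], [X[va]], scaled)
        folds.append((X_tr, y[tr], X_va, y[va]))

    selected: list[int] = []
    remaining = list(range(len(cols)))
    curve_rows = []
    for _ in range(max(cfg.k_grid)):
        best_score, best_sd, best_j = -np.inf, np.nan, None
        for j in remaining:
            trial_cols = selected + [j]
            fold_scores = []
            with _quiet_fits():
                for X_tr, y_tr, X_va, y_va in folds:
                    est = clone(base)
                    est.fit(X_tr[:, trial_cols], y_tr)
                    fold_scores.append(
                        f1_score(y_va, est.predict(X_va[:, trial_cols]), zero_division=0)
                    )
            mean_score = float(np.mean(fold_scores))
            if mean_score > best_score:  # strict: ties keep earlier column
                best_score, best_j = mean_score, j
                best_sd = float(np.std(fold_scores, ddof=1))
        selected.append(best_j)
        remaining.remove(best_j)
        curve_rows.append({"k": len(selected), "mean_f1": best_score, "sd_f1": best_sd})

    curve = pd.DataFrame(curve_rows)
    grid_curve = curve[curve["k"].isin(cfg.k_grid)]
    best_k = int(grid_curve.loc[grid_curve["mean_f1"].idxmax(), "k"])  # first max: smallest k
    path = [cols[j] for j in selected]
    return SelectionResult(best_k, path[:best_k], path, curve)


def evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    family: str,
    selection: SelectionResult,
) -> EvaluationReport:
    """Refit on the complete training set and score once on the test set."""
    cols = selection.features
    scaled = family in _SCALED_FAMILIES
    X_train, (X_test,) = _prepare(
        train[cols].to_numpy(dtype=float), [test[cols].to_numpy(dtype=float)], scaled
    )
    y_train, y_test = _labels(train), _labels(test)

    with _quiet_fits():
        est = clone(build_estimator(family))
        est.fit(X_train, y_train)
        y_pred = est.predict(X_test)
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X_test)[:, 1]
        elif hasattr(est, "decision_function"):
            scores = est.decision_function(X_test)
        else:
            raise ValueError(f"{family}: no continuous score available for ROC analysis")

    tn = int(np.sum((y_test == 0) & (y_pred == 0)))
    fp = int(np.sum((y_test == 0) & (y_pred == 1)))
    fn = int(np.sum((y_test == 1) & (y_pred == 0)))
    tp = int(np.sum((y_test == 1) & (y_pred == 1)))
    metrics = classification_metrics(tn, fp, fn, tp)
    metrics["roc_auc"] = float(roc_auc_score(y_test, scores))

    fpr, tpr, roc_thr = roc_curve(y_test, scores)
    prec, rec, _ = precision_recall_curve(y_test, scores)
    return EvaluationReport(
        family=family,
        hyperparameters=build_estimator(family).get_params(),
        scaled=scaled,
        best_k=selection.best_k,
        selected_features=list(cols),
        tn=tn, fp=fp, fn=fn, tp=tp,
        metrics=metrics,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        pr_points=pd.DataFrame({"precision": prec, "recall": rec}),
        cv_curve=selection.cv_curve,
    )


def run_benchmark(
    table: pd.DataFrame,
    split_spec: SplitSpec | None = None,
    selection_cfg: SelectionConfig | None = None,
    families: tuple[str, ...] = MODEL_FAMILIES,
) -> dict[str, EvaluationReport]:
    """The full protocol: one shared split, then SFS + single evaluation
    per model family."""
    split_spec = split_spec or SplitSpec()
    train, test = make_split(table, split_spec)
    reports = {}
    for family in families:
        selection = select_features(train, family, selection_cfg)
        reports[family] = evaluate(train, test, family, selection)
    return reports


def consensus_features(
    reports: dict[str, EvaluationReport], min_models: int = 3
) -> pd.DataFrame:
    """Features retained by at least ``min_models`` of the model reports,
    sorted by how many models selected them."""
    if len(reports) < 2:
        raise ValueError("consensus requires at least 2 model reports")
    tally: dict[str, list[str]] = {}
    for family, report in reports.items():
        for name in report.selected_features:
            tally.setdefault(name, []).append(family)
    rows = []
    for name, families in tally.items():
        if len(families) < min_models:
            continue
        spec = resolve(name)
        rows.append({
            "feature": name,
            "models": ", ".join(families),
            "n_models": len(families),
            "domain": spec.domain,
            "axis": spec.axis,
        })
    out = pd.DataFrame(rows, columns=["feature", "models", "n_models", "domain", "axis"])
    return out.sort_values(["n_models", "feature"], ascending=[False, True], ignore_index=True)
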