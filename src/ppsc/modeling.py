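"""Candidate classifier zoo, soft-voting ensemble, and evaluation protocol.

Eight model families (logistic regression, cost-complexity-pruned decision
tree, random forest, linear-kernel SVM, AdaBoost, XGBoost, LightGBM, KNN)
are tuned by exhaustive grid search (3-fold stratified, AUROC objective)
and combined by unweighted soft voting. Validation is repeated stratified
cross-validation over the training partition (default 10 repeats x 5
folds) with preprocessing refit inside every cycle; test evaluation uses
the untouched 20% partition with train-fitted preprocessing. Metrics:
balanced accuracy, recall, precision, F1 from the confusion matrix at a
0.5 probability threshold (ties positive), AUROC by trapezoid with a
stratified-bootstrap 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

# lightgbm's sklearn wrapper emits this even for ndarray-only fits
warnings.filterwarnings("ignore", message="X does not have valid feature names")

from .exceptions import ParameterError
from .preprocess import SplitPlan, preprocess_apply, preprocess_fit

FAMILIES = (
    "logistic", "decision_tree", "random_forest", "svm_linear",
    "adaboost", "xgb", "lgbm", "knn",
)

#: Grid-search value sets per family.
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.7, 1.0, 1.2]},
    "decision_tree": {"ccp_alpha": [0.005, 0.01, 0.015, 0.02, 0.025]},
    "random_forest": {"n_estimators": [50, 100, 150], "ccp_alpha": [0.01, 0.05, 0.1]},
    "svm_linear": {"C": [0.4, 0.6, 0.8], "kernel": ["linear"], "degree": [2, 3]},
    "adaboost": {"n_estimators": [20, 40, 60, 100], "learning_rate": [0.6, 1.0, 1.4]},
    "xgb": {
        "n_estimators": [50, 100, 200],
        "learning_rate": [0.6, 0.8, 1.0, 1.2],
        "reg_alpha": [0.4, 0.8, 1.2, 1.6],
        "reg_lambda": [1.4, 1.8, 2.2, 2.6],
        "gamma": [0.6, 1.0, 1.4, 1.8],
    },
    "lgbm": {
        "n_estimators": [25, 50, 100],
        "learning_rate": [0.2, 0.4, 0.6, 0.8, 1.0],
        "reg_alpha": [0.8, 1.2, 1.6, 2.0],
        "reg_lambda": [0.8, 1.2, 1.6, 2.0],
    },
    "knn": {"n_neighbors": [5, 10, 15, 20, 25], "weights": ["uniform", "distance"]},
}

#: The tuned optimum for each family on the full training partition of the
#: reference protocol; used as defaults when tuning is switched off.
OPTIMAL_PARAMS: dict[str, dict] = {
    "logistic": {"C": 1.0},
    "decision_tree": {"ccp_alpha": 0.02},
    "random_forest": {"n_estimators": 100, "ccp_alpha": 0.05},
    "svm_linear": {"C": 0.6, "kernel": "linear", "degree": 2},
    "adaboost": {"n_estimators": 20, "learning_rate": 0.6},
    "xgb": {"n_estimators": 50, "learning_rate": 0.6, "reg_alpha": 0.8,
            "reg_lambda": 2.6, "gamma": 0.6},
    "lgbm": {"n_estimators": 25, "learning_rate": 0.2, "reg_alpha": 2.0, "reg_lambda": 2.0},
    "knn": {"n_neighbors": 25, "weights": "distance"},
}


def build_model(family: str, seed: int = 0, params: dict | None = None):
    """Instantiate one candidate classifier.

    Inverse-class-frequency weighting is applied for the five families that
    support it natively (logistic, tree, forest, SVM, LightGBM); AdaBoost,
    XGBoost and KNN run unweighted.
    """
    p = dict(params or {})
    if family == "logistic":
        return LogisticRegression(class_weight="balanced", max_iter=5000, random_state=seed, **p)
    if family == "decision_tree":
        return DecisionTreeClassifier(class_weight="balanced", random_state=seed, **p)
    if family == "random_forest":
        return RandomForestClassifier(class_weight="balanced", random_state=seed, n_jobs=1, **p)
    if family == "svm_linear":
        p.setdefault("kernel", "linear")
        # margin scores -> probabilities by Platt sigmoid fitted on
        # training-internal folds (soft voting needs calibrated outputs)
        svc = SVC(class_weight="balanced", random_state=seed, **p)
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **p)
    if family == "xgb":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                             verbosity=0, **p)
    if family == "lgbm":
        return LGBMClassifier(class_weight="balanced", random_state=seed, n_jobs=1,
                              verbose=-1, **p)
    if family == "knn":
        return KNeighborsClassifier(**p)
    raise ParameterError(f"unknown model family {family!r}")


def tune_and_fit(family: str, X, y, seed: int = 0, grid: dict | None = None,
                 tuning_folds: int = 3):
    """Exhaustive grid search maximizing mean AUROC across stratified
    tuning folds, then refit on the full matrix with the best set.

    Ties break in first-in-grid order (the search keeps the first best).
    Returns ``(fitted_model, best_params)``.
    """
    grid = grid if grid is not None else MODEL_GRIDS[family]
    if family == "svm_linear":  # the SVC sits inside the calibration wrapper
        grid = {f"estimator__{k}": v for k, v in grid.items()}
    cv = StratifiedKFold(n_splits=tuning_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(build_model(family, seed), grid, scoring="roc_auc", cv=cv,
                          n_jobs=1, refit=True)
    search.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    best = {k.removeprefix("estimator__"): v for k, v in search.best_params_.items()}
    return search.best_estimator_, best


def soft_vote_proba(models: dict, X) -> np.ndarray:
    """Ensemble positive-class probability: unweighted mean of components."""
    if not models:
        raise ParameterError("no component models")
    probs = []
    for name, m in models.items():
        if not hasattr(m, "predict_proba"):
            raise ParameterError(f"component {name!r} lacks probability output")
        probs.append(m.predict_proba(np.asarray(X, dtype=float))[:, 1])
    return np.mean(probs, axis=0)


def predict_labels(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Decision rule: probability >= threshold classifies positive."""
    return (np.asarray(probabilities) >= threshold).astype(int)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        return cls(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                   fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Balanced accuracy, recall, precision, F1. Undefined ratios (zero
    denominator) are reported as ``None``, never silently zero."""
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else None
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    bacc = (recall + specificity) / 2 if recall is not None and specificity is not None else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and precision + recall > 0
        else None
    )
    return {"balanced_accuracy": bacc, "recall": recall, "precision": precision, "f1": f1}


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as (1 - specificity, sensitivity) points."""
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def auroc(scores, labels) -> float:
    """Area under the empirical ROC curve by trapezoid integration.

    Equals the tie-corrected pairwise concordance probability between the
    positive- and negative-class score distributions.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ParameterError("AUROC needs both classes present")
    pts = roc_points(scores, y)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auroc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
             level: float = 0.95) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the AUROC."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        vals[b] = auroc(s[idx], y[idx])
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Per-model metric table for one evaluation phase."""

    phase: str  # "validation" | "test"
    table: pd.DataFrame  # index: model (8 families + soft_vote), columns: metrics
    auroc_ci: dict[str, tuple[float, float]]
    n_cycles: int = 1
    best_model: str | None = None
    params: dict[str, dict] = field(default_factory=dict)


def _resolve_params(families, X, y, seed, params, tuning_folds):
    """Per-family hyperparameters: fixed dict, printed defaults, or tuned
    once on the given matrix."""
    if params == "tune":
        out = {}
        for fam in families:
            _, best = tune_and_fit(fam, X, y, seed=seed, tuning_folds=tuning_folds)
            out[fam] = best
        return out
    if params == "optimal" or params is None:
        return {fam: dict(OPTIMAL_PARAMS[fam]) for fam in families}
    return {fam: dict(params[fam]) for fam in families}


def _fit_all(families, params, X, y, seed):
    models = {}
    for fam in families:
        m = build_model(fam, seed=seed, params=params[fam])
        m.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        models[fam] = m
    return models


def _score_models(models, X, y) -> dict[str, dict[str, float]]:
    out = {}
    X = np.asarray(X, dtype=float)
    for name, m in {**models, "soft_vote": None}.items():
        proba = soft_vote_proba(models, X) if name == "soft_vote" else m.predict_proba(X)[:, 1]
        cm = ConfusionMatrix.from_labels(y, predict_labels(proba))
        met = confusion_metrics(cm)
        met["auroc"] = auroc(proba, y)
        out[name] = met
    return out


def run_validation(
    X: pd.DataFrame,
    y,
    plan: SplitPlan,
    families=FAMILIES,
    params="optimal",
    integer_features=(),
    binary_features=(),
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified CV over the training partition.

    Hyperparameters are resolved once (tuned on the preprocessed full
    training partition when ``params='tune'``); each (repeat, fold) cycle
    then refits preprocessing and all models on its sub-training rows and
    scores the held-out fold. Reported metrics are means over all cycles;
    the AUROC CI is the percentile interval of the per-cycle values.
    """
    y = np.asarray(y).astype(int)
    if params == "tune":
        Xtr, imp, sc = preprocess_fit(X.iloc[plan.train_idx], integer_features,
                                      binary_features, seed=seed)
        params = _resolve_params(families, Xtr, y[plan.train_idx], seed, "tune",
                                 plan.tuning_folds)
    resolved = _resolve_params(families, None, None, seed, params, plan.tuning_folds)

    records: list[dict] = []
    for rep, fold, tr, va in plan.validation_cycles:
        Xtr, imp, sc = preprocess_fit(X.iloc[tr], integer_features, binary_features,
                                      seed=seed + rep)
        Xva = preprocess_apply(X.iloc[va], imp, sc, integer_features, binary_features)
        models = _fit_all(families, resolved, Xtr, y[tr], seed=seed + rep)
        scored = _score_models(models, Xva, y[va])
        for name, met in scored.items():
            records.append({"model": name, "repeat": rep, "fold": fold, **met})

    raw = pd.DataFrame(records)
    metrics = ["balanced_accuracy", "recall", "precision", "f1", "auroc"]
    table = raw.groupby("model")[metrics].mean().reindex(list(families) + ["soft_vote"])
    ci = {
        name: tuple(np.quantile(raw.loc[raw["model"] == name, "auroc"], [0.025, 0.975]))
        for name in table.index
    }
    best = table["auroc"].idxmax()
    return EvalReport(phase="validation", table=table, auroc_ci=ci,
                      n_cycles=len(plan.validation_cycles), best_model=best, params=resolved)


def run_test_evaluation(
    X: pd.DataFrame,
    y,
    plan: SplitPlan,
    families=FAMILIES,
    params="optimal",
    integer_features=(),
    binary_features=(),
    seed: int = 0,
    n_boot: int = 2000,
    return_models: bool = False,
):
    """Fit on the full training partition, evaluate on the untouched test
    partition with train-fitted preprocessing. Best model = highest test
    AUROC."""
    y = np.asarray(y).astype(int)
    Xtr, imp, sc = preprocess_fit(X.iloc[plan.train_idx], integer_features,
                                  binary_features, seed=seed)
    ytr = y[plan.train_idx]
    if params == "tune":
        params = _resolve_params(families, Xtr, ytr, seed, "tune", plan.tuning_folds)
    resolved = _resolve_params(families, None, None, seed, params, plan.tuning_folds)

    Xte = preprocess_apply(X.iloc[plan.test_idx], imp, sc, integer_features, binary_features)
    yte = y[plan.test_idx]
    models = _fit_all(families, resolved, Xtr, ytr, seed=seed)
    scored = _score_models(models, Xte, yte)
    ci = {}
    for name in scored:
        proba = (soft_vote_proba(models, Xte) if name == "soft_vote"
                 else models[name].predict_proba(np.asarray(Xte, dtype=float))[:, 1])
        ci[name] = auroc_ci(proba, yte, n_boot=n_boot, seed=seed)
    metrics = ["balanced_accuracy", "recall", "precision", "f1", "auroc"]
    table = pd.DataFrame(scored).T[metrics].reindex(list(families) + ["soft_vote"])
    report = EvalReport(phase="test", table=table, auroc_ci=ci, n_cycles=1,
                        best_model=table["auroc"].idxmax(), params=resolved)
    if return_models:
        return report, models, (Xtr, ytr, Xte, yte)
    return report
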