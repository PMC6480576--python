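"""Stage classification (healthy / mild / severe) and its validity panel.

Models: multinomial logistic regression — the softmax generalization of
P(X) = e^f(x)/(1+e^f(x)) with linear predictor f(x) = β0 + β1·x1 + … —
and an RBF-kernel support vector machine with internally standardized
features.  Both are evaluated on a single 50/50 percentage split: half
the subjects build the model, the other half test it.

The validity panel mirrors routine diagnostic-test reporting for a
three-class problem: per-class one-vs-rest sensitivity, specificity, PPV
and NPV with prevalence-weighted averages, overall accuracy, macro
one-vs-rest AUC (rank / Mann–Whitney formulation) and Cohen's kappa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import STAGES

__all__ = [
    "VARIABLE_GROUPS",
    "StageClassifier",
    "ValidityReport",
    "split_half",
    "fit_logistic",
    "fit_svm_rbf",
    "confusion_matrix",
    "cohen_kappa",
    "auc_score",
    "evaluate",
    "run_model_grid",
]

#: Table-4-style explanatory variable groups: single features, the
#: activity-distribution pair (FAD), activity volume (FAV), and all three
#: key features together (FADV).
VARIABLE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "SK": ("SK",),
    "KUR": ("KUR",),
    "FAV": ("DTAV",),
    "FAD": ("SK", "KUR"),
    "FADV": ("SK", "KUR", "DTAV"),
}


def split_half(
    table: pd.DataFrame, seed: int, stratified: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single random 50/50 percentage split into (train, test).

    Sizes are ceil(n/2) / floor(n/2).  Stratification preserves per-stage
    proportions up to rounding; a stage with fewer than 2 members forces a
    plain random split (with a warning) and may land entirely on one side.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = math.ceil(n / 2)
    strat = table["stage"] if (stratified and "stage" in table.columns) else None
    if strat is not None and strat.value_counts().min() < 2:
        warnings.warn(
            "a stage has fewer than 2 subjects; falling back to unstratified split",
            stacklevel=2,
        )
        strat = None
    train, test = train_test_split(
        table, train_size=n_train, random_state=seed, stratify=strat
    )
    return train, test


class StageClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style three-class stage classifier.

    ``method="lr"`` fits an (unpenalized, intercepted) multinomial
    logistic regression on the raw features; if the optimizer fails to
    converge — the signature of (quasi-)separated classes — the fit is
    repeated with an L2 ridge penalty and a note is logged.
    ``method="svm"`` fits a one-vs-one RBF SVC on standardized features
    (training statistics), C and gamma as given; ``gamma="scale"`` is
    1/(n_features · feature variance).
    """

    def __init__(self, method: str = "svm", C: float = 1.0, gamma="scale", max_iter: int = 5000):
        self.method = method
        self.C = C
        self.gamma = gamma
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2D with one row per label")
        classes = np.unique(y)
        if self.method == "svm" and len(classes) < 2:
            raise ValueError("SVM requires at least 2 classes in the training set")
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("degenerate constant feature in training data")
        if self.method == "lr":
            model = LogisticRegression(penalty=None, max_iter=self.max_iter)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model.fit(X, y)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                warnings.warn(
                    "unpenalized logistic fit did not converge (separation "
                    "suspected); refitting with L2 penalty",
                    stacklevel=2,
                )
                model = LogisticRegression(C=1.0, max_iter=self.max_iter)
                model.fit(X, y)
        elif self.method == "svm":
            model = make_pipeline(
                StandardScaler(),
                SVC(kernel="rbf", C=self.C, gamma=self.gamma, decision_function_shape="ovr"),
            )
            model.fit(X, y)
        else:
            raise ValueError(f"unknown method {self.method!r}; use 'lr' or 'svm'")
        self.model_ = model
        self.classes_ = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float64))

    def predict_scores(self, X) -> np.ndarray:
        """(n, k) class scores for ranking: probabilities for LR, one-vs-rest
        decision values for the SVM."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float64)
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(X)
        scores = self.model_.decision_function(X)
        if scores.ndim == 1:  # binary: make (n, 2)
            scores = np.column_stack([-scores, scores])
        return scores


def _xy(table: pd.DataFrame, features: Sequence[str]):
    return table[list(features)].to_numpy(dtype=np.float64), table["stage"].to_numpy()


def fit_logistic(train: pd.DataFrame, features: Sequence[str]) -> StageClassifier:
    clf = StageClassifier(method="lr")
    return clf.fit(*_xy(train, features))


def fit_svm_rbf(
    train: pd.DataFrame, features: Sequence[str], C: float = 1.0, gamma="scale"
) -> StageClassifier:
    clf = StageClassifier(method="svm", C=C, gamma=gamma)
    return clf.fit(*_xy(train, features))


def confusion_matrix(
    y_true, y_pred, classes: Sequence[str] = STAGES
) -> np.ndarray:
    """k×k counts, rows = truth, columns = prediction."""
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) from a confusion
    matrix; degenerate single-cell matrices (p_e = 1) return 0."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix (p_e = 1); kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """One-vs-rest AUC via the rank (Mann–Whitney) formulation."""
    scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(scores)
    n_pos, n_neg = pos.size, neg.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_score(scores: np.ndarray, labels, classes: Sequence[str] | None = None):
    """Per-class one-vs-rest AUC and its macro average.

    ``scores`` is (n, k), columns ordered like ``classes``.  Classes with
    no positive or no negative example are undefined (excluded from the
    macro average); a single-class label vector is an error.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if classes is None:
        classes = sorted(np.unique(labels))
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    per_class: dict[str, float] = {}
    for j, c in enumerate(classes):
        pos = scores[labels == c, j]
        neg = scores[labels != c, j]
        if pos.size and neg.size:
            per_class[c] = _rank_auc(pos, neg)
    macro = float(np.mean(list(per_class.values())))
    return macro, per_class


@dataclass
class ValidityReport:
    """One validity column: averaged panel plus its per-class breakdown."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float
    kappa: float
    n_test: int
    per_class: dict = field(default_factory=dict)
    confusion: list = field(default_factory=list)
    classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def _ovr_metrics(cm: np.ndarray, i: int) -> dict[str, float | None]:
    tp = cm[i, i]
    fn = cm[i, :].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp

    def ratio(num, den):
        return float(num / den) if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def evaluate(
    model: StageClassifier, test: pd.DataFrame, features: Sequence[str]
) -> ValidityReport:
    """Score a fitted model on the test half and build its validity column.

    Per-class one-vs-rest metrics are averaged weighted by class
    prevalence in the test truth; classes absent from the test set are
    flagged (metrics None) and excluded from the averages.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    X, y_true = _xy(test, features)
    y_pred = model.predict(X)
    classes = [c for c in STAGES if c in set(y_true) | set(model.classes_)]
    cm = confusion_matrix(y_true, y_pred, classes=classes)
    per_class = {}
    for i, c in enumerate(classes):
        m = _ovr_metrics(cm, i)
        m["present_in_test"] = bool(cm[i, :].sum() > 0)
        per_class[c] = m
    present = [c for c in classes if per_class[c]["present_in_test"]]
    weights = np.array([cm[classes.index(c), :].sum() for c in present], dtype=np.float64)
    weights /= weights.sum()

    def wavg(key):
        # average over classes where the ratio is defined, renormalized
        pairs = [(w, per_class[c][key]) for w, c in zip(weights, present)]
        pairs = [(w, v) for w, v in pairs if v is not None]
        wsum = sum(w for w, _ in pairs)
        return float(sum(w * v for w, v in pairs) / wsum) if wsum > 0 else float("nan")

    # AUC needs scores restricted to the model's class ordering
    score_cols = list(model.classes_)
    scores = model.predict_scores(X)
    macro_auc, auc_per_class = auc_score(scores, y_true, classes=score_cols)
    for c, v in auc_per_class.items():
        per_class.setdefault(c, {})["auc"] = v
    return ValidityReport(
        sensitivity=wavg("sensitivity"),
        specificity=wavg("specificity"),
        ppv=wavg("ppv"),
        npv=wavg("npv"),
        accuracy=float(np.trace(cm) / cm.sum()),
        auc=macro_auc,
        kappa=cohen_kappa(cm),
        n_test=int(cm.sum()),
        per_class=per_class,
        confusion=cm.tolist(),
        classes=classes,
    )


def run_model_grid(
    table: pd.DataFrame,
    seed: int,
    C: float = 1.0,
    gamma="scale",
    stratified: bool = True,
) -> dict[tuple[str, str], ValidityReport]:
    """Fit and validate every (method × variable group) cell on one shared
    50/50 split: 2 methods × 5 groups = 10 validity reports."""
    train, test = split_half(table, seed=seed, stratified=stratified)
    out: dict[tuple[str, str], ValidityReport] = {}
    for group, feats in VARIABLE_GROUPS.items():
        lr = fit_logistic(train, feats)
        out[("lr", group)] = evaluate(lr, test, feats)
        svm = fit_svm_rbf(train, feats, C=C, gamma=gamma)
        out[("svm", group)] = evaluate(svm, test, feats)
    return out


def grid_to_frame(grid: Mapping[tuple[str, str], ValidityReport]) -> pd.DataFrame:
    """Render a model grid as a metrics × (method, group) table."""
    metrics = ["sensitivity", "specificity", "ppv", "npv", "accuracy", "auc", "kappa"]
    data = {
        (method.upper(), group): [getattr(rep, m) for m in metrics]
        for (method, group), rep in grid.items()
    }
    return pd.DataFrame(data, index=metrics)
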