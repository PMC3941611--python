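"""Ridge regression from contact-vector features to ΔΔG, leave-one-out
evaluation and hot-spot classification metrics.

Feature columns are z-scored with statistics estimated on the training rows
only (re-estimated inside every cross-validation fold); constant columns get
coefficient zero. The ridge solve is the deterministic closed form (SVD).
ΔΔG ≥ 2 kcal/mol defines a hot spot, for both the experimental labels and
the predictions. The squared-error summary uses the N−1 denominator:
SE = Σ(ΔΔG_e − ΔΔG_p)² / (N−1), δ = √SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge

HOTSPOT_THRESHOLD = 2.0        # kcal/mol
OUTLIER_LOW, OUTLIER_HIGH = -3.0, 11.0  # predicted-ΔΔG outlier bounds
DEFAULT_LAMBDA = 1.0


@dataclass
class RegressionModel:
    coef: np.ndarray           # one per input column (zeros for constant cols)
    intercept: float
    mean: np.ndarray
    sd: np.ndarray             # 1.0 stored for constant columns
    ridge_lambda: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean) / self.sd
        return Z @ self.coef + self.intercept


def ridge_fit(X: np.ndarray, y: np.ndarray,
              ridge_lambda: float = DEFAULT_LAMBDA) -> RegressionModel:
    """Fit ridge regression on z-scored columns (closed-form SVD solve)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per y value")
    if len(X) < 2:
        raise ValueError("at least two training rows are required")
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be non-negative")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    live = sd > 0
    sd_safe = np.where(live, sd, 1.0)
    Z = (X - mean) / sd_safe
    coef = np.zeros(X.shape[1])
    model = Ridge(alpha=ridge_lambda, fit_intercept=True, solver="svd")
    model.fit(Z[:, live], y)
    coef[live] = model.coef_
    return RegressionModel(coef=coef, intercept=float(model.intercept_),
                           mean=mean, sd=sd_safe, ridge_lambda=ridge_lambda)


def loocv_predict(X: np.ndarray, y: np.ndarray,
                  ridge_lambda: float = DEFAULT_LAMBDA,
                  groups: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out predictions (or leave-one-group-out when ``groups``
    is given), with column normalisation re-estimated per fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three rows for leave-one-out")
    pred = np.empty(n)
    fold_ids = np.arange(n) if groups is None else np.asarray(groups)
    for g in np.unique(fold_ids):
        test = fold_ids == g
        model = ridge_fit(X[~test], y[~test], ridge_lambda)
        pred[test] = model.predict(X[test])
    return pred


@dataclass
class EvaluationReport:
    r: float                    # Pearson R on all points (nan if undefined)
    r_no_outliers: float        # Pearson R after removing flagged outliers
    se: float                   # mean squared error, N-1 denominator
    delta: float                # sqrt(SE), "average standard deviation"
    outliers: list[int]         # row indices with out-of-range predictions
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    accuracy: float = 0.0
    precision_defined: bool = True
    predictions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def as_dict(self) -> dict:
        return {
            "R": self.r, "R_no_outliers": self.r_no_outliers,
            "SE": self.se, "delta": self.delta,
            "outliers": self.outliers,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "precision": self.precision, "recall": self.recall,
            "F1": self.f1, "accuracy": self.accuracy,
            "precision_defined": self.precision_defined,
        }


def regression_metrics(pred: np.ndarray, exp: np.ndarray):
    """(R, SE, δ, outlier indices, R without outliers).

    R is nan when either vector has zero variance. Outliers (predictions
    below −3 or above 11 kcal/mol) are flagged and reported, never dropped
    from SE/δ; R is additionally reported with them removed.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    n = len(pred)
    if n != len(exp) or n < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    se = float(((exp - pred) ** 2).sum() / (n - 1))
    delta = float(np.sqrt(se))

    def pearson(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(stats.pearsonr(a, b).statistic)

    r = pearson(pred, exp)
    outliers = [int(i) for i in np.flatnonzero(
        (pred < OUTLIER_LOW) | (pred > OUTLIER_HIGH))]
    keep = np.ones(n, dtype=bool)
    keep[outliers] = False
    r_no = pearson(pred[keep], exp[keep]) if keep.sum() >= 3 else float("nan")
    return r, se, delta, outliers, r_no


def classify_hotspots(pred: np.ndarray) -> np.ndarray:
    """Hot spot iff predicted ΔΔG ≥ 2 kcal/mol (inclusive boundary)."""
    return np.asarray(pred, dtype=float) >= HOTSPOT_THRESHOLD


def classification_metrics(pred_labels, true_labels) -> dict:
    """Precision, recall, F1, accuracy from hot-spot labels (positives).

    With no positive predictions, precision (and hence F1) is reported as 0
    with ``precision_defined`` false rather than raising.
    """
    p = np.asarray(pred_labels, dtype=bool)
    t = np.asarray(true_labels, dtype=bool)
    if len(p) != len(t):
        raise ValueError("label vectors differ in length")
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    fn = int((~p & t).sum())
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    accuracy = (tp + tn) / len(p) if len(p) else 0.0
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "precision": precision, "recall": recall, "F1": f1,
            "accuracy": accuracy, "precision_defined": precision_defined}


def evaluate(X: np.ndarray, y: np.ndarray,
             ridge_lambda: float = DEFAULT_LAMBDA,
             groups: np.ndarray | None = None) -> EvaluationReport:
    """Leave-one-out (or leave-one-group-out) evaluation: regression and
    hot-spot classification metrics in one report."""
    pred = loocv_predict(X, y, ridge_lambda, groups)
    r, se, delta, outliers, r_no = regression_metrics(pred, y)
    cm = classification_metrics(classify_hotspots(pred), classify_hotspots(y))
    return EvaluationReport(
        r=r, r_no_outliers=r_no, se=se, delta=delta, outliers=outliers,
        tp=cm["TP"], fp=cm["FP"], tn=cm["TN"], fn=cm["FN"],
        precision=cm["precision"], recall=cm["recall"], f1=cm["F1"],
        accuracy=cm["accuracy"], precision_defined=cm["precision_defined"],
        predictions=pred,
    )
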