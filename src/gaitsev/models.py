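"""Severity classification and logistic-regression analysis.

The four-class severity classifier is a soft-margin RBF support vector
machine evaluated by stratified k-fold cross-validation: out-of-fold
predictions are pooled into a single 4x4 confusion matrix and summarised
with macro one-vs-rest metrics (accuracy, PPV, sensitivity, specificity,
F1, NPV) and macro one-vs-rest AUC from the decision scores.  Features are
standardized inside each fold using training-fold statistics only, and the
RBF kernel scale is set per fold by the median heuristic on the training
pairwise distances.

The conventional-statistics counterpart is maximum-likelihood logistic
regression (healthy controls vs. the dementia group, CDR >= 1) with Wald
95% confidence intervals on the odds ratios, Cox-Snell R^2 and its
max-rescaled (Nagelkerke) form, and classification accuracy at the 0.5
probability threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import GROUPS
from .features import FEATURE_NAMES

__all__ = [
    "CLASS_ORDER",
    "CvReport",
    "LogisticFit",
    "multiclass_metrics",
    "train_eval_svm",
    "fit_logistic",
    "cv_logistic_accuracy",
]

#: fixed class order of every confusion matrix (rows = actual)
CLASS_ORDER = GROUPS


@dataclass
class CvReport:
    """Cross-validated classification report for the 4-class severity task."""

    confusion: np.ndarray  # (4, 4) counts, rows = actual
    accuracy: float  # %
    precision_ppv: float  # % macro one-vs-rest
    recall_sensitivity: float  # %
    specificity: float  # %
    f1: float  # %
    npv: float  # %
    auc: float  # macro one-vs-rest, [0, 1]
    fold_count: int
    seed: int | None
    kernel_spec: dict = field(default_factory=dict)
    features: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "class_order": list(CLASS_ORDER),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision_ppv": self.precision_ppv,
            "recall_sensitivity": self.recall_sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "npv": self.npv,
            "auc": self.auc,
            "fold_count": self.fold_count,
            "seed": self.seed,
            "kernel_spec": self.kernel_spec,
            "features": list(self.features),
        }
        return d


def multiclass_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Macro one-vs-rest metric panel from a square confusion matrix.

    Percent scale for all entries.  F1 is the harmonic mean of the macro PPV
    and macro sensitivity.  A class with a zero denominator contributes 0 to
    the corresponding macro mean (with a warning).
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (c < 0).any() or c.sum() <= 0:
        raise ValueError("confusion matrix needs non-negative counts, total > 0")
    total = c.sum()
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe(num, den, name):
        den = np.asarray(den, dtype=float)
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        if not ok.all():
            warnings.warn(f"zero denominator in {name}; class contributes 0", stacklevel=2)
        out[ok] = num[ok] / den[ok]
        return out

    ppv = safe(tp, tp + fp, "PPV").mean() * 100.0
    sens = safe(tp, tp + fn, "sensitivity").mean() * 100.0
    spec = safe(tn, tn + fp, "specificity").mean() * 100.0
    npv = safe(tn, tn + fn, "NPV").mean() * 100.0
    f1 = 2.0 * ppv * sens / (ppv + sens) if (ppv + sens) > 0 else 0.0
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision_ppv": ppv,
        "recall_sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "npv": npv,
    }


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma = 1 / (2 s^2), s the median pairwise Euclidean distance."""
    d = pdist(X)
    d = d[d > 0]
    s = float(np.median(d)) if d.size else 1.0
    return 1.0 / (2.0 * s * s) if s > 0 else 1.0


def train_eval_svm(
    table: pd.DataFrame,
    selected_features: list[str] | None = None,
    folds: int = 5,
    seed: int | None = 0,
    kernel: str = "rbf",
    C: float = 1.0,
) -> CvReport:
    """Stratified k-fold cross-validated SVM severity classification.

    ``table`` is a feature table with ``group`` labels; out-of-fold
    predictions are pooled into one confusion matrix in the fixed class
    order healthy -> MCI -> mild -> moderate.
    """
    features = list(selected_features or FEATURE_NAMES)
    X = table[features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = table.loc[~np.isfinite(X).all(axis=1), "subject_id"].tolist()
        raise ValueError(f"non-finite features for subjects {bad}")
    y = table["group"].to_numpy()
    present = [c for c in CLASS_ORDER if c in set(y)]
    if len(present) < 2:
        raise ValueError("need at least two classes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].to_dict()
        raise ValueError(f"classes too small for {folds}-fold stratification: {small}")

    class_to_col = {c: i for i, c in enumerate(present)}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(present)))
    gamma_used = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        gamma = median_heuristic_gamma(Xtr) if kernel == "rbf" else "scale"
        gamma_used.append(gamma if kernel == "rbf" else float("nan"))
        clf = SVC(
            C=C, kernel=kernel, gamma=gamma, decision_function_shape="ovr"
        ).fit(Xtr, y[train])
        y_pred[test] = clf.predict(Xte)
        df = clf.decision_function(Xte)
        if df.ndim == 1:  # binary: score for the positive class
            pos = class_to_col[clf.classes_[1]]
            neg = class_to_col[clf.classes_[0]]
            scores[test, pos] = df
            scores[test, neg] = -df
        else:
            for j, cls in enumerate(clf.classes_):
                scores[test, class_to_col[cls]] = df[:, j]

    conf = confusion_matrix(y, list(y_pred), labels=list(present))
    panel = multiclass_metrics(conf)
    aucs = []
    for cls, col in class_to_col.items():
        aucs.append(roc_auc_score((y == cls).astype(int), scores[:, col]))
    return CvReport(
        confusion=conf,
        auc=float(np.mean(aucs)),
        fold_count=folds,
        seed=seed,
        kernel_spec={
            "kernel": kernel,
            "C": C,
            "gamma": "median-heuristic" if kernel == "rbf" else "scale",
            "gamma_per_fold": [float(g) for g in gamma_used],
        },
        features=tuple(features),
        **panel,
    )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with ORs and pseudo-R-squares."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, CI low, CI high
    p_values: dict[str, float]
    r_square: float  # Cox-Snell
    max_rescaled_r_square: float  # Nagelkerke
    classification_accuracy: float  # % at threshold 0.5
    n: int
    converged: bool
    separation_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "odds_ratios": {k: list(v) for k, v in self.odds_ratios.items()},
            "p_values": self.p_values,
            "r_square": self.r_square,
            "max_rescaled_r_square": self.max_rescaled_r_square,
            "classification_accuracy": self.classification_accuracy,
            "n": self.n,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


def dementia_outcome(table: pd.DataFrame, include_mci: bool = False) -> pd.DataFrame:
    """Restrict a feature table to healthy controls vs. the dementia group.

    The dementia group is mild + moderate (CDR >= 1); MCI is excluded by
    default and included via ``include_mci``.
    """
    dem = {"mild_dementia", "moderate_dementia"} | ({"mci"} if include_mci else set())
    sub = table[table["group"].isin(dem | {"healthy_control"})].copy()
    sub["outcome"] = sub["group"].isin(dem).astype(int)
    return sub


def _irls_logit(X1: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Uses the pseudo-inverse for the Newton step so that quasi-separated
    designs do not hard-fail; separation shows up as diverging coefficients
    and is flagged by the caller.  Returns (beta, cov, log_likelihood,
    converged).
    """
    n, p = X1.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -35.0, 35.0)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X1.T @ (y - mu)
        hess = X1.T @ (X1 * w[:, None])
        step = np.linalg.pinv(hess) @ grad
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X1 @ beta, -35.0, 35.0)
    mu = expit(eta)
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1.0 - y) * np.log(1.0 - mu + eps)))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv(X1.T @ (X1 * w[:, None]))
    return beta, cov, ll, converged


def _null_loglik(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return n * (p * math.log(p) + (1.0 - p) * math.log(1.0 - p))


def fit_logistic(
    table: pd.DataFrame, predictors: list[str], outcome: str = "outcome"
) -> LogisticFit:
    """Univariable or multivariable logistic regression by IRLS.

    Wald 95% CIs as exp(beta +/- 1.96 SE); Cox-Snell
    R^2 = 1 - exp((2/n)(LL0 - LL1)); max-rescaled (Nagelkerke)
    R^2 = Cox-Snell / (1 - exp(2 LL0 / n)).  (Quasi-)separated data yield a
    flagged result with a diverged-coefficient warning rather than a silent
    estimate.
    """
    y = table[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = table[list(predictors)].to_numpy(dtype=float)
    n = len(y)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    X1 = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X1) < X.shape[1] + 1:
        raise ValueError(f"singular design among predictors {list(predictors)}")

    beta, cov, ll1, converged = _irls_logit(X1, y)
    separation = bool(np.max(np.abs(beta)) > 30.0) or not converged
    if separation:
        warnings.warn(
            "quasi-complete separation: coefficients diverged, "
            "odds ratios and CIs are unreliable",
            stacklevel=2,
        )

    ll0 = _null_loglik(y)
    cox_snell = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / denom if denom > 0 else 0.0
    prob = expit(np.clip(X1 @ beta, -35.0, 35.0))
    acc = 100.0 * float(np.mean((prob >= 0.5) == (y == 1)))

    names = ["const", *predictors]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    coef = dict(zip(names, map(float, beta)))
    se_d = dict(zip(names, map(float, se)))
    z = {p: coef[p] / se_d[p] if se_d[p] > 0 else 0.0 for p in predictors}
    pvals = {p: float(2.0 * stats.norm.sf(abs(z[p]))) for p in predictors}
    ors = {
        p: (
            math.exp(min(coef[p], 35.0)),
            math.exp(min(coef[p] - 1.96 * se_d[p], 35.0)),
            math.exp(min(coef[p] + 1.96 * se_d[p], 35.0)),
        )
        for p in predictors
    }
    return LogisticFit(
        predictors=tuple(predictors),
        coefficients=coef,
        odds_ratios=ors,
        p_values=pvals,
        r_square=cox_snell,
        max_rescaled_r_square=max(0.0, min(1.0, nagelkerke)),
        classification_accuracy=acc,
        n=n,
        converged=converged,
        separation_flag=separation,
    )


def cv_logistic_accuracy(
    table: pd.DataFrame,
    predictors: list[str],
    outcome: str = "outcome",
    folds: int = 5,
    seed: int | None = 0,
) -> float:
    """Pooled out-of-fold accuracy (%) of the logistic model at threshold 0.5."""
    y = table[outcome].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        X1 = np.column_stack([np.ones(len(train)), X[train]])
        beta, _, _, _ = _irls_logit(X1, y[train])
        eta = np.clip(np.column_stack([np.ones(len(test)), X[test]]) @ beta, -35, 35)
        correct += int(np.sum((expit(eta) >= 0.5) == (y[test] == 1)))
    return 100.0 * correct / len(y)
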