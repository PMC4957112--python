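"""Evaluation statistics: RMSE, classification error, ROC/AUC with 95% CI,
Youden-optimal operating points, stratified k-fold CV, and the paired
Wilcoxon signed-rank comparison.

Conventions, fixed and tested:

* AUC is the Mann–Whitney probability that a random positive scores above
  a random negative, with ties counted 1/2.
* The AUC confidence interval is Hanley–McNeil: with ``A`` the AUC,
  ``Q1 = A/(2-A)``, ``Q2 = 2A^2/(1+A)``,
  ``SE^2 = (A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)) / (n+ n-)``,
  and the 95% interval is ``A +/- 1.96 SE`` clipped to [0, 1].
* The "optimal threshold" maximises Youden's J = sensitivity +
  specificity - 1 over observed score cut-points (predict positive when
  score >= cut); ties take the lowest threshold.
* The Wilcoxon signed-rank test drops zero differences, midranks ties,
  and uses the tie-corrected normal approximation with a 0.5 continuity
  correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.base import clone, is_classifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ROCResult",
    "CVResult",
    "rmse",
    "class_error",
    "roc_auc",
    "auc_ci",
    "optimal_threshold",
    "roc_report",
    "kfold_cv",
    "wilcoxon_paired",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("labels must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def rmse(pred, truth) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be nonempty and equal-length")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def class_error(pred_labels, truth) -> float:
    """Fraction of mismatched labels, in [0, 1]."""
    pred_labels = np.asarray(pred_labels)
    truth = np.asarray(truth)
    if pred_labels.size == 0 or pred_labels.shape != truth.shape:
        raise ValueError("pred and truth must be nonempty and equal-length")
    return float(np.mean(pred_labels != truth))


def roc_auc(scores, labels) -> float:
    """Mann–Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley–McNeil confidence interval for an AUC."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = np.sqrt(max(var, 0.0))
    z = float(norm.ppf(0.5 + level / 2.0))
    return float(max(a - z * se, 0.0)), float(min(a + z * se, 1.0))


def optimal_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Youden-optimal cut: ``(threshold, sensitivity, specificity, accuracy)``.

    A sample is called positive when its score is >= the threshold; the
    threshold maximising J over the observed scores is returned, the
    lowest such threshold on ties.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    cuts = np.unique(scores)  # ascending
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    n_pos, n_neg = pos.size, neg.size
    # P(score >= cut | class), via counts below each cut
    sens = 1.0 - np.searchsorted(pos, cuts, side="left") / n_pos
    spec = np.searchsorted(neg, cuts, side="left") / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max -> lowest threshold
    acc = (sens[best] * n_pos + spec[best] * n_neg) / (n_pos + n_neg)
    return float(cuts[best]), float(sens[best]), float(spec[best]), float(acc)


@dataclass
class ROCResult:
    """AUC with CI, the Youden operating point, and the ROC curve points."""

    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    curve: list[tuple[float, float]] = field(default_factory=list)


def roc_report(scores, labels) -> ROCResult:
    """Full ROC analysis of one score vector against binary labels."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_binary(labels)
    auc = roc_auc(scores, labels)
    n_pos = int(labels.sum())
    lo, hi = auc_ci(auc, n_pos, labels.size - n_pos)
    thr, sens, spec, acc = optimal_threshold(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return ROCResult(auc, lo, hi, thr, sens, spec, acc, list(zip(fpr.tolist(), tpr.tolist())))


@dataclass
class CVResult:
    fold_metrics: list[dict]
    mean_metrics: dict
    fold_assignments: np.ndarray  # fold id per sample


def kfold_cv(X, y, estimator, k: int = 10, seed: int = 0) -> CVResult:
    """Seeded k-fold cross-validation, stratified for classifiers.

    Stratification guarantees every test fold contains both classes
    (provided each class has at least ``k`` members), so no fold is ever
    scored single-class.  Classification folds report AUC (+ CI),
    error/accuracy and the Youden operating point; regression folds report
    RMSE.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k > len(y):
        raise ValueError("k cannot exceed the number of samples")
    classification = is_classifier(estimator)
    if classification:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    folds = np.empty(len(y), dtype=int)
    fold_metrics: list[dict] = []
    for fold_id, (tr, te) in enumerate(splitter.split(X, y if classification else None)):
        folds[te] = fold_id
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        if classification:
            scores = est.predict_proba(X[te])[:, 1]
            y01 = (y[te] == est.classes_[-1]).astype(int)
            rep = roc_report(scores, y01)
            fold_metrics.append(
                {
                    "auc": rep.auc,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                    "error": class_error(est.predict(X[te]), y[te]),
                }
            )
        else:
            fold_metrics.append({"rmse": rmse(est.predict(X[te]), y[te])})

    mean_metrics = {
        key: float(np.mean([m[key] for m in fold_metrics])) for key in fold_metrics[0]
    }
    return CVResult(fold_metrics, mean_metrics, folds)


def wilcoxon_paired(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; absolute differences are midranked; W is
    the sum of ranks of positive differences (x - y).  The p-value uses the
    normal approximation with tie-corrected variance
    ``n(n+1)(2n+1)/24 - sum(t^3 - t)/48`` and a 0.5 continuity correction.
    ``alternative='less'`` tests whether x is systematically below y.
    Returns ``(W, p)``; all differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length nonempty 1-D vectors")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0.0:
        return w, 1.0
    sd = np.sqrt(var)

    if alternative == "less":
        p = float(norm.cdf((w - mu + 0.5) / sd))
    elif alternative == "greater":
        p = float(norm.sf((w - mu - 0.5) / sd))
    else:
        z = (w - mu - 0.5 * np.sign(w - mu)) / sd
        p = float(min(2.0 * norm.sf(abs(z)), 1.0))
    return w, p
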