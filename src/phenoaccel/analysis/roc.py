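"""AUROC with DeLong variance, and the paired DeLong comparison test.

The AUC is the Mann–Whitney concordance probability (ties count one half).
Its variance, and the covariance between two AUCs computed from paired
scores on the same patients, follow DeLong, DeLong & Clarke-Pearson (1988)
via placement values: the placement of a positive is the fraction of
negatives it outranks, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["RocResult", "auroc", "compare_auroc"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    se: float


def _check_labels(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC plus placement values of positives (V10) and negatives (V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auroc(scores, labels, alpha: float = 0.05) -> RocResult:
    """Mann–Whitney AUC with a DeLong-variance confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_labels(labels)
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha / 2)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n_pos=m,
        n_neg=n,
        se=se,
    )


def compare_auroc(scores_a, scores_b, labels) -> dict:
    """DeLong test for two correlated ROC curves on the same patients.

    Returns the AUC difference (a minus b), its standard error and the
    two-sided p-value. Identical score vectors give difference 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired scores and labels must have equal length")
    _check_labels(labels)

    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        # degenerate: perfectly correlated placements (e.g. identical scores)
        p = 1.0 if diff == 0 else 0.0
        return {"auc_a": auc_a, "auc_b": auc_b, "difference": diff, "se": 0.0, "p_value": p}
    se = float(np.sqrt(var))
    zstat = diff / se
    p = float(2 * norm.sf(abs(zstat)))
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": float(diff), "se": se, "p_value": p}
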