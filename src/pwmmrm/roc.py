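"""ROC analysis: tie-aware AUC and a case-resampling bootstrap interval.

The AUC is computed through midranks, which makes it identical (not just
asymptotically equal) to the Mann-Whitney pair statistic

    AUC = (#{score_pos > score_neg} + 0.5 * #{score_pos = score_neg}) / (n1*n0).

The bootstrap resamples subjects with replacement; resamples containing a
single class leave the AUC undefined and are redrawn.  The percentile
interval is widened, if necessary, to contain the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ROCResult", "roc_auc", "roc_curve_points", "bootstrap_auc_ci"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)
    n_bootstrap: int
    level: float


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: only one class present")


def roc_auc(scores, labels) -> float:
    """Tie-aware AUC of ``scores`` against binary ``labels`` (1 = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve_points(scores, labels) -> np.ndarray:
    """Ordered (false-positive-rate, true-positive-rate) points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    # collapse tied scores into single thresholds
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    idx = np.r_[np.nonzero(distinct)[0][1:] - 1, s.size - 1]
    tpr = tp[idx] / lab.sum()
    fpr = fp[idx] / (lab.size - lab.sum())
    pts = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_redraws: int = 1000,
) -> ROCResult:
    """Percentile bootstrap confidence interval for the AUC.

    Reproducible given ``seed``; requires ``n_boot >= 100`` so the percentile
    endpoints are meaningfully estimated.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        aucs[b] = roc_auc(scores[idx], lab)
    alpha = 1.0 - level
    lo = float(np.quantile(aucs, alpha / 2.0))
    hi = float(np.quantile(aucs, 1.0 - alpha / 2.0))
    return ROCResult(
        auc=point,
        ci_low=min(lo, point),
        ci_high=max(hi, point),
        curve=roc_curve_points(scores, labels),
        n_bootstrap=n_boot,
        level=level,
    )
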