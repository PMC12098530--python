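"""ROC/AUC statistics for paired model comparison.

Implements the Mann-Whitney AUC estimator (ties half-credited), DeLong's
asymptotic test for two correlated ROC curves via placement values, and
stratified-bootstrap percentile confidence intervals for the AUC.

All routines operate on :class:`ScoredOutcome` pairs of continuous scores
and binary labels — typically pooled out-of-fold predictions from
cross-validation, so that two models evaluated on the same subjects can be
compared with a paired test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = [
    "ScoredOutcome",
    "AucEstimate",
    "DeLongComparison",
    "auc_mann_whitney",
    "delong_components",
    "delong_paired_test",
    "delong_ci",
    "stratified_bootstrap_ci",
]


@dataclass(frozen=True)
class ScoredOutcome:
    """Per-subject continuous scores paired with true binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-d vectors")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        if labels.sum() == 0 or labels.sum() == labels.size:
            raise ValueError("need at least one positive and one negative label")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int8))

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


@dataclass(frozen=True)
class AucEstimate:
    """Point AUC with a confidence interval and the method that produced it."""

    auc: float
    ci_low: float
    ci_high: float
    method: str  # "delong" or "stratified_bootstrap"
    alpha: float = 0.05
    n_boot: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass(frozen=True)
class DeLongComparison:
    """Result of DeLong's test for two correlated ROC curves."""

    auc1: float
    auc2: float
    var1: float
    var2: float
    cov12: float
    z: float
    p: float


def _auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney via midranks: ties receive half credit automatically
    r = rankdata(scores)
    m = int(labels.sum())
    n = labels.size - m
    rank_sum_pos = float(r[labels == 1].sum())
    return (rank_sum_pos - m * (m + 1) / 2.0) / (m * n)


def auc_mann_whitney(s: ScoredOutcome) -> float:
    """AUC as the Mann-Whitney two-sample statistic.

    Over all (positive, negative) pairs: the fraction where the positive's
    score exceeds the negative's, with ties counted 1/2.  Equals the
    trapezoidal area under the empirical ROC curve.
    """
    return _auc_from_ranks(s.scores, np.asarray(s.labels))


def delong_components(s: ScoredOutcome) -> tuple[np.ndarray, np.ndarray]:
    """Placement values ``(V10, V01)`` for positives and negatives.

    ``V10[i]`` is the fraction of negatives scored below positive ``i``
    (ties 1/2); ``V01[j]`` the fraction of positives scored above negative
    ``j``.  Both vectors have mean equal to the Mann-Whitney AUC.  Computed
    with midranks in O(n log n).
    """
    pos = s.scores[s.labels == 1]
    neg = s.scores[s.labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    return v10, v01


def delong_variance(s: ScoredOutcome) -> float:
    """DeLong variance of a single AUC estimator."""
    v10, v01 = delong_components(s)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_ci(s: ScoredOutcome, alpha: float = 0.05) -> AucEstimate:
    """Asymptotic-normal AUC confidence interval from the DeLong variance."""
    auc = auc_mann_whitney(s)
    se = np.sqrt(delong_variance(s))
    z = float(-ndtri(alpha / 2.0))
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return AucEstimate(auc=auc, ci_low=lo, ci_high=hi, method="delong", alpha=alpha)


def delong_paired_test(s1: ScoredOutcome, s2: ScoredOutcome) -> DeLongComparison:
    """DeLong's test comparing two AUCs computed on the same subjects.

    Requires identical labels in identical subject order (the paired
    design).  Variances and the covariance of the two AUC estimators come
    from the sample (co)variances of the placement-value vectors; the test
    statistic ``z = (auc1 - auc2) / sqrt(var1 + var2 - 2 cov12)`` is
    referred to the standard normal, two-sided.  A degenerate zero variance
    of the difference (e.g. comparing a score vector to itself) gives
    ``z = 0, p = 1``.
    """
    if not np.array_equal(s1.labels, s2.labels):
        raise ValueError("paired DeLong test requires identical labels in order")
    v10_1, v01_1 = delong_components(s1)
    v10_2, v01_2 = delong_components(s2)
    m, n = v10_1.size, v01_1.size
    auc1 = float(v10_1.mean())
    auc2 = float(v10_2.mean())
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var1 = float(s10[0, 0] / m + s01[0, 0] / n)
    var2 = float(s10[1, 1] / m + s01[1, 1] / n)
    cov12 = float(s10[0, 1] / m + s01[0, 1] / n)
    var_diff = var1 + var2 - 2.0 * cov12
    if var_diff <= 1e-15:
        z, p = 0.0, 1.0
    else:
        z = (auc1 - auc2) / np.sqrt(var_diff)
        p = float(2.0 * ndtr(-abs(z)))
    return DeLongComparison(
        auc1=auc1, auc2=auc2, var1=var1, var2=var2, cov12=cov12, z=float(z), p=p
    )


def stratified_bootstrap_ci(
    s: ScoredOutcome,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AucEstimate:
    """Percentile bootstrap CI for the AUC, stratified by outcome class.

    Positives and negatives are resampled separately with replacement,
    preserving the class counts, so no replicate can lose a class.  The
    interval is the (alpha/2, 1-alpha/2) percentile of the replicate AUCs.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for a stable percentile CI")
    pos = s.scores[s.labels == 1]
    neg = s.scores[s.labels == 0]
    m, n = pos.size, neg.size
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(m, dtype=np.int8), np.zeros(n, dtype=np.int8)])
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, m, m)]
        bn = neg[rng.integers(0, n, n)]
        aucs[b] = _auc_from_ranks(np.concatenate([bp, bn]), labels)
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = auc_mann_whitney(s)
    # percentile endpoints can sit on the far side of the point estimate in
    # tiny samples; clamp so the interval always contains it
    return AucEstimate(
        auc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        method="stratified_bootstrap",
        alpha=alpha,
        n_boot=n_boot,
    )
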