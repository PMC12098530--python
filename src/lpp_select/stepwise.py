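"""Forward and backward stepwise logistic regression with AIC.

The greedy procedures add (forward) or remove (backward) the single
predictor that most lowers the Akaike Information Criterion, stopping when
no move lowers it.  Selection runs once on the full data; the retained set
is then evaluated by 10-fold cross-validation with the coefficients refit
inside each training fold (the selection itself is not re-run per fold, so
the reported cross-validated AUC carries the usual selection optimism).

Maximum-likelihood fits go through statsmodels' Logit (Newton/IRLS).  With
low-prevalence binary predictors quasi-complete separation is common; fits
whose coefficients exceed a declared bound on the log-odds scale, or that
fail to converge, are flagged rather than penalised — mirroring how
unstable rare-predictor estimates are reported in screening-tool practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, ndtri
from sklearn.model_selection import StratifiedKFold

from ._seeds import child_seed
from .roc_stats import AucEstimate, ScoredOutcome, stratified_bootstrap_ci
from .synthetic_data import BinaryDataset

__all__ = [
    "LogisticFit",
    "StepwiseResult",
    "fit_logistic",
    "wald_odds_ratios",
    "backward_stepwise",
    "forward_stepwise",
    "cv_logistic_auc",
]

#: |coefficient| above this (log-odds scale) flags quasi-complete separation.
SEPARATION_BOUND = 15.0
#: AIC differences below this are ties; ties prefer the smaller model.
AIC_TIE_TOL = 1e-8


@dataclass
class LogisticFit:
    """A fitted logistic regression: coefficients, likelihood, AIC, flags."""

    predictors: list[str]
    coefficients: np.ndarray  # log-odds, aligned with predictors
    standard_errors: np.ndarray
    intercept: float
    intercept_se: float
    log_likelihood: float
    aic: float
    converged: bool
    separation_flag: bool
    dropped: list[str] = field(default_factory=list)  # constant columns removed

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coefficients)


@dataclass
class StepwiseResult:
    """Outcome of one greedy AIC selection run."""

    direction: str  # "forward" or "backward"
    retained: list[str]
    trajectory: list[tuple[int, str, str | None, float]]  # (step, action, predictor, aic)
    final_fit: LogisticFit
    cv_auc: AucEstimate | None = None


def _design(data: BinaryDataset, predictors: list[str]) -> np.ndarray:
    X = data.columns(predictors).astype(float)
    return np.column_stack([np.ones(data.n), X])


def _fit_raw(y: np.ndarray, Xd: np.ndarray):
    model = sm.Logit(y, Xd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, method="newton", maxiter=50, warn_convergence=False)
        except np.linalg.LinAlgError:
            # singular Hessian (constant column, quasi-complete separation in
            # a tiny stratum): fall back to pseudoinverse IRLS so the step
            # still yields a (flagged, non-converged) fit with a finite AIC
            return _pinv_irls(y, Xd)


class _PinvFit:
    """Minimal stand-in for a statsmodels results object from the fallback."""

    def __init__(self, params, bse, llf, aic):
        self.params = params
        self.bse = bse
        self.llf = llf
        self.aic = aic
        self.mle_retvals = {"converged": False}


def _pinv_irls(y: np.ndarray, Xd: np.ndarray, maxiter: int = 50) -> _PinvFit:
    beta = np.zeros(Xd.shape[1])
    H = np.eye(Xd.shape[1])
    for _ in range(maxiter):
        p = expit(Xd @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Xd * w[:, None]).T @ Xd
        step = np.linalg.pinv(H) @ (Xd.T @ (y - p))
        beta = np.clip(beta + step, -2 * SEPARATION_BOUND, 2 * SEPARATION_BOUND)
        if np.max(np.abs(step)) < 1e-8:
            break
    p = np.clip(expit(Xd @ beta), 1e-12, 1.0 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    bse = np.sqrt(np.clip(np.diag(np.linalg.pinv(H)), 0.0, None))
    return _PinvFit(params=beta, bse=bse, llf=llf, aic=2.0 * Xd.shape[1] - 2.0 * llf)


def fit_logistic(data: BinaryDataset, predictors) -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on a predictor subset.

    Constant columns are dropped with a warning and recorded on the result.
    A singular (collinear) design raises ``ValueError`` naming the dependent
    columns.  Separation is flagged per :data:`SEPARATION_BOUND`.
    """
    predictors = list(predictors)
    unknown = [p for p in predictors if p not in data.names]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")
    if data.degenerate:
        raise ValueError("outcome vector is degenerate (single class)")
    if data.n <= len(predictors) + 1:
        raise ValueError("need n > number of parameters")

    dropped = []
    kept = []
    for name in predictors:
        col = data.columns([name])[:, 0]
        if col.min() == col.max():
            dropped.append(name)
        else:
            kept.append(name)
    if dropped:
        warnings.warn(
            f"dropping constant predictor columns: {dropped}", UserWarning, stacklevel=2
        )

    Xd = _design(data, kept)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # name the columns involved in the linear dependency via QR pivoting
        _, R = np.linalg.qr(Xd)
        diag = np.abs(np.diag(R))
        bad = [kept[i - 1] for i in range(1, Xd.shape[1]) if diag[i] < 1e-8]
        raise ValueError(f"singular design; collinear predictors: {bad or kept}")

    y = np.asarray(data.y, dtype=float)
    res = _fit_raw(y, Xd)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    separation = (not converged) or bool(np.abs(params).max(initial=0.0) > SEPARATION_BOUND)
    return LogisticFit(
        predictors=kept,
        coefficients=params[1:],
        standard_errors=bse[1:],
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        converged=converged,
        separation_flag=separation,
        dropped=dropped,
    )


def wald_odds_ratios(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-predictor odds ratios with Wald confidence intervals.

    ``OR = exp(coef)``, ``CI = exp(coef +/- z * SE)``.  When the fit is
    separation-flagged the intervals are emitted but marked unreliable.
    """
    z = float(-ndtri(alpha / 2.0))
    coef = fit.coefficients
    se = fit.standard_errors
    return pd.DataFrame(
        {
            "predictor": fit.predictors,
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "unreliable": fit.separation_flag,
        }
    )


def _aic_of(data: BinaryDataset, predictors: list[str], cache: dict) -> float:
    key = frozenset(predictors)
    if key not in cache:
        y = np.asarray(data.y, dtype=float)
        cache[key] = float(_fit_raw(y, _design(data, predictors)).aic)
    return cache[key]


def backward_stepwise(data: BinaryDataset, predictors=None) -> StepwiseResult:
    """Greedy backward elimination on AIC.

    Starts from the full model; each step removes the single predictor whose
    removal lowers AIC most, until no removal lowers it.  AIC ties (within
    :data:`AIC_TIE_TOL`) prefer the smaller model; ties between candidate
    predictors break lexicographically by name, so reruns are deterministic.
    """
    current = list(predictors) if predictors is not None else list(data.names)
    cache: dict = {}
    aic = _aic_of(data, current, cache)
    trajectory = [(0, "start", None, aic)]
    step = 0
    while len(current) > 0:
        candidates = []
        for name in current:
            reduced = [p for p in current if p != name]
            candidates.append((_aic_of(data, reduced, cache), name))
        best_aic = min(a for a, _ in candidates)
        # removal wins ties against the larger current model
        if best_aic >= aic + AIC_TIE_TOL:
            break
        best_name = min(n for a, n in candidates if a <= best_aic + AIC_TIE_TOL)
        current = [p for p in current if p != best_name]
        aic = _aic_of(data, current, cache)
        step += 1
        trajectory.append((step, "remove", best_name, aic))
    return StepwiseResult(
        direction="backward",
        retained=current,
        trajectory=trajectory,
        final_fit=fit_logistic(data, current),
    )


def forward_stepwise(data: BinaryDataset, predictors=None) -> StepwiseResult:
    """Greedy forward addition on AIC, from the intercept-only model.

    Adds the single predictor that lowers AIC most per step; stops when no
    addition lowers AIC.  Tie handling mirrors :func:`backward_stepwise`
    (ties prefer not adding; candidate ties break lexicographically).
    """
    pool = list(predictors) if predictors is not None else list(data.names)
    current: list[str] = []
    cache: dict = {}
    aic = _aic_of(data, current, cache)
    trajectory = [(0, "start", None, aic)]
    step = 0
    while len(current) < len(pool):
        remaining = [p for p in pool if p not in current]
        candidates = [
            (_aic_of(data, current + [name], cache), name) for name in remaining
        ]
        best_aic = min(a for a, _ in candidates)
        # addition must strictly beat the smaller current model
        if best_aic >= aic - AIC_TIE_TOL:
            break
        best_name = min(n for a, n in candidates if a <= best_aic + AIC_TIE_TOL)
        current = current + [best_name]
        aic = _aic_of(data, current, cache)
        step += 1
        trajectory.append((step, "add", best_name, aic))
    return StepwiseResult(
        direction="forward",
        retained=current,
        trajectory=trajectory,
        final_fit=fit_logistic(data, current),
    )


def cv_logistic_auc(
    data: BinaryDataset,
    predictors,
    k_folds: int = 10,
    seed: int = 0,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> tuple[AucEstimate, ScoredOutcome]:
    """Cross-validated AUC for a FIXED predictor set.

    Stratified K-fold assignment deterministic in ``seed``; the logistic
    model is refit within each training fold and each subject scored by the
    model that never saw it.  Pooled out-of-fold probabilities are scored by
    the Mann-Whitney AUC with a stratified-bootstrap percentile CI.  Folds
    whose fit separates are flagged via the usual warning machinery but
    still produce (finite) predicted probabilities.
    """
    predictors = list(predictors)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(data.y)
    Xd = _design(data, predictors)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=child_seed(seed))
    oof = np.full(data.n, np.nan)
    for train, test in skf.split(Xd, y):
        res = _fit_raw(y[train].astype(float), Xd[train])
        oof[test] = expit(Xd[test] @ np.asarray(res.params))
    scored = ScoredOutcome(scores=oof, labels=y)
    est = stratified_bootstrap_ci(
        scored, n_boot=n_boot, alpha=alpha, seed=child_seed(seed, 1)
    )
    return est, scored
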