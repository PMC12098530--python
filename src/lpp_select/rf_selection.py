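"""Random-forest variable selection for low-prevalence binary predictors.

The procedure:

1. Fit ``n_repeats`` independent forests (default 25, each of 10,000 trees)
   and average the out-of-bag permutation importance of every predictor
   across repeats, then rank predictors by the averaged importance.
2. Drop predictors whose averaged importance is not positive.
3. Build a series of nested forests on the top-k ranked predictors
   (k = k_min .. all positive), score each by pooled out-of-fold class-vote
   probabilities from stratified K-fold cross-validation, and compare each
   nested model's AUC to the full model (ALL candidate predictors, same
   folds) with the paired DeLong test.
4. The parsimonious model is the smallest k whose AUC does not differ
   significantly from the full model's.

Importance is the UNSCALED mean decrease in out-of-bag accuracy: for each
tree, the drop in accuracy on that tree's out-of-bag subjects when one
predictor's values are permuted among them, averaged over trees.  The
scaled variant (divided by its standard error) is deliberately not used, as
it distorts comparisons between predictors.  scikit-learn's forests do not
expose per-tree out-of-bag permutation importance, so the operator is
implemented here directly over each tree's bootstrap indices.

The out-of-fold score of a subject is the fraction of trees voting class 1
(majority-vote probability), with no calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils import check_random_state

from ._seeds import child_seed
from .roc_stats import (
    AucEstimate,
    ScoredOutcome,
    delong_paired_test,
    stratified_bootstrap_ci,
)
from .synthetic_data import BinaryDataset

__all__ = [
    "RfParams",
    "CvPredictions",
    "NestedModelResult",
    "RfSelectionResult",
    "average_importance",
    "filter_negative",
    "cv_forest_predictions",
    "sequential_selection",
    "mtry_sweep",
]

#: mtry values swept in the screening-tool analysis: small, default (~sqrt(32)), large.
DEFAULT_MTRY_SWEEP = (3, 6, 16)


@dataclass(frozen=True)
class RfParams:
    """Forest hyperparameters for one selection run.

    ``mtry`` is the number of candidate predictors considered at each
    split.  Full-scale defaults are 10,000 trees and 25 repeats; tests use
    scaled-down configurations.
    """

    mtry: int
    n_trees: int = 10_000
    n_repeats: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry < 1 or self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("mtry, n_trees and n_repeats must be positive")

    def validate_for(self, p: int) -> None:
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds predictor count {p}")


@dataclass
class CvPredictions:
    """Pooled out-of-fold scores with the fold assignment that produced them."""

    fold_assignment: np.ndarray  # length n, values 0..K-1
    oof_scores: np.ndarray
    labels: np.ndarray

    def scored(self) -> ScoredOutcome:
        return ScoredOutcome(scores=self.oof_scores, labels=self.labels)


@dataclass
class NestedModelResult:
    """One nested ranked-predictor model: size, AUC, DeLong p vs full model."""

    k: int
    auc: AucEstimate
    delong_p_vs_full: float


@dataclass
class RfSelectionResult:
    """Outcome of the sequential selection for one mtry."""

    mtry: int
    ranked_predictors: list[str]  # positive-importance predictors, rank order
    chosen_k: int | None
    retained: list[str]
    full_model_auc: AucEstimate

    def __post_init__(self) -> None:
        if self.chosen_k is not None:
            expected = self.ranked_predictors[: self.chosen_k]
            if self.retained != expected:
                raise ValueError("retained must be the first chosen_k ranked predictors")


# ---------------------------------------------------------------------------
# out-of-bag permutation importance


def _tree_oob_indices(tree, n: int, n_samples_bootstrap: int) -> np.ndarray:
    """Out-of-bag sample indices for one fitted tree.

    Reconstructs the bootstrap draw from the tree's ``random_state`` the
    same way scikit-learn draws it at fit time.
    """
    rs = check_random_state(tree.random_state)
    sampled = rs.randint(0, n, n_samples_bootstrap)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return np.nonzero(mask)[0]


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Unscaled mean decrease in out-of-bag accuracy, one value per predictor.

    For each tree: accuracy on its out-of-bag subjects, minus the accuracy
    after permuting one predictor's values among those subjects; averaged
    over all trees with at least two out-of-bag subjects.
    """
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y)
    n, p = X32.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    n_used = 0
    for tree in forest.estimators_:
        oob = _tree_oob_indices(tree, n, n)
        if oob.size < 2:
            continue
        Xo = X32[oob].copy()
        yo = y[oob]
        base_acc = float(np.mean(tree.predict(Xo, check_input=False) == yo))
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[rng.permutation(oob.size)]
            perm_acc = float(np.mean(tree.predict(Xo, check_input=False) == yo))
            Xo[:, j] = saved
            drops[j] += base_acc - perm_acc
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return drops / n_used


def _fit_forest(
    X: np.ndarray, y: np.ndarray, mtry: int, n_trees: int, seed: int
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        n_jobs=1,
        random_state=seed,
    )
    rf.fit(np.ascontiguousarray(X, dtype=np.float32), y)
    return rf


def average_importance(data: BinaryDataset, params: RfParams) -> pd.DataFrame:
    """Importance table averaged over ``n_repeats`` independent forests.

    Returns a DataFrame indexed by predictor name with columns
    ``mean_importance``, ``sd_importance`` (across repeats) and ``rank``
    (1 = highest mean; ties break lexicographically by name).
    """
    params.validate_for(data.p)
    if data.degenerate:
        raise ValueError("outcome vector is degenerate (single class)")
    y = np.asarray(data.y)
    per_repeat = np.empty((params.n_repeats, data.p))
    for r in range(params.n_repeats):
        rf = _fit_forest(
            data.X, y, params.mtry, params.n_trees, child_seed(params.seed, r, 0)
        )
        per_repeat[r] = oob_permutation_importance(
            rf, data.X, y, seed=child_seed(params.seed, r, 1)
        )
    mean = per_repeat.mean(axis=0)
    sd = per_repeat.std(axis=0, ddof=1) if params.n_repeats > 1 else np.zeros(data.p)
    table = pd.DataFrame(
        {"mean_importance": mean, "sd_importance": sd},
        index=pd.Index(data.names, name="predictor"),
    )
    # lexicographic tie-break: sort by name first, then stable-sort by importance
    order = table.sort_index().sort_values(
        by="mean_importance", ascending=False, kind="mergesort"
    )
    table["rank"] = pd.Series(
        np.arange(1, data.p + 1), index=order.index
    ).reindex(table.index)
    return table


def rank_importances(importances: np.ndarray, names: list[str]) -> np.ndarray:
    """Ranks 1..p by descending importance, name-lexicographic tie-break."""
    order = sorted(range(len(names)), key=lambda i: (-importances[i], names[i]))
    ranks = np.empty(len(names), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def filter_negative(table: pd.DataFrame) -> list[str]:
    """Predictors with strictly positive mean importance, in rank order.

    Zero importance is treated as non-positive and removed.  An empty
    result is flagged with a warning (no selectable predictors).
    """
    kept = table[table["mean_importance"] > 0].sort_values("rank")
    names = list(kept.index)
    if not names:
        warnings.warn(
            "all predictors have non-positive importance; nothing selectable",
            UserWarning,
            stacklevel=2,
        )
    return names


# ---------------------------------------------------------------------------
# cross-validated forest predictions


def stratified_folds(
    y: np.ndarray, k_folds: int, cv_seed: int, max_tries: int = 10
) -> np.ndarray:
    """Outcome-stratified fold assignment, deterministic in ``cv_seed``.

    Regenerates with the next derived seed in the (rare) event a fold ends
    up single-class.  The same assignment must be reused across all nested
    models in one selection run so the paired DeLong test is valid.
    """
    y = np.asarray(y)
    for attempt in range(max_tries):
        skf = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=child_seed(cv_seed, attempt)
        )
        assignment = np.empty(y.size, dtype=int)
        ok = True
        for fold, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
            assignment[test] = fold
            train_y = np.delete(y, test)
            if train_y.min() == train_y.max():
                ok = False
                break
        if ok:
            return assignment
    raise RuntimeError("could not build stratified folds without a single-class fold")


def _vote_scores(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting class 1 (hard majority votes per tree)."""
    Xc = np.ascontiguousarray(X, dtype=np.float32)
    votes = np.zeros(Xc.shape[0])
    for tree in rf.estimators_:
        votes += tree.predict(Xc, check_input=False)
    return votes / len(rf.estimators_)


def cv_forest_predictions(
    data: BinaryDataset,
    predictors,
    params: RfParams,
    k_folds: int = 10,
    cv_seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CvPredictions:
    """Pooled out-of-fold class-vote scores from a stratified K-fold split.

    Every subject is scored exactly once, by the forest trained without its
    fold.  Pass ``fold_assignment`` to share one split across several
    models (required for paired AUC comparison).
    """
    predictors = list(predictors)
    y = np.asarray(data.y)
    if fold_assignment is None:
        fold_assignment = stratified_folds(y, k_folds, cv_seed)
    X = data.columns(predictors)
    oof = np.full(data.n, np.nan)
    for fold in np.unique(fold_assignment):
        test = fold_assignment == fold
        train = ~test
        rf = _fit_forest(
            X[train],
            y[train],
            min(params.mtry, len(predictors)),
            params.n_trees,
            child_seed(params.seed, 7, int(fold)),
        )
        oof[test] = _vote_scores(rf, X[test])
    return CvPredictions(
        fold_assignment=np.asarray(fold_assignment), oof_scores=oof, labels=y
    )


def sequential_selection(
    data: BinaryDataset,
    ranked,
    params: RfParams,
    k_folds: int = 10,
    alpha: float = 0.05,
    k_min: int = 3,
    n_boot: int = 2000,
    cv_seed: int | None = None,
) -> tuple[list[NestedModelResult], RfSelectionResult]:
    """Sequential ranked-predictor selection against the full model.

    For each k from ``k_min`` to the number of (positive-importance) ranked
    predictors, scores the top-k model by pooled out-of-fold AUC with a
    stratified-bootstrap CI, and compares it to the full model — ALL of the
    dataset's predictors, cross-validated on the same folds — with the
    paired DeLong test.  The chosen model is the smallest k whose p-value
    is at least ``alpha``; ``chosen_k`` is None when no nested model
    matches the full model (the large-mtry outcome).
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked predictor list is empty")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if cv_seed is None:
        cv_seed = child_seed(params.seed, 11)
    y = np.asarray(data.y)
    folds = stratified_folds(y, k_folds, cv_seed)
    full_preds = cv_forest_predictions(
        data, data.names, params, k_folds, fold_assignment=folds
    )
    full_scored = full_preds.scored()
    full_auc = stratified_bootstrap_ci(
        full_scored, n_boot=n_boot, alpha=alpha, seed=child_seed(params.seed, 13)
    )
    results: list[NestedModelResult] = []
    chosen_k: int | None = None
    for k in range(min(k_min, len(ranked)), len(ranked) + 1):
        preds_k = cv_forest_predictions(
            data, ranked[:k], params, k_folds, fold_assignment=folds
        )
        scored_k = preds_k.scored()
        est = stratified_bootstrap_ci(
            scored_k, n_boot=n_boot, alpha=alpha, seed=child_seed(params.seed, 17, k)
        )
        cmp = delong_paired_test(scored_k, full_scored)
        results.append(NestedModelResult(k=k, auc=est, delong_p_vs_full=cmp.p))
        # alpha >= 1 is the degenerate threshold: every model qualifies
        if chosen_k is None and (alpha >= 1.0 or cmp.p >= alpha):
            chosen_k = k
    selection = RfSelectionResult(
        mtry=params.mtry,
        ranked_predictors=ranked,
        chosen_k=chosen_k,
        retained=ranked[:chosen_k] if chosen_k is not None else [],
        full_model_auc=full_auc,
    )
    return results, selection


def mtry_sweep(
    data: BinaryDataset,
    mtry_values=DEFAULT_MTRY_SWEEP,
    n_trees: int = 10_000,
    n_repeats: int = 25,
    k_folds: int = 10,
    alpha: float = 0.05,
    k_min: int = 3,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[int, dict]:
    """Run the whole selection procedure once per mtry value.

    Each mtry gets independent derived seeds.  Returns a mapping
    ``mtry -> {"importance": table, "nested": [...], "selection": result}``.
    """
    out: dict[int, dict] = {}
    for i, mtry in enumerate(mtry_values):
        params = RfParams(
            mtry=mtry, n_trees=n_trees, n_repeats=n_repeats, seed=child_seed(seed, i)
        )
        table = average_importance(data, params)
        ranked = filter_negative(table)
        nested, selection = sequential_selection(
            data,
            ranked,
            params,
            k_folds=k_folds,
            alpha=alpha,
            k_min=k_min,
            n_boot=n_boot,
        )
        out[mtry] = {"importance": table, "nested": nested, "selection": selection}
    return out
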