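"""Prevalence-threshold simulation study.

Four arms — the original predictor prevalences and minimum-prevalence
floors of 10%, 20% and 30% — each with ``n_datasets`` synthetic cohorts.
Per cohort, the random-forest arm fits ONE forest (not the 25-repeat
average used for the real-data selection), records every predictor's
permutation-importance rank (1 = highest .. p = lowest) and the pooled
out-of-fold cross-validated AUC; the stepwise arm runs greedy AIC
selection (backward by default), records which predictors were retained
and the cross-validated AUC of the retained model.

Betas are held fixed across arms so only predictor prevalence varies.  By
default the intercept is recalibrated per arm to hold the marginal outcome
prevalence at its target; without this, raising the prevalence of
positive-effect predictors would inflate the outcome rate and confound the
AUC trend (a fixed-intercept mode is available by flag).

Both arms consume identical cohorts (same per-dataset derived seeds), so
differences between arms are method differences, and the whole study
replays deterministically from one master seed.  Optional per-dataset JSON
checkpoints make long runs resumable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .rf_selection import (
    RfParams,
    _fit_forest,
    cv_forest_predictions,
    oob_permutation_importance,
    rank_importances,
)
from .roc_stats import auc_mann_whitney
from .stepwise import backward_stepwise, cv_logistic_auc, forward_stepwise
from .synthetic_data import (
    DegenerateOutcomeWarning,
    GeneratorConfig,
    PredictorSpec,
    apply_prevalence_floor,
    calibrate_intercept,
    default_predictor_specs,
    generate_dataset,
)

__all__ = [
    "ORIGINAL",
    "SimulationConfig",
    "run_rf_simulation",
    "run_swr_simulation",
    "summarize_rank_shift",
]

#: Sentinel floor for the "original prevalence" arm (floor of 0 = identity).
ORIGINAL = 0.0

DEFAULT_THRESHOLDS = (ORIGINAL, 0.10, 0.20, 0.30)


def _threshold_label(floor: float) -> str:
    return "original" if floor == ORIGINAL else f"{floor:.0%}"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one simulation run depends on."""

    specs: tuple[PredictorSpec, ...] = field(
        default_factory=lambda: tuple(default_predictor_specs())
    )
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_datasets: int = 1000
    n_subjects: int = 3473
    target_outcome_prevalence: float = 0.151
    mtry: int = 3
    n_trees: int = 500
    k_folds: int = 10
    swr_direction: str = "backward"
    master_seed: int = 0
    scale: str = "full"  # "full" or "desk"
    recalibrate_intercept: bool = True
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("full", "desk"):
            raise ValueError("scale must be 'full' or 'desk'")
        if self.scale == "desk" and (self.n_datasets > 50 or self.n_trees > 500):
            raise ValueError("desk scale caps n_datasets at 50 and n_trees at 500")
        if self.swr_direction not in ("forward", "backward"):
            raise ValueError("swr_direction must be 'forward' or 'backward'")
        for t in self.thresholds:
            if not (0.0 <= t < 1.0):
                raise ValueError(f"threshold {t} outside [0, 1)")

    @classmethod
    def desk(cls, master_seed: int = 0, **overrides) -> "SimulationConfig":
        """Scaled-down configuration for a single workstation.

        20 datasets per threshold, 300-tree forests, cohorts of n = 1200
        with 5-fold cross-validation.  The arms, effect sizes and outcome
        prevalence are identical to the full-scale design; only the
        replication counts shrink.
        """
        kwargs = dict(
            n_datasets=20,
            n_subjects=1200,
            n_trees=300,
            k_folds=5,
            master_seed=master_seed,
            scale="desk",
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def full(cls, master_seed: int = 0, **overrides) -> "SimulationConfig":
        """The full 4 x 1000 design at n = 3473 with 10-fold CV."""
        kwargs = dict(master_seed=master_seed, scale="full")
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def p(self) -> int:
        return len(self.specs)


@lru_cache(maxsize=64)
def _cached_intercept(
    specs: tuple[PredictorSpec, ...], target: float, seed: int
) -> float:
    return calibrate_intercept(list(specs), target, seed=seed)


def _arm_generator_config(
    config: SimulationConfig, floor: float, dataset_seed: int
) -> GeneratorConfig:
    specs = apply_prevalence_floor(list(config.specs), floor)
    calib_specs = tuple(specs) if config.recalibrate_intercept else config.specs
    b0 = _cached_intercept(
        calib_specs,
        config.target_outcome_prevalence,
        child_seed(config.master_seed, 0xCA11),
    )
    return GeneratorConfig(
        specs=tuple(specs),
        intercept=b0,
        n=config.n_subjects,
        seed=dataset_seed,
        target_outcome_prevalence=config.target_outcome_prevalence,
    )


def _generate_cohort(config: SimulationConfig, ti: int, d: int):
    """Cohort for (threshold index, dataset index); redraws degenerate outcomes."""
    for retry in range(20):
        seed = child_seed(config.master_seed, ti, d, retry)
        gc = _arm_generator_config(config, config.thresholds[ti], seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateOutcomeWarning)
            ds = generate_dataset(gc)
        if not ds.degenerate:
            return ds, retry
    raise RuntimeError("could not generate a non-degenerate cohort in 20 tries")


def _checkpoint_path(config: SimulationConfig, arm: str, ti: int, d: int) -> Path | None:
    if config.checkpoint_dir is None:
        return None
    root = Path(config.checkpoint_dir) / arm
    root.mkdir(parents=True, exist_ok=True)
    return root / f"t{ti}_d{d}.json"


def _load_or_compute(path: Path | None, compute):
    if path is not None and path.exists():
        return json.loads(path.read_text())
    result = compute()
    if path is not None:
        path.write_text(json.dumps(result))
    return result


def run_rf_simulation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-forest arm: importance-rank distributions and AUC summary.

    Returns ``(rank_distribution, auc_summary)``: the first is long-format
    with columns (predictor, threshold, rank, count) where counts per
    predictor-threshold cell sum to ``n_datasets``; the second has one row
    per threshold with the mean and SD of the per-dataset pooled
    out-of-fold CV AUC.
    """
    names = [s.name for s in config.specs]
    p = config.p
    rank_counts = {ti: np.zeros((p, p), dtype=int) for ti in range(len(config.thresholds))}
    aucs: dict[int, list[float]] = {ti: [] for ti in range(len(config.thresholds))}
    regenerated = 0
    for ti in range(len(config.thresholds)):
        for d in range(config.n_datasets):
            ckpt = _checkpoint_path(config, "rf", ti, d)

            def compute(ti=ti, d=d):
                ds, retries = _generate_cohort(config, ti, d)
                y = np.asarray(ds.y)
                fit_seed = child_seed(config.master_seed, 1, ti, d)
                rf = _fit_forest(ds.X, y, config.mtry, config.n_trees, fit_seed)
                imp = oob_permutation_importance(
                    rf, ds.X, y, seed=child_seed(config.master_seed, 2, ti, d)
                )
                ranks = rank_importances(imp, names)
                params = RfParams(
                    mtry=config.mtry,
                    n_trees=config.n_trees,
                    n_repeats=1,
                    seed=child_seed(config.master_seed, 3, ti, d),
                )
                preds = cv_forest_predictions(
                    ds,
                    names,
                    params,
                    k_folds=config.k_folds,
                    cv_seed=child_seed(config.master_seed, 4, ti, d),
                )
                auc = auc_mann_whitney(preds.scored())
                return {"ranks": ranks.tolist(), "auc": auc, "retries": retries}

            rec = _load_or_compute(ckpt, compute)
            regenerated += rec["retries"]
            for j, r in enumerate(rec["ranks"]):
                rank_counts[ti][j, r - 1] += 1
            aucs[ti].append(rec["auc"])
    if regenerated:
        warnings.warn(
            f"{regenerated} degenerate cohorts were regenerated", UserWarning, stacklevel=2
        )
    rank_rows = []
    for ti, floor in enumerate(config.thresholds):
        label = _threshold_label(floor)
        for j, name in enumerate(names):
            for r in range(p):
                rank_rows.append((name, label, r + 1, int(rank_counts[ti][j, r])))
    rank_df = pd.DataFrame(rank_rows, columns=["predictor", "threshold", "rank", "count"])
    auc_df = _auc_summary(config, aucs)
    return rank_df, auc_df


def run_swr_simulation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stepwise arm: retention counts and AUC summary.

    Consumes the same per-dataset cohorts as :func:`run_rf_simulation`
    (identical derived seeds).  Returns ``(retention_counts, auc_summary)``
    with retention in long format (predictor, threshold, retained_count)
    and the AUC of each dataset's RETAINED model summarised per threshold.
    """
    names = [s.name for s in config.specs]
    step = backward_stepwise if config.swr_direction == "backward" else forward_stepwise
    retained_counts = {
        ti: np.zeros(config.p, dtype=int) for ti in range(len(config.thresholds))
    }
    aucs: dict[int, list[float]] = {ti: [] for ti in range(len(config.thresholds))}
    for ti in range(len(config.thresholds)):
        for d in range(config.n_datasets):
            ckpt = _checkpoint_path(config, "swr", ti, d)

            def compute(ti=ti, d=d):
                ds, _ = _generate_cohort(config, ti, d)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = step(ds)
                    est, _scored = cv_logistic_auc(
                        ds,
                        result.retained,
                        k_folds=config.k_folds,
                        seed=child_seed(config.master_seed, 5, ti, d),
                        n_boot=200,
                    )
                return {"retained": result.retained, "auc": est.auc}

            rec = _load_or_compute(ckpt, compute)
            for name in rec["retained"]:
                retained_counts[ti][names.index(name)] += 1
            aucs[ti].append(rec["auc"])
    rows = []
    for ti, floor in enumerate(config.thresholds):
        label = _threshold_label(floor)
        for j, name in enumerate(names):
            rows.append((name, label, int(retained_counts[ti][j])))
    ret_df = pd.DataFrame(rows, columns=["predictor", "threshold", "retained_count"])
    auc_df = _auc_summary(config, aucs)
    return ret_df, auc_df


def _auc_summary(config: SimulationConfig, aucs: dict[int, list[float]]) -> pd.DataFrame:
    rows = []
    for ti, floor in enumerate(config.thresholds):
        arr = np.asarray(aucs[ti])
        rows.append(
            (
                _threshold_label(floor),
                float(arr.mean()),
                float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                arr.size,
            )
        )
    return pd.DataFrame(rows, columns=["threshold", "mean_auc", "sd_auc", "n_datasets"])


def _rank_quantile(counts: np.ndarray, q: float) -> float:
    """Quantile of an empirical rank distribution given per-rank counts."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty rank distribution")
    values = np.repeat(np.arange(1, counts.size + 1), counts)
    return float(np.quantile(values, q))


def summarize_rank_shift(
    rank_distribution: pd.DataFrame, threshold_a: str, threshold_b: str
) -> pd.DataFrame:
    """Per-predictor change in rank location/spread between two thresholds.

    ``median_shift = median_b - median_a`` (negative = moved toward rank 1,
    i.e. greater importance) and ``iqr_change = IQR_b - IQR_a`` (negative =
    less variability), both from the empirical rank counts.
    """
    out = []
    for thr in (threshold_a, threshold_b):
        if thr not in set(rank_distribution["threshold"]):
            raise ValueError(f"threshold {thr!r} not present in rank distribution")
    for name, grp in rank_distribution.groupby("predictor", sort=False):
        stats = {}
        for thr in (threshold_a, threshold_b):
            sub = grp[grp["threshold"] == thr].sort_values("rank")
            counts = sub["count"].to_numpy()
            stats[thr] = (
                _rank_quantile(counts, 0.5),
                _rank_quantile(counts, 0.75) - _rank_quantile(counts, 0.25),
            )
        out.append(
            (
                name,
                stats[threshold_b][0] - stats[threshold_a][0],
                stats[threshold_b][1] - stats[threshold_a][1],
            )
        )
    return pd.DataFrame(out, columns=["predictor", "median_shift", "iqr_change"])
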