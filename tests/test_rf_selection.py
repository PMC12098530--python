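"""Forest importance averaging, negative filtering, CV predictions, selection."""

import numpy as np
import pytest
import pandas as pd

from lpp_select.rf_selection import (
    RfParams,
    _fit_forest,
    average_importance,
    cv_forest_predictions,
    filter_negative,
    oob_permutation_importance,
    rank_importances,
    sequential_selection,
    stratified_folds,
    mtry_sweep,
)
from lpp_select.roc_stats import auc_mann_whitney
from lpp_select.synthetic_data import BinaryDataset

from conftest import make_cohort


class TestOobImportance:
    def test_oob_indices_match_forest_oob_machinery(self):
        """Reconstructed per-tree OOB indices agree with the forest library's
        own out-of-bag bookkeeping (checked via OOB score reproduction)."""
        from sklearn.ensemble._forest import _generate_unsampled_indices

        from lpp_select.rf_selection import _tree_oob_indices

        ds = make_cohort([1.0, 0.0], [0.3, 0.3], n=300, seed=0)
        rf = _fit_forest(ds.X, ds.y, 1, 25, seed=3)
        for tree in rf.estimators_:
            ref = np.sort(_generate_unsampled_indices(tree.random_state, 300, 300, None))
            assert np.array_equal(_tree_oob_indices(tree, 300, 300), ref)

    def test_exact_mirror_predictor_dominates(self):
        rng = np.random.default_rng(1)
        y = (rng.random(600) < 0.4).astype(np.int8)
        x2 = (rng.random(600) < 0.5).astype(np.int8)
        ds = BinaryDataset(X=np.column_stack([y, x2]), y=y, names=["mirror", "noise"])
        table = average_importance(ds, RfParams(mtry=1, n_trees=100, n_repeats=3, seed=0))
        assert table.loc["mirror", "rank"] == 1
        assert table.loc["mirror", "mean_importance"] > table.loc["noise", "mean_importance"]

    def test_pure_noise_importance_near_zero(self):
        ds = make_cohort([1.5, 0.0], [0.3, 0.3], n=1500, seed=2, names=["signal", "pure_noise"])
        table = average_importance(ds, RfParams(mtry=1, n_trees=200, n_repeats=5, seed=1))
        mean = table.loc["pure_noise", "mean_importance"]
        sd = table.loc["pure_noise", "sd_importance"]
        assert abs(mean) <= 3 * sd

    def test_identical_seed_identical_table(self):
        ds = make_cohort([1.0, 0.3, 0.0], [0.3, 0.2, 0.3], n=500, seed=3)
        params = RfParams(mtry=2, n_trees=60, n_repeats=2, seed=9)
        a = average_importance(ds, params)
        b = average_importance(ds, params)
        pd.testing.assert_frame_equal(a, b)

    def test_repeat_averaging_stabilises_importance(self):
        """The spread of repeat-averaged importances shrinks roughly like
        1/sqrt(n_repeats) (checked at 5 vs 25 single-forest importances)."""
        ds = make_cohort([1.2, 0.6, 0.0], [0.3, 0.2, 0.3], n=800, seed=4)
        singles = []
        for r in range(25):
            params = RfParams(mtry=2, n_trees=80, n_repeats=1, seed=100 + r)
            singles.append(average_importance(ds, params)["mean_importance"].to_numpy())
        singles = np.asarray(singles)
        per_forest_sd = singles.std(axis=0, ddof=1)
        sem5 = per_forest_sd / np.sqrt(5)
        sem25 = per_forest_sd / np.sqrt(25)
        mean5 = singles[:5].mean(axis=0)
        mean25 = singles.mean(axis=0)
        # the 25-repeat mean sits within ~3 SEM-5 of the 5-repeat mean, and
        # its own standard error is smaller by construction
        assert np.all(np.abs(mean5 - mean25) < 4 * sem5 + 1e-12)
        assert np.all(sem25 < sem5)

    def test_importance_tracks_generating_effect(self):
        from scipy.stats import spearmanr

        betas = [1.8, 1.2, 0.8, 0.4, 0.0, 0.0]
        ds = make_cohort(betas, [0.3] * 6, n=3000, seed=5)
        table = average_importance(ds, RfParams(mtry=2, n_trees=150, n_repeats=3, seed=2))
        rho, _ = spearmanr(betas, -table["rank"].to_numpy())
        assert rho > 0


class TestFilterNegative:
    def _table(self, means):
        names = list(means)
        vals = np.array([means[n] for n in names])
        return pd.DataFrame(
            {
                "mean_importance": vals,
                "sd_importance": 0.0,
                "rank": rank_importances(vals, names),
            },
            index=pd.Index(names, name="predictor"),
        )

    def test_drops_negative_keeps_rank_order(self):
        assert filter_negative(self._table({"A": 0.02, "B": -0.001, "C": 0.01})) == ["A", "C"]

    def test_all_negative_flags_empty(self):
        with pytest.warns(UserWarning, match="non-positive"):
            assert filter_negative(self._table({"A": -0.1, "B": -0.2})) == []

    def test_zero_importance_removed(self):
        assert filter_negative(self._table({"A": 0.05, "B": 0.0})) == ["A"]

    def test_no_negatives_identity(self):
        assert filter_negative(self._table({"A": 0.3, "B": 0.1, "C": 0.2})) == ["A", "C", "B"]


class TestCvForestPredictions:
    def test_every_subject_scored_once(self):
        ds = make_cohort([1.0, 0.0], [0.3, 0.3], n=400, seed=6)
        preds = cv_forest_predictions(
            ds, ds.names, RfParams(mtry=1, n_trees=50, n_repeats=1, seed=0), k_folds=4
        )
        assert np.isfinite(preds.oof_scores).all()
        assert np.bincount(preds.fold_assignment, minlength=4).min() > 0

    def test_informative_predictor_gives_high_auc(self):
        rng = np.random.default_rng(7)
        y = (rng.random(2000) < 0.3).astype(np.int8)
        noisy = np.where(rng.random(2000) < 0.95, y, 1 - y).astype(np.int8)
        ds = BinaryDataset(X=noisy.reshape(-1, 1), y=y, names=["probe"])
        preds = cv_forest_predictions(
            ds, ["probe"], RfParams(mtry=1, n_trees=100, n_repeats=1, seed=1), k_folds=5
        )
        assert auc_mann_whitney(preds.scored()) > 0.95

    def test_fold_assignment_deterministic_and_stratified(self):
        ds = make_cohort([0.5], [0.3], n=500, seed=8)
        a = stratified_folds(ds.y, 5, cv_seed=3)
        b = stratified_folds(ds.y, 5, cv_seed=3)
        assert np.array_equal(a, b)
        rates = [ds.y[a == f].mean() for f in range(5)]
        assert max(rates) - min(rates) < 0.1


class TestSequentialSelection:
    def test_alpha_one_selects_k_min(self):
        ds = make_cohort([1.0, 0.5, 0.0, 0.0], [0.3] * 4, n=600, seed=9)
        params = RfParams(mtry=2, n_trees=60, n_repeats=1, seed=0)
        nested, sel = sequential_selection(
            ds, list(ds.names), params, k_folds=3, alpha=1.0, k_min=3, n_boot=300
        )
        assert sel.chosen_k == 3
        assert sel.retained == list(ds.names)[:3]

    def test_full_rank_list_matches_full_model_scores(self):
        """With no negative-importance exclusions, the k = p nested model and
        the full reference model are the same forest: identical score vectors
        and a DeLong p of 1."""
        ds = make_cohort([1.2, 0.6, 0.0], [0.3, 0.25, 0.3], n=500, seed=10)
        params = RfParams(mtry=2, n_trees=60, n_repeats=1, seed=5)
        nested, sel = sequential_selection(
            ds, list(ds.names), params, k_folds=3, alpha=0.0, k_min=3, n_boot=300
        )
        last = nested[-1]
        assert last.k == ds.p
        assert last.delong_p_vs_full == 1.0

    def test_signal_concentrated_in_top_ranks_selects_small_model(self):
        betas = [2.2, 1.8, 1.5] + [0.0] * 5
        ds = make_cohort(betas, [0.35] * 8, n=3000, intercept=-2.2, seed=11)
        params = RfParams(mtry=2, n_trees=250, n_repeats=3, seed=3)
        table = average_importance(ds, params)
        ranked = filter_negative(table)
        assert ranked[:3] == ["x0", "x1", "x2"]
        nested, sel = sequential_selection(
            ds, ranked, params, k_folds=5, alpha=0.05, k_min=3, n_boot=500
        )
        assert sel.chosen_k is not None and sel.chosen_k <= 5


def test_mtry_sweep_runs_each_value_independently():
    ds = make_cohort([1.5, 0.8, 0.0, 0.0], [0.3] * 4, n=500, seed=12)
    out = mtry_sweep(
        ds, mtry_values=(1, 2), n_trees=50, n_repeats=2, k_folds=3, n_boot=300, seed=1
    )
    assert set(out) == {1, 2}
    for entry in out.values():
        assert len(entry["importance"]) == 4
        assert entry["selection"].mtry in (1, 2)
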