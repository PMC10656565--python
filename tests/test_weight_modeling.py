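"""Splits, cross-validated grid search, feature selection, temporal schemes
and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from uavpheno.phenotype_features import FeatureTable
from uavpheno.weight_modeling import (
    GROWTH_PATTERN_ANCHORS,
    ModelSpec,
    TemporalScheme,
    build_design,
    cross_validate,
    exhaustive_selection,
    prior_to_harvest_sweep,
    r_squared,
    rf_importance,
    rmse,
    select_timepoints,
    sfs_forward,
    split_data,
)


def _table(n_rows, tps=(12, 40), n_feats=7, seed=0, weights=None):
    rng = np.random.default_rng(seed)
    cols = [f"f{i}@{dat}" for dat in tps for i in range(n_feats)]
    data = pd.DataFrame(rng.normal(size=(n_rows, len(cols))), columns=cols)
    if weights is None:
        weights = pd.Series(rng.uniform(500, 5000, size=n_rows))
    return FeatureTable(data=data, weights=weights)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_case(self):
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, y_hat) == pytest.approx(0.5)
        assert rmse(y, y_hat) == pytest.approx(np.sqrt(1 / 3))

    def test_matches_textbook_oracles(self):
        from sklearn.metrics import mean_squared_error, r2_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=50)
            y_hat = y + rng.normal(size=50)
            assert abs(r_squared(y, y_hat) - r2_score(y, y_hat)) < 1e-12
            assert abs(rmse(y, y_hat) - np.sqrt(mean_squared_error(y, y_hat))) < 1e-12

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.arange(5.0))


class TestSplit:
    def test_reported_split_sizes(self):
        table = _table(839)
        train, test = split_data(table, test_fraction=0.10, seed=0)
        assert (len(train.data), len(test.data)) == (756, 83)

    def test_disjoint_and_deterministic(self):
        table = _table(100)
        tr1, te1 = split_data(table, seed=4)
        tr2, te2 = split_data(table, seed=4)
        assert set(tr1.data.index).isdisjoint(te1.data.index)
        assert list(tr1.data.index) == list(tr2.data.index)
        assert list(te1.data.index) == list(te2.data.index)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            split_data(_table(9), seed=0)


class TestCrossValidate:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X @ np.array([3.0, -2.0, 1.0, 0.5, 4.0]) + 7
        res = cross_validate(ModelSpec("lasso", seed=0), X, y)
        assert res.mean_cv_r2 >= 0.999

    def test_fold_sizes_near_equal(self):
        from uavpheno.weight_modeling import _fold_indices

        folds = _fold_indices(756, 5, seed=0)
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [151, 151, 151, 151, 152]

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(size=40)
        r1 = cross_validate(ModelSpec("ridge", seed=2), X, y)
        r2 = cross_validate(ModelSpec("ridge", seed=2), X, y)
        np.testing.assert_array_equal(r1.fold_r2, r2.fold_r2)
        assert r1.best_params == r2.best_params

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("ridge"), np.eye(10), np.ones(10))

    def test_oof_predictions_cover_each_row_once(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = X[:, 0] + rng.normal(size=25)
        res = cross_validate(ModelSpec("ridge", seed=0), X, y)
        assert res.oof_predictions.shape == (25,)
        assert np.isfinite(res.oof_predictions).all()


def _signal_frame(rng, n=120, p=8, noise=0.1):
    X = rng.normal(size=(n, p))
    y = X[:, 0] + X[:, 1] + rng.normal(0, noise, size=n)
    cols = [f"x{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestSelection:
    def test_exhaustive_subset_count(self):
        rng = np.random.default_rng(0)
        df, y = _signal_frame(rng, n=40, p=3)
        out = exhaustive_selection(df, y, seed=0)
        assert len(out) == 7  # 2^3 - 1

    def test_exhaustive_rejects_large_p(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 16)))
        df.columns = [f"x{i}" for i in range(16)]
        with pytest.raises(ValueError, match="sfs"):
            exhaustive_selection(df, rng.normal(size=20))

    def test_exhaustive_recovers_generators(self):
        rng = np.random.default_rng(2)
        df, y = _signal_frame(rng)
        out = exhaustive_selection(df, y, max_set_size=2, seed=0)
        best2 = out[(out["size"] == 2) & out["best_in_size"]]["features"].iloc[0]
        assert set(best2) == {"x0", "x1"}

    def test_exhaustive_best_score_nests_within_tolerance(self):
        rng = np.random.default_rng(3)
        df, y = _signal_frame(rng, p=4)
        out = exhaustive_selection(df, y, seed=0)
        best = out[out["best_in_size"]].sort_values("size")["cv_r2"].to_numpy()
        assert (np.diff(best) >= -0.02).all()

    def test_sfs_dominant_feature_first(self):
        rng = np.random.default_rng(4)
        df, y = _signal_frame(rng)
        y = 5 * df["x3"].to_numpy() + rng.normal(0, 0.1, size=len(df))
        path = sfs_forward(df, y, n_select=3, seed=0)
        assert path[0] == "x3"

    def test_sfs_full_path_is_permutation_with_prefix_property(self):
        rng = np.random.default_rng(5)
        df, y = _signal_frame(rng, n=60, p=5)
        full = sfs_forward(df, y, n_select=5, seed=0)
        assert sorted(full) == sorted(df.columns)
        short = sfs_forward(df, y, n_select=2, seed=0)
        assert full[:2] == short

    def test_rf_importance_normalized_and_deterministic(self):
        rng = np.random.default_rng(6)
        df, y = _signal_frame(rng)
        imp1 = rf_importance(df, y, seed=1)
        imp2 = rf_importance(df, y, seed=1)
        assert imp1.sum() == pytest.approx(1.0)
        pd.testing.assert_series_equal(imp1, imp2)
        assert set(imp1.index[:2]) == {"x0", "x1"}


class TestSelectTimepoints:
    def test_exact_weekly_calendar(self):
        sch = TemporalScheme("interval_7d")
        assert select_timepoints([12, 19, 26, 33], sch) == [12, 19, 26, 33]

    def test_greedy_walk_on_4day_calendar(self):
        sch = TemporalScheme("interval_7d")
        assert select_timepoints([12, 16, 20, 24, 28], sch) == [12, 20, 28]

    def test_growth_pattern_exact_membership(self):
        cal = [12, 20, 34, 45, 56, 70, 80, 90, 101]
        sch = TemporalScheme("growth_pattern")
        assert select_timepoints(cal, sch) == list(GROWTH_PATTERN_ANCHORS)

    def test_cutoff_truncates(self):
        sch = TemporalScheme("all_tps", cutoff_dat=40)
        assert select_timepoints([12, 40, 54, 80], sch) == [12, 40]

    def test_empty_after_cutoff_rejected(self):
        with pytest.raises(ValueError):
            select_timepoints([12, 40], TemporalScheme("all_tps", cutoff_dat=5))


class TestBuildDesign:
    def test_cumulative_column_count(self):
        table = _table(30, tps=(12, 20, 28, 36), n_feats=7)
        X, y = build_design(table, TemporalScheme("all_tps", "cumulative", 36))
        assert X.shape[1] == 7 * 4

    def test_single_tp_columns(self):
        table = _table(30, tps=(12, 20, 28, 36), n_feats=7)
        X, _ = build_design(table, TemporalScheme("all_tps", "single_tp", 36))
        assert X.shape[1] == 7
        assert all(c.endswith("@36") for c in X.columns)

    def test_cutoff_before_second_tp_collapses_modes(self):
        table = _table(30, tps=(12, 20), n_feats=3)
        Xc, _ = build_design(table, TemporalScheme("all_tps", "cumulative", 12))
        Xs, _ = build_design(table, TemporalScheme("all_tps", "single_tp", 12))
        pd.testing.assert_frame_equal(Xc, Xs)


class TestSweepAndLeakage:
    def _signal_table(self, n=60):
        rng = np.random.default_rng(7)
        tps = (12, 40, 80)
        cols = [f"f{i}@{dat}" for dat in tps for i in range(3)]
        data = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        w = 1000 + 300 * data["f0@80"] + 100 * data["f1@40"] + rng.normal(0, 30, n)
        return FeatureTable(data=data, weights=pd.Series(w.clip(lower=1.0)))

    def test_sweep_bookkeeping(self):
        table = self._signal_table()
        out = prior_to_harvest_sweep(
            table,
            [TemporalScheme("all_tps", "cumulative")],
            harvest_dat=85,
            models=[ModelSpec("ridge", seed=0), ModelSpec("lasso", seed=0)],
            seed=0,
        )
        assert len(out) == 3 * 2  # cutoffs x models
        assert set(out["dph"]) == {85 - 12, 85 - 40, 85 - 80}

    def test_training_metrics_blind_to_test_weights(self):
        table = self._signal_table()
        train, test = split_data(table, seed=0)
        X, y = build_design(train, TemporalScheme("all_tps", "cumulative", 80))
        before = cross_validate(ModelSpec("ridge", seed=0), X, y)
        # scramble the held-out weights; training-fold metrics cannot move
        test.weights[:] = test.weights.sample(frac=1.0, random_state=1).to_numpy()
        after = cross_validate(ModelSpec("ridge", seed=0), X, y)
        np.testing.assert_array_equal(before.fold_r2, after.fold_r2)
        np.testing.assert_array_equal(before.fold_rmse, after.fold_rmse)
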