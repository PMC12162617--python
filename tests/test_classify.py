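"""Youden thresholding, fold construction, CV mechanics, grid search, sweep."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from settledown import (
    RFParams,
    WindowSpec,
    YoudenForestClassifier,
    grid_search_params,
    run_cv,
    stratified_folds,
    sweep_window_stride,
    youden_threshold,
)
from settledown.features import FEATURE_NAMES
from settledown.types import SettlingPeriod

from oracles import youden_brute_force


def toy_table(n_per_class=120, sep=3.0, seed=0, n_children=8):
    """Gaussian two-class feature table; sep in within-class SD units."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in (("SS", sep), ("NSS", 0.0)):
        for i in range(n_per_class):
            feats = rng.normal(mu, 1.0, size=len(FEATURE_NAMES))
            rows.append(
                {
                    "child_id": f"{g}{i % n_children}",
                    "night_date": f"2021-10-{(i % 9) + 1:02d}",
                    "group": g,
                    "window_start": i,
                    **dict(zip(FEATURE_NAMES, feats)),
                }
            )
    return pd.DataFrame(rows)


class TestYouden:
    def test_separable_returns_lowest_perfect_midpoint(self):
        t = youden_threshold(np.array([1, 1, 0, 0], bool), np.array([0.9, 0.8, 0.1, 0.2]))
        assert t == pytest.approx(0.5)

    def test_constant_scores_zero_j_lowest_candidate(self):
        t = youden_threshold(np.array([1, 0, 1, 0], bool), np.full(4, 0.7))
        assert t == -np.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold(np.ones(4, bool), np.arange(4.0))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            labels = np.zeros(n, bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or (~labels).all():
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
            assert youden_threshold(labels, scores) == youden_brute_force(
                labels.tolist(), scores.tolist()
            )

    def test_chosen_threshold_beats_default_half(self):
        rng = np.random.default_rng(6)
        labels = rng.random(60) < 0.4
        labels[0], labels[1] = True, False
        scores = np.clip(rng.normal(0.3 + 0.3 * labels, 0.2), 0, 1)

        def j_at(t):
            pred = scores >= t
            return pred[labels].mean() - pred[~labels].mean()

        assert j_at(youden_threshold(labels, scores)) >= j_at(0.5) - 1e-12


class TestFolds:
    def test_disjoint_cover(self):
        table = toy_table(50)
        folds = stratified_folds(table, k=10, seed=0)
        test_sets = [set(te) for _, te in folds]
        assert sum(len(t) for t in test_sets) == len(table)
        assert set().union(*test_sets) == set(range(len(table)))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)

    def test_label_ratio_within_5_points(self):
        table = toy_table(n_per_class=90)
        # make it 60/40 by dropping some NSS rows
        table = pd.concat([table[table.group == "SS"], table[table.group == "NSS"].iloc[:60]])
        table = table.reset_index(drop=True)
        global_ratio = (table.group == "SS").mean()
        for _, te in stratified_folds(table, k=10, seed=1):
            ratio = (table.iloc[te].group == "SS").mean()
            assert abs(ratio - global_ratio) <= 0.05 + 1e-9

    def test_paper_mode_spreads_subjects(self):
        table = toy_table(100)
        folds = stratified_folds(table, k=10, mode="paper", seed=0)
        # every subject appears in several different test folds
        for cid in table.child_id.unique():
            rows = set(np.flatnonzero(table.child_id == cid))
            hit = sum(1 for _, te in folds if rows & set(te))
            assert hit >= 5

    def test_grouped_mode_isolates_subjects(self):
        table = toy_table(100, n_children=10)
        folds = stratified_folds(table, k=5, mode="grouped", seed=0)
        for cid in table.child_id.unique():
            rows = set(np.flatnonzero(table.child_id == cid))
            in_test = [bool(rows & set(te)) for _, te in folds]
            assert sum(in_test) == 1
            for tr, te in folds:
                assert not (rows & set(tr) and rows & set(te))

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(toy_table(2), k=1000)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        clf = YoudenForestClassifier(n_trees=7, max_depth=2, random_state=3)
        assert clf.get_params() == {"n_trees": 7, "max_depth": 2, "random_state": 3}
        clf.set_params(n_trees=9)
        assert clf.n_trees == 9

    def test_fit_sets_attributes_and_positive_class(self):
        table = toy_table(40)
        X = table[FEATURE_NAMES].to_numpy()
        y = table["group"].to_numpy()
        clf = YoudenForestClassifier(n_trees=20, random_state=0).fit(X, y)
        assert list(clf.classes_) == ["NSS", "SS"]
        assert np.isfinite(clf.threshold_) or clf.threshold_ in (-np.inf, np.inf)
        assert set(clf.predict(X)) <= {"NSS", "SS"}

    def test_vote_fraction_bounds_and_auc_monotone_invariance(self):
        table = toy_table(40, sep=1.0)
        X = table[FEATURE_NAMES].to_numpy()
        y = table["group"].to_numpy()
        clf = YoudenForestClassifier(n_trees=30, random_state=0).fit(X, y)
        s = clf.vote_fraction(X)
        assert np.all((0 <= s) & (s <= 1))
        pos = y == "SS"
        a0 = roc_auc_score(pos, s)
        assert roc_auc_score(pos, np.exp(4 * s)) == pytest.approx(a0, abs=1e-12)

    def test_binary_only(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            YoudenForestClassifier().fit(X, np.array(["a", "b", "c"]))


class TestRunCV:
    def test_separable_data_near_perfect(self):
        rep = run_cv(toy_table(100, sep=6.0), RFParams(n_trees=30, seed=0), k=5)
        assert rep.accuracy >= 0.99
        assert rep.auc >= 0.99

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(8)
        aucs = []
        for seed in range(5):
            table = toy_table(100, sep=4.0, seed=seed)
            table["group"] = rng.permutation(table["group"].to_numpy())
            rep = run_cv(table, RFParams(n_trees=30, seed=seed), k=5, seed=seed)
            aucs.append(rep.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_averages_equal_fold_recomputation(self):
        rep = run_cv(toy_table(60, sep=1.0), RFParams(n_trees=20, seed=1), k=5)
        for col in ("accuracy", "sensitivity", "specificity", "auc"):
            assert getattr(rep, col) == pytest.approx(rep.folds[col].mean())

    def test_empty_and_single_class_rejected(self):
        with pytest.raises(ValueError):
            run_cv(toy_table(0), RFParams())
        one = toy_table(30)
        one = one[one.group == "SS"].reset_index(drop=True)
        with pytest.raises(ValueError):
            run_cv(one, RFParams(n_trees=5), k=2)


class TestGridSearch:
    def test_single_cell_grid(self):
        params = grid_search_params(toy_table(40), grid=[(17, 4)], inner_folds=3)
        assert (params.n_trees, params.max_depth) == (17, 4)

    def test_tie_break_prefers_smallest_model(self):
        params = grid_search_params(
            toy_table(80, sep=8.0),  # separable: every cell reaches AUC 1
            grid=[(50, None), (50, 3), (100, 3), (100, None)],
            inner_folds=3,
            seed=0,
        )
        assert (params.n_trees, params.max_depth) == (50, 3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_params(toy_table(20), grid=[])

    def test_deterministic(self):
        a = grid_search_params(toy_table(60, sep=0.5), grid=[(20, 3), (40, None)], seed=2)
        b = grid_search_params(toy_table(60, sep=0.5), grid=[(20, 3), (40, None)], seed=2)
        assert a == b


class TestSweep:
    def _periods(self, seed=0):
        rng = np.random.default_rng(seed)
        periods = []
        for g, mu in (("SS", 2500), ("NSS", 1200)):
            for i in range(6):
                for day in range(1, 5):
                    start = pd.Timestamp(f"2021-10-{day:02d} 21:00")
                    L = int(rng.integers(14, 30))
                    counts = rng.exponential(mu, L).round()
                    periods.append(
                        SettlingPeriod(f"{g}{i}", start.date(), g, start,
                                       start + pd.Timedelta(minutes=L), counts)
                    )
        return periods

    def test_full_grid_emitted_and_deterministic(self):
        periods = self._periods()
        grid = [(7, 1), (7, 3), (9, 1), (9, 3)]
        a = sweep_window_stride(periods, grid, RFParams(n_trees=15, seed=0), k=3, seed=0)
        b = sweep_window_stride(periods, grid, RFParams(n_trees=15, seed=0), k=3, seed=0)
        assert len(a.rows) == 4
        assert list(a.rows[["window_min", "stride_min"]].itertuples(index=False, name=None)) == grid
        pd.testing.assert_frame_equal(a.rows, b.rows)
        assert a.best == b.best

    def test_oversized_window_yields_undefined_cell(self):
        periods = self._periods()
        rep = sweep_window_stride(periods, [(40, 1)], RFParams(n_trees=5, seed=0), k=2, seed=0)
        assert np.isnan(rep.rows["mean_auc"].iloc[0])
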