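"""Random-forest SS/NSS window classification with Youden-J thresholding.

The classifier is a random forest whose score for a window is the fraction
of trees voting for the positive (SS) class; the decision threshold is not
the default 0.5 but the Youden-J maximizer (J = TPR - FPR) computed on the
*training* scores, wrapped as the sklearn-compatible estimator
:class:`YoudenForestClassifier`.

Cross-validation follows the window-level scheme of the source analysis by
default (``mode="paper"``: each subject's windows are spread across folds,
so a subject can appear in both train and test — optimistic under subject
heterogeneity) and offers a leakage-safe alternative (``mode="grouped"``:
whole subjects assigned to folds via stratified group k-fold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, WindowSpec, build_feature_table
from .types import SS, SettlingPeriod

log = logging.getLogger(__name__)

POSITIVE_CLASS = SS


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 100
    max_depth: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None (unlimited)")


def youden_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Score threshold maximizing J = TPR - FPR (classify positive at >= t).

    Candidates are midpoints between adjacent distinct sorted scores plus
    -inf and +inf; ties in J resolve to the lowest threshold.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or (~y).all():
        raise ValueError("need at least one positive and one negative label")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    n_pos, n_neg = y.sum(), (~y).sum()
    best_t, best_j = -np.inf, -np.inf
    for t in candidates:
        pred = s >= t
        j = (pred & y).sum() / n_pos - (pred & ~y).sum() / n_neg
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


class YoudenForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with vote-fraction scores and a Youden-J threshold.

    Parameters
    ----------
    n_trees : number of trees in the forest.
    max_depth : maximum tree depth; None grows trees fully.
    random_state : forest seed.

    Fitted attributes
    -----------------
    classes_ : the two class labels (negative, positive).
    forest_ : the fitted ``RandomForestClassifier``.
    threshold_ : Youden-J threshold computed on the training vote fractions.
    """

    def __init__(self, n_trees: int = 100, max_depth: Optional[int] = None,
                 random_state: Optional[int] = None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("YoudenForestClassifier is strictly binary")
        # put the SS / positive label second
        if POSITIVE_CLASS in classes:
            classes = np.array([c for c in classes if c != POSITIVE_CLASS] + [POSITIVE_CLASS])
        self.classes_ = classes
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        train_scores = self.vote_fraction(X)
        self.threshold_ = youden_threshold(y == self.classes_[1], train_scores)
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees whose majority-vote prediction is the positive class."""
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        votes = np.stack([tree.predict(X) for tree in self.forest_.estimators_])
        pos_code = np.flatnonzero(self.forest_.classes_ == self.classes_[1])[0]
        return (votes == pos_code).mean(axis=0)

    def predict_proba(self, X) -> np.ndarray:
        p = self.vote_fraction(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return np.where(self.vote_fraction(X) >= self.threshold_,
                        self.classes_[1], self.classes_[0])


def stratified_folds(
    table: pd.DataFrame, k: int = 10, mode: str = "paper", seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """k disjoint (train_idx, test_idx) splits of a feature table.

    ``mode="paper"`` deals each subject's (shuffled) windows round-robin
    across folds, so every fold sees every subject and the label ratio
    tracks the global one; ``mode="grouped"`` keeps each subject's windows
    in a single test fold (stratified group k-fold, leakage-safe).
    """
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    y = (table["group"] == POSITIVE_CLASS).to_numpy()
    groups = table["child_id"].to_numpy()
    if mode == "grouped":
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), y, groups)]
    if mode != "paper":
        raise ValueError(f"unknown fold mode {mode!r}")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for cid in sorted(pd.unique(groups)):
        idx = np.flatnonzero(groups == cid)
        rng.shuffle(idx)
        start = int(np.argmin(fold_sizes))
        for i, row in enumerate(idx):
            assign[row] = (start + i) % k
        fold_sizes += np.bincount((start + np.arange(len(idx))) % k, minlength=k)
    all_idx = np.arange(n)
    return [(all_idx[assign != f], all_idx[assign == f]) for f in range(k)]


@dataclass
class CVReport:
    folds: pd.DataFrame  # fold_index, accuracy, sensitivity, specificity, auc, threshold
    params: RFParams
    spec: WindowSpec
    mode: str

    @property
    def accuracy(self) -> float:
        return float(self.folds["accuracy"].mean())

    @property
    def sensitivity(self) -> float:
        return float(self.folds["sensitivity"].mean())

    @property
    def specificity(self) -> float:
        return float(self.folds["specificity"].mean())

    @property
    def auc(self) -> float:
        return float(self.folds["auc"].mean())

    def summary(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def run_cv(
    table: pd.DataFrame,
    params: RFParams = RFParams(),
    k: int = 10,
    mode: str = "paper",
    seed: Optional[int] = None,
    spec: WindowSpec = WindowSpec(),
) -> CVReport:
    """Stratified k-fold CV of the Youden-thresholded forest.

    Per fold the forest is fit on the training windows, the threshold comes
    from the training vote fractions, and accuracy / sensitivity (SS
    positive) / specificity / AUC are evaluated on the test windows.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if seed is None:
        seed = params.seed
    X = table[FEATURE_NAMES].to_numpy(float)
    y = np.where(table["group"] == POSITIVE_CLASS, POSITIVE_CLASS, "NSS")
    if len(np.unique(y)) < 2:
        raise ValueError("feature table must contain both classes")
    rows = []
    for f, (tr, te) in enumerate(stratified_folds(table, k=k, mode=mode, seed=seed)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn(f"fold {f}: single-class split, skipped")
            continue
        clf = YoudenForestClassifier(
            n_trees=params.n_trees, max_depth=params.max_depth,
            random_state=params.seed + f,
        ).fit(X[tr], y[tr])
        scores = clf.vote_fraction(X[te])
        y_pos = y[te] == POSITIVE_CLASS
        pred_pos = scores >= clf.threshold_
        rows.append(
            {
                "fold_index": f,
                "accuracy": float((pred_pos == y_pos).mean()),
                "sensitivity": float(pred_pos[y_pos].mean()),
                "specificity": float((~pred_pos[~y_pos]).mean()),
                "auc": float(roc_auc_score(y_pos, scores)),
                "threshold": clf.threshold_,
            }
        )
    return CVReport(folds=pd.DataFrame(rows), params=params, spec=spec, mode=mode)


DEFAULT_GRID: List[Tuple[int, Optional[int]]] = [
    (t, d) for t in (100, 200, 500) for d in (3, 5, 10, None)
]


def grid_search_params(
    train_table: pd.DataFrame,
    grid: Sequence[Tuple[int, Optional[int]]] = tuple(DEFAULT_GRID),
    inner_folds: int = 5,
    seed: int = 0,
) -> RFParams:
    """Best (n_trees, max_depth) by inner-CV AUC on the training split.

    Deterministic tie-break: fewer trees first, then shallower depth
    (None = unlimited sorts deepest).
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    X = train_table[FEATURE_NAMES].to_numpy(float)
    y = (train_table["group"] == POSITIVE_CLASS).to_numpy()
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    results = []
    for n_trees, depth in grid:
        aucs = []
        for tr, te in splits:
            forest = RandomForestClassifier(
                n_estimators=n_trees, max_depth=depth, random_state=seed, n_jobs=1
            ).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], forest.predict_proba(X[te])[:, 1]))
        results.append((float(np.mean(aucs)), n_trees, depth))
    depth_key = lambda d: np.inf if d is None else d
    best = max(results, key=lambda r: (r[0], -r[1], -depth_key(r[2])))
    log.info("grid search: best AUC %.3f at n_trees=%d depth=%s", *best)
    return RFParams(n_trees=best[1], max_depth=best[2], seed=seed)


def split_4to1(
    table: pd.DataFrame, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 4:1 train/test split of the feature table."""
    y = (table["group"] == POSITIVE_CLASS).to_numpy()
    tr, te = train_test_split(
        np.arange(len(table)), test_size=0.2, stratify=y, random_state=seed
    )
    return table.iloc[np.sort(tr)], table.iloc[np.sort(te)]


@dataclass
class SweepReport:
    rows: pd.DataFrame  # window_min, stride_min, mean_auc
    best: Optional[Tuple[int, int]] = None


DEFAULT_SWEEP_GRID = [(w, s) for w in (7, 9, 11, 13) for s in (1, 3)]


def sweep_window_stride(
    periods: List[SettlingPeriod],
    grid: Sequence[Tuple[int, int]] = tuple(DEFAULT_SWEEP_GRID),
    params: RFParams = RFParams(),
    k: int = 10,
    mode: str = "paper",
    seed: Optional[int] = None,
) -> SweepReport:
    """Rebuild the feature table and run k-fold CV for every (window, stride)."""
    rows = []
    for w, s in grid:
        spec = WindowSpec(window_min=w, stride_min=s)
        table = build_feature_table(periods, spec)
        if len(table) == 0 or table["group"].nunique() < 2:
            rows.append({"window_min": w, "stride_min": s, "mean_auc": np.nan})
            continue
        report = run_cv(table, params=params, k=k, mode=mode, seed=seed, spec=spec)
        rows.append({"window_min": w, "stride_min": s, "mean_auc": report.auc})
    df = pd.DataFrame(rows)
    best = None
    if df["mean_auc"].notna().any():
        top = df.loc[df["mean_auc"].idxmax()]
        best = (int(top["window_min"]), int(top["stride_min"]))
    return SweepReport(rows=df, best=best)
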