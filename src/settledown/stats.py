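"""Permutation feature importance, subject aggregates, group tests and the
post-hoc standardized regressions.

Statistical conventions: the Mann-Whitney U reported here counts (x, y)
pairs with x > y (plus half-ties) and is accompanied by a signed z from the
tie-corrected normal approximation without continuity correction — group
tables in this literature sometimes print the z where "U" is labelled, so
both are reported explicitly. Regressions are OLS with standardized betas
``b * sd(x)/sd(y)`` (sample n-1 SDs); no multiple-testing correction is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .classify import POSITIVE_CLASS, RFParams, YoudenForestClassifier, split_4to1
from .features import FEATURE_NAMES
from .types import ChildRecord, SettlingPeriod

log = logging.getLogger(__name__)


def permutation_importance(
    table: pd.DataFrame,
    params: RFParams = RFParams(),
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] = tuple(FEATURE_NAMES),
) -> pd.DataFrame:
    """Refit-from-scratch permutation importance scored by held-out AUC.

    A 4:1 stratified split is drawn; the baseline forest is fit on the
    training portion and scored on the held-out portion. For each feature,
    ``n_repeats`` times: that feature's column is permuted across *all*
    rows, the forest is refit from scratch on the permuted training rows,
    and AUC is measured on the (equally permuted) held-out rows.
    Importance = baseline AUC - mean permuted AUC.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    table = table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    train, test = split_4to1(table, seed=seed)
    tr_idx = train.index.to_numpy()
    te_idx = test.index.to_numpy()
    X = table[list(feature_names)].to_numpy(float)
    y = np.where(table["group"] == POSITIVE_CLASS, POSITIVE_CLASS, "NSS")
    pos_te = y[te_idx] == POSITIVE_CLASS

    def auc_of(Xm: np.ndarray, rs: int) -> float:
        clf = YoudenForestClassifier(
            n_trees=params.n_trees, max_depth=params.max_depth, random_state=rs
        ).fit(Xm[tr_idx], y[tr_idx])
        return roc_auc_score(pos_te, clf.vote_fraction(Xm[te_idx]))

    baseline = auc_of(X, params.seed)
    rows = []
    for j, name in enumerate(feature_names):
        drops = []
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - auc_of(Xp, params.seed + r + 1))
        rows.append(
            {
                "feature_name": name,
                "mean_auc_decrease": float(np.mean(drops)),
                "sd_auc_decrease": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
                "n_repeats": n_repeats,
                "baseline_auc": baseline,
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_auc_decrease", ascending=False)
    return out.reset_index(drop=True)


def subject_aggregates(
    table: pd.DataFrame,
    periods: List[SettlingPeriod],
    records: Optional[List[ChildRecord]] = None,
) -> pd.DataFrame:
    """Per-child aggregates feeding the group tests and regressions.

    * ``mean_magnitude``     — mean window mean magnitude over all windows;
    * ``mean_max_magnitude`` — mean over nights of the per-night maximum
      window maximum magnitude;
    * ``median_entropy``     — median window entropy over all windows;
    * ``mean/sd_settling_min`` — over the child's nightly durations.

    Children with no windows are excluded (logged).
    """
    durations: Dict[str, List[float]] = {}
    for p in periods:
        durations.setdefault(p.child_id, []).append(float(p.duration_min))
    meta = {r.child_id: r for r in records} if records else {}
    rows = []
    for cid in sorted(durations):
        sub = table[table["child_id"] == cid]
        if len(sub) == 0:
            log.info("subject %s has no windows; excluded from aggregates", cid)
            continue
        d = np.array(durations[cid])
        night_max = sub.groupby("night_date")["max_mag"].max()
        row = {
            "child_id": cid,
            "group": sub["group"].iloc[0],
            "mean_settling_min": float(d.mean()),
            "sd_settling_min": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "mean_magnitude": float(sub["mean_mag"].mean()),
            "mean_max_magnitude": float(night_max.mean()),
            "median_entropy": float(sub["entropy_bits"].median()),
        }
        if cid in meta:
            row["age_years"] = meta[cid].age_years
            row["sex"] = meta[cid].sex
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Mann-Whitney U (pairs with x > y, half-ties), signed z, two-sided p.

    The z uses the tie-corrected normal approximation
    ``sigma_U^2 = n1*n2/12 * ((n+1) - sum(t^3 - t)/(n*(n-1)))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:
        raise ValueError("degenerate samples: all values identical")
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma_sq)
    p = 2.0 * sps.norm.sf(abs(z))
    return u, float(z), float(p)


def group_tests(
    aggregates: pd.DataFrame,
    variables: Sequence[str] = (
        "mean_settling_min",
        "mean_magnitude",
        "mean_max_magnitude",
        "sd_settling_min",
        "median_entropy",
    ),
) -> pd.DataFrame:
    """Group means/SDs plus Mann-Whitney U, z, p for each subject aggregate.

    A variable that is constant across both groups (e.g. entropy saturated
    at its ceiling) has no defined test; its U/z/p are reported as NaN.
    """
    ss = aggregates[aggregates["group"] == POSITIVE_CLASS]
    nss = aggregates[aggregates["group"] != POSITIVE_CLASS]
    rows = []
    for var in variables:
        try:
            u, z, p = mann_whitney(ss[var], nss[var])
        except ValueError:
            log.info("group test for %s degenerate (constant variable)", var)
            u = z = p = float("nan")
        rows.append(
            {
                "variable": var,
                "ss_mean": ss[var].mean(),
                "ss_sd": ss[var].std(ddof=1),
                "nss_mean": nss[var].mean(),
                "nss_sd": nss[var].std(ddof=1),
                "U": u,
                "z": z,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    model_id: str
    standardized_betas: Dict[str, float]
    unstandardized_betas: Dict[str, float]
    std_errors: Dict[str, float]
    p_values: Dict[str, float]
    constant: float
    constant_se: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    n_obs: int


def posthoc_regression(
    aggregates: pd.DataFrame, predictor: Optional[str] = None
) -> RegressionResult:
    """OLS of mean settling duration on group (+ optional predictor), with
    age and sex (F=0, M=1) as covariates; standardized betas reported."""
    need = {"age_years", "sex"}
    if not need.issubset(aggregates.columns):
        raise ValueError("aggregates must carry age_years and sex for regression")
    df = aggregates.copy()
    outcome = df["mean_settling_min"].to_numpy(float)
    design = {
        "group": (df["group"] == POSITIVE_CLASS).astype(float).to_numpy(),
    }
    if predictor is not None:
        if predictor not in df.columns:
            raise ValueError(f"unknown predictor {predictor!r}")
        design[predictor] = df[predictor].to_numpy(float)
    design["age_years"] = df["age_years"].to_numpy(float)
    design["sex"] = (df["sex"] == "M").astype(float).to_numpy()
    X = pd.DataFrame(design)
    if (X.std(ddof=1) == 0).any():
        raise ValueError("singular design: a predictor column has zero variance")
    if len(df) < X.shape[1] + 2:
        raise ValueError("too few subjects for the requested model")
    model = sm.OLS(outcome, sm.add_constant(X)).fit()
    sd_y = float(np.std(outcome, ddof=1))
    std_betas = {
        c: float(model.params[c] * X[c].std(ddof=1) / sd_y) for c in X.columns
    }
    return RegressionResult(
        model_id=predictor or "group_only",
        standardized_betas=std_betas,
        unstandardized_betas={c: float(model.params[c]) for c in X.columns},
        std_errors={c: float(model.bse[c]) for c in X.columns},
        p_values={c: float(model.pvalues[c]) for c in X.columns},
        constant=float(model.params["const"]),
        constant_se=float(model.bse["const"]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        n_obs=int(model.nobs),
    )


def regression_table(
    aggregates: pd.DataFrame,
    predictors: Sequence[Optional[str]] = (
        None,
        "mean_magnitude",
        "mean_max_magnitude",
        "sd_settling_min",
        "median_entropy",
    ),
) -> pd.DataFrame:
    """One column per model: standardized betas, R², F, p, n.

    Models whose design is singular on this cohort (a constant predictor)
    are reported as an all-NaN column rather than aborting the table.
    """
    rows = {}
    for i, pred in enumerate(predictors, start=1):
        try:
            res = posthoc_regression(aggregates, pred)
        except ValueError as exc:
            log.info("regression model %s unfittable: %s", pred or "group_only", exc)
            rows[f"model_{i}_{pred or 'group_only'}"] = {"n_obs": len(aggregates)}
            continue
        col = {}
        for name, beta in res.standardized_betas.items():
            col[f"beta[{name}]"] = beta
        col["constant"] = res.constant
        col["r_squared"] = res.r_squared
        col["f_stat"] = res.f_stat
        col["f_pvalue"] = res.f_pvalue
        col["n_obs"] = res.n_obs
        rows[f"model_{i}_{res.model_id}"] = col
    return pd.DataFrame(rows)
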