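"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately avoids the vectorized/library code paths of the
package: plain Python loops and first-principles definitions.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple


def sadeh_ps_scalar(counts: Sequence[float], t: int) -> float:
    """Sadeh PS for epoch t, computed epoch-by-epoch with explicit loops."""
    padded = [0.0] * 5 + list(float(c) for c in counts) + [0.0] * 5
    i = t + 5  # index into padded
    window = padded[i - 5 : i + 6]
    mw = sum(window) / 11.0
    nat = sum(1 for v in window if 50.0 <= v < 100.0)
    back = padded[i - 5 : i + 1]
    mean_b = sum(back) / 6.0
    sd6 = math.sqrt(sum((v - mean_b) ** 2 for v in back) / 5.0)
    lg = math.log(padded[i] + 1.0)
    return 7.601 - 0.065 * mw - 1.08 * nat - 0.056 * sd6 - 0.703 * lg


def rest_periods_rle(
    states: Sequence[bool], onset_run: int, offset_run: int, min_rest: int
) -> List[Tuple[int, int]]:
    """Rest periods as (start, end) epoch indices via an explicit scan.

    A period opens at the first epoch of the first not-yet-consumed run of
    >= onset_run consecutive sleep epochs and closes at the first epoch of
    the next run of >= offset_run consecutive wake epochs (or the sequence
    end); periods shorter than min_rest are dropped.
    """
    n = len(states)
    periods = []
    i = 0
    while i < n:
        # find a sleep run of length >= onset_run starting at i
        if states[i]:
            j = i
            while j < n and states[j]:
                j += 1
            if j - i >= onset_run:
                # scan forward for a wake run >= offset_run
                k = j
                end = n
                while k < n:
                    if not states[k]:
                        m = k
                        while m < n and not states[m]:
                            m += 1
                        if m - k >= offset_run:
                            end = k
                            break
                        k = m
                    else:
                        k += 1
                if end - i >= min_rest:
                    periods.append((i, end))
                i = end if end < n else n
                # skip past the closing wake run
                while i < n and not states[i]:
                    i += 1
                continue
            i = j
        else:
            i += 1
    return periods


def youden_brute_force(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Lowest threshold maximizing TPR - FPR over midpoint candidates."""
    distinct = sorted(set(scores))
    candidates = [-math.inf]
    for a, b in zip(distinct, distinct[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(math.inf)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -math.inf
    for t in candidates:
        tp = sum(1 for y, s in zip(labels, scores) if y and s >= t)
        fp = sum(1 for y, s in zip(labels, scores) if not y and s >= t)
        j = tp / n_pos - fp / n_neg
        if j > best_j:
            best_j, best_t = j, t
    return best_t


def mann_whitney_pairs(x: Sequence[float], y: Sequence[float]) -> float:
    """U by literal pair counting: #(x > y) + 0.5 * #(x == y)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def ols_normal_equations(X, y):
    """OLS via (X'X)^{-1} X'y with R^2 and overall F, no statsmodels.

    X excludes the intercept; one is prepended here. Returns
    (betas_with_const, r_squared, f_stat).
    """
    import numpy as np

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Xc = np.hstack([np.ones((n, 1)), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    resid = y - Xc @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    f = (r2 / p) / ((1.0 - r2) / (n - p - 1))
    return beta, r2, f
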