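"""Rolling-window slicing and the seven per-window activity features.

Each settling period is cut into fixed-length windows advanced by a stride;
every window yields one feature row: mean magnitude, maximum magnitude,
excess kurtosis, skewness, Shannon entropy (bits), sample standard
deviation and interquartile range.

Conventions (pinned for reproducibility):

* skewness = m3 / m2^(3/2) and kurtosis = m4 / m2^2 - 3 with central sample
  moments mk = mean((x - mean)^k) (moment definitions, no bias correction);
  both defined as 0 when m2 = 0 (constant window);
* sd uses the n-1 denominator; IQR uses linear-interpolation (type-7)
  quantiles;
* entropy is computed on the empirical distribution of the *exact* count
  values in the window, base 2, so 0 <= H <= log2(window length) with the
  maximum attained when all values are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats

from .types import EPOCH_SECONDS, SettlingPeriod

FEATURE_NAMES = ["mean_mag", "max_mag", "kurtosis", "skewness", "entropy_bits", "sd", "iqr"]


@dataclass
class WindowSpec:
    window_min: int = 11
    stride_min: int = 1

    def __post_init__(self) -> None:
        if self.window_min < 3:
            raise ValueError("window_min must be >= 3")
        if self.stride_min < 1:
            raise ValueError("stride_min must be >= 1")


def roll_windows(counts: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """All full-length windows: shape (floor((L-W)/S)+1, W); empty if L < W."""
    c = np.asarray(counts, dtype=float)
    w, s = spec.window_min, spec.stride_min
    if len(c) < w:
        return np.empty((0, w))
    return np.lib.stride_tricks.sliding_window_view(c, w)[::s].copy()


def shannon_entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of the empirical value distribution."""
    c = np.asarray(counts)
    if len(c) == 0:
        raise ValueError("entropy of an empty window is undefined")
    _, mult = np.unique(c, return_counts=True)
    p = mult / len(c)
    return float(-(p * np.log2(p)).sum())


def compute_features(counts: np.ndarray) -> Dict[str, float]:
    """The seven features of one window (length >= 3)."""
    c = np.asarray(counts, dtype=float)
    if len(c) < 3:
        raise ValueError("window must contain at least 3 epochs")
    m2 = float(np.mean((c - c.mean()) ** 2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(c, bias=True))
        kurt = float(stats.kurtosis(c, fisher=True, bias=True))
    q1, q3 = np.percentile(c, [25, 75])  # linear interpolation (type-7)
    return {
        "mean_mag": float(c.mean()),
        "max_mag": float(c.max()),
        "kurtosis": kurt,
        "skewness": skew,
        "entropy_bits": shannon_entropy_bits(c),
        "sd": float(c.std(ddof=1)),
        "iqr": float(q3 - q1),
    }


def build_feature_table(
    periods: List[SettlingPeriod], spec: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """One row per rolling window with subject/night/group metadata.

    Periods shorter than the window yield no rows (skipped, not truncated).
    Row order is deterministic: (child_id, night_date, window_start).
    """
    rows = []
    for p in sorted(periods, key=lambda p: (p.child_id, p.night_date)):
        wins = roll_windows(p.counts, spec)
        for k, win in enumerate(wins):
            feats = _features_fast(win)
            rows.append(
                {
                    "child_id": p.child_id,
                    "night_date": p.night_date,
                    "group": p.group,
                    "window_start": p.start
                    + pd.Timedelta(seconds=k * spec.stride_min * EPOCH_SECONDS),
                    **feats,
                }
            )
    cols = ["child_id", "night_date", "group", "window_start", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def _features_fast(c: np.ndarray) -> Dict[str, float]:
    # same definitions as compute_features, inlined for the hot loop
    mean = c.mean()
    d = c - mean
    m2 = np.mean(d * d)
    if m2 == 0.0:
        skew = kurt = 0.0
        sd = 0.0
    else:
        m3 = np.mean(d**3)
        m4 = np.mean(d**4)
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
        sd = np.sqrt(m2 * len(c) / (len(c) - 1))
    q1, q3 = np.percentile(c, [25, 75])
    return {
        "mean_mag": float(mean),
        "max_mag": float(c.max()),
        "kurtosis": float(kurt),
        "skewness": float(skew),
        "entropy_bits": shannon_entropy_bits(c),
        "sd": float(sd),
        "iqr": float(q3 - q1),
    }
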