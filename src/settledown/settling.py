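"""Settling-down window extraction, inclusion rules and duration summaries.

The settling-down period of a night runs from the caregiver-reported
settling start (diary mode) to the algorithmic sleep onset, half-open on the
onset. A fixed-offset fallback mode takes the 60 minutes preceding the
algorithmic onset instead, for nights (or studies) without usable diaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import EPOCH_SECONDS, ActivitySeries, DiaryEntry, SettlingPeriod, SleepOnset


@dataclass
class Rejection:
    child_id: str
    night_date: object
    reason: str  # missing_diary | onset_before_start | too_short


@dataclass
class DurationSummary:
    group: str
    mean_min: float
    sd_min: float
    n_subjects: int
    n_nights: int
    per_subject_mean: Dict[str, float]
    per_subject_sd: Dict[str, float]
    pooled_mean_min: float  # over nights, for comparison with per-subject framing
    pooled_sd_min: float


def extract_settling(
    series: ActivitySeries,
    diary: Optional[DiaryEntry],
    onset: SleepOnset,
    mode: str = "diary",
    fixed_offset_min: int = 60,
    min_duration: int = 3,
    group: Optional[str] = None,
) -> SettlingPeriod | Rejection:
    """Cut one night's settling window, or reject it with a reason code."""
    if mode not in ("diary", "fixed_offset"):
        raise ValueError(f"unknown mode {mode!r}")
    night = diary.night_date if diary is not None else onset.night_date
    if mode == "diary":
        if diary is None:
            return Rejection(series.child_id, onset.night_date, "missing_diary")
        start = diary.settling_start
        night = diary.night_date
    else:
        start = onset.onset - pd.Timedelta(minutes=fixed_offset_min)
    if onset.onset <= start:
        return Rejection(series.child_id, night, "onset_before_start")
    n_min = int(round((onset.onset - start).total_seconds() / EPOCH_SECONDS))
    if n_min < min_duration:
        return Rejection(series.child_id, night, "too_short")
    counts = series.slice_counts(start, onset.onset)
    return SettlingPeriod(
        child_id=series.child_id,
        night_date=night,
        group=group,
        start=start,
        end=onset.onset,
        counts=counts,
    )


def apply_inclusion(
    periods: List[SettlingPeriod], min_nights: int = 4
) -> Tuple[List[SettlingPeriod], List[dict]]:
    """Drop children contributing fewer than ``min_nights`` valid nights."""
    by_child: Dict[str, List[SettlingPeriod]] = {}
    for p in periods:
        by_child.setdefault(p.child_id, []).append(p)
    included: List[SettlingPeriod] = []
    exclusion_log: List[dict] = []
    for cid in sorted(by_child):
        nights = by_child[cid]
        if len(nights) < min_nights:
            exclusion_log.append(
                {
                    "child_id": cid,
                    "reason": "too_few_nights",
                    "n_valid_nights": len(nights),
                    "min_nights": min_nights,
                }
            )
        else:
            included.extend(nights)
    return included, exclusion_log


def duration_summary(periods: List[SettlingPeriod], group: str) -> DurationSummary:
    """Group settling-duration summary, per-subject and pooled-over-nights.

    The headline mean/SD are computed over per-subject means (each child one
    observation); the pooled-over-nights variant treats every night as one
    observation. Both are reported because group summaries in this literature
    are ambiguous between the two framings.
    """
    rows = [p for p in periods if p.group == group]
    if not rows:
        raise ValueError(f"no settling periods for group {group!r}")
    by_child: Dict[str, List[float]] = {}
    for p in rows:
        by_child.setdefault(p.child_id, []).append(float(p.duration_min))
    per_mean = {c: float(np.mean(v)) for c, v in by_child.items()}
    per_sd = {
        c: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for c, v in by_child.items()
    }
    subject_means = np.array(list(per_mean.values()))
    nightly = np.array([p.duration_min for p in rows], dtype=float)
    return DurationSummary(
        group=group,
        mean_min=float(subject_means.mean()),
        sd_min=float(subject_means.std(ddof=1)) if len(subject_means) > 1 else 0.0,
        n_subjects=len(per_mean),
        n_nights=len(rows),
        per_subject_mean=per_mean,
        per_subject_sd=per_sd,
        pooled_mean_min=float(nightly.mean()),
        pooled_sd_min=float(nightly.std(ddof=1)) if len(nightly) > 1 else 0.0,
    )


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Hedges' g: pooled-SD standardized mean difference with the small-sample
    correction J = 1 - 3/(4*(n1+n2-2) - 1)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    s_pooled_sq = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if s_pooled_sq == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (m1 - m2) / np.sqrt(s_pooled_sq))


def periods_frame(periods: List[SettlingPeriod]) -> pd.DataFrame:
    """Exportable settling-period table (no counts)."""
    return pd.DataFrame(
        [
            {
                "child_id": p.child_id,
                "night_date": p.night_date,
                "group": p.group,
                "start": p.start,
                "end": p.end,
                "duration_min": p.duration_min,
            }
            for p in periods
        ]
    )
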