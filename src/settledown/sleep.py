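"""Per-epoch sleep/wake scoring and nightly rest-period delimitation.

The scorer is the Sadeh pediatric discriminant

    PS = 7.601 - 0.065*MW - 1.08*NAT - 0.056*SD6 - 0.703*LG

with, for epoch ``t`` of a 60-s count series:

* ``MW``  — mean counts over the 11-epoch window centred on ``t``;
* ``NAT`` — number of epochs in that window with counts in [50, 100);
* ``SD6`` — sample (n-1) standard deviation of epochs ``t-5..t``;
* ``LG``  — natural log of (counts[t] + 1).

An epoch is scored *sleep* iff PS >= 0. The series is zero-padded by five
epochs on each side so the discriminant is defined at the boundaries.

Rest (in-bed) periods are then delimited by consecutive-epoch rules in the
style of Tudor-Locke: a period opens at the first epoch of a run of at least
``onset_run`` sleep-scored epochs and closes at the first epoch of a
subsequent run of at least ``offset_run`` wake-scored epochs; periods
shorter than ``min_rest_minutes`` are discarded. Periods are reconciled with
the caregiver diary under a 30-minute rule: the diary time replaces the
algorithmic boundary only when the two disagree by strictly less than 30
minutes (at 30+ minutes the algorithm is trusted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import EPOCH_SECONDS, ActivitySeries, DiaryEntry, RestPeriod, SleepOnset

SADEH_INTERCEPT = 7.601
SADEH_MW = 0.065
SADEH_NAT = 1.08
SADEH_SD6 = 0.056
SADEH_LG = 0.703
_HALF_WINDOW = 5


@dataclass
class ScoringParams:
    onset_run: int = 5
    offset_run: int = 10
    min_rest_minutes: int = 160
    onset_consecutive: int = 3

    def __post_init__(self) -> None:
        for name in ("onset_run", "offset_run", "min_rest_minutes", "onset_consecutive"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def sadeh_scores(counts: np.ndarray) -> np.ndarray:
    """Vector of PS values, one per epoch (zero-padded boundaries)."""
    c = np.asarray(counts, dtype=float)
    n = len(c)
    if n == 0:
        return np.empty(0)
    pad = np.concatenate([np.zeros(_HALF_WINDOW), c, np.zeros(_HALF_WINDOW)])
    win = np.lib.stride_tricks.sliding_window_view(pad, 11)  # row t = epochs t-5..t+5
    mw = win.mean(axis=1)
    nat = ((win >= 50) & (win < 100)).sum(axis=1)
    back = win[:, : _HALF_WINDOW + 1]  # epochs t-5..t
    sd6 = back.std(axis=1, ddof=1)
    lg = np.log1p(c)
    return (
        SADEH_INTERCEPT - SADEH_MW * mw - SADEH_NAT * nat - SADEH_SD6 * sd6 - SADEH_LG * lg
    )


def sadeh_ps(series: ActivitySeries, epoch_index: int) -> float:
    """PS for a single epoch of a series (scalar convenience form)."""
    return float(sadeh_scores(series.counts)[epoch_index])


def sleep_states(counts: np.ndarray) -> np.ndarray:
    """Boolean per-epoch sleep labels (True = sleep, PS >= 0)."""
    return sadeh_scores(counts) >= 0.0


def _runs(labels: np.ndarray) -> List[Tuple[bool, int, int]]:
    """Run-length encoding: (value, start, length) per maximal run."""
    out = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((bool(labels[i]), i, j - i))
        i = j
    return out


def detect_rest_periods(
    series: ActivitySeries,
    params: ScoringParams = ScoringParams(),
    states: Optional[np.ndarray] = None,
) -> List[RestPeriod]:
    """Delimit rest periods from per-epoch sleep labels.

    ``states`` defaults to Sadeh labels of the series (single-scorer design).
    A period left open at the end of the series closes at the series end.
    """
    if len(series) == 0:
        return []
    if states is None:
        states = sleep_states(series.counts)
    periods: List[RestPeriod] = []
    open_start: Optional[int] = None
    for value, start, length in _runs(np.asarray(states, bool)):
        if open_start is None:
            if value and length >= params.onset_run:
                open_start = start
        else:
            if not value and length >= params.offset_run:
                _append_period(periods, series, open_start, start, params)
                open_start = None
    if open_start is not None:
        _append_period(periods, series, open_start, len(series), params)
    return periods


def _append_period(
    periods: List[RestPeriod], series: ActivitySeries, i0: int, i1: int, params: ScoringParams
) -> None:
    if i1 - i0 < params.min_rest_minutes:
        return
    t0 = series.start_time + pd.Timedelta(seconds=i0 * EPOCH_SECONDS)
    t1 = series.start_time + pd.Timedelta(seconds=i1 * EPOCH_SECONDS)
    periods.append(RestPeriod(series.child_id, None, t0, t1, source="algorithm"))


def reconcile_with_diary(
    period: RestPeriod,
    diary: DiaryEntry,
    threshold_min: float = 30.0,
    reported_wake: Optional[pd.Timestamp] = None,
) -> RestPeriod:
    """Apply the 30-minute diary-reconciliation rule to a rest period.

    The caregiver-reported sleep onset replaces the algorithmic period start
    only when they differ by strictly less than ``threshold_min`` minutes
    (a 30+-minute disagreement keeps the algorithm). The same rule applies
    independently to the period end against a morning wake report when one
    is supplied.
    """
    start, end, source = period.start, period.end, period.source
    if diary.reported_sleep_onset is not None:
        diff = abs((diary.reported_sleep_onset - start).total_seconds()) / 60.0
        if diff < threshold_min:
            start, source = diary.reported_sleep_onset, "diary_adjusted"
    if reported_wake is not None:
        diff = abs((pd.Timestamp(reported_wake) - end).total_seconds()) / 60.0
        if diff < threshold_min:
            end, source = pd.Timestamp(reported_wake), "diary_adjusted"
    if not start < end:
        return period
    return RestPeriod(period.child_id, period.night_date, start, end, source)


def sleep_onset(
    period: RestPeriod,
    series: ActivitySeries,
    params: ScoringParams = ScoringParams(),
    states: Optional[np.ndarray] = None,
) -> Optional[SleepOnset]:
    """First epoch in the period opening a sustained sleep run, or None.

    The onset is the first epoch within the period that begins a run of at
    least ``onset_consecutive`` sleep-scored epochs. ``None`` marks the night
    invalid (excluded downstream).
    """
    if states is None:
        states = sleep_states(series.counts)
    i0 = series.index_of(period.start)
    i1 = series.index_of(period.end - pd.Timedelta(seconds=EPOCH_SECONDS)) + 1
    sub = np.asarray(states[i0:i1], bool)
    run = 0
    for k, s in enumerate(sub):
        run = run + 1 if s else 0
        if run == params.onset_consecutive:
            start_idx = i0 + k - params.onset_consecutive + 1
            onset = series.start_time + pd.Timedelta(seconds=start_idx * EPOCH_SECONDS)
            return SleepOnset(period.child_id, period.night_date, onset, method="sadeh")
    return None


def scores_frame(series: ActivitySeries) -> pd.DataFrame:
    """Exportable per-epoch scoring table: epoch_time, ps, state."""
    ps = sadeh_scores(series.counts)
    return pd.DataFrame(
        {
            "child_id": series.child_id,
            "epoch_time": series.times(),
            "ps": ps,
            "state": np.where(ps >= 0, "sleep", "wake"),
        }
    )
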