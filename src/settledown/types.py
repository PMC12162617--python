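"""Core domain containers shared across the pipeline.

All timestamps are timezone-naive local clock time (``pandas.Timestamp``).
Epochs are 60 s and half-open: epoch ``i`` of a series covers
``[start_time + 60*i s, start_time + 60*(i+1) s)``. A *night* is attributed
to the civil date on which the settling start falls, with starts between
midnight and 06:00 attributed to the previous date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd

EPOCH_SECONDS = 60

SS = "SS"
NSS = "NSS"
GROUPS = (SS, NSS)


class FormatError(ValueError):
    """A file violated the expected dialect (gap, duplicate, bad value)."""


class AssemblyError(ValueError):
    """Cohort pieces reference each other inconsistently."""


def night_date_of(ts: pd.Timestamp) -> date:
    """Civil date owning a settling start; 00:00-06:00 belongs to the prior day."""
    ts = pd.Timestamp(ts)
    if ts.hour < 6:
        return (ts - pd.Timedelta(days=1)).date()
    return ts.date()


@dataclass
class ActivitySeries:
    """Contiguous per-child sequence of 60-s vector-magnitude epochs."""

    child_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    axis_counts: Optional[np.ndarray] = None  # shape (3, n) when present
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError(f"epoch_seconds must be {EPOCH_SECONDS}")
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0) or np.any(~np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.axis_counts is not None:
            self.axis_counts = np.asarray(self.axis_counts, dtype=float)
            if self.axis_counts.shape != (3, len(self.counts)):
                raise ValueError("axis_counts must have shape (3, n_epochs)")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=EPOCH_SECONDS * len(self))

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="60s")

    def index_of(self, ts: pd.Timestamp) -> int:
        """Epoch index containing ``ts`` (floor to the epoch grid)."""
        delta = (pd.Timestamp(ts) - self.start_time).total_seconds()
        idx = int(np.floor(delta / EPOCH_SECONDS))
        if idx < 0 or idx >= len(self):
            raise IndexError(f"{ts} outside series span of {self.child_id}")
        return idx

    def slice_counts(self, start: pd.Timestamp, end: pd.Timestamp) -> np.ndarray:
        """Counts for epochs in the half-open interval [start, end)."""
        i = self.index_of(start)
        j = i + int(round((pd.Timestamp(end) - pd.Timestamp(start)).total_seconds() / EPOCH_SECONDS))
        if j > len(self):
            raise IndexError("slice extends past end of series")
        return self.counts[i:j]


@dataclass
class DiaryEntry:
    """One caregiver diary night: settling start and (optional) perceived onset."""

    child_id: str
    night_date: date
    settling_start: pd.Timestamp
    reported_sleep_onset: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        self.settling_start = pd.Timestamp(self.settling_start)
        if self.reported_sleep_onset is not None:
            self.reported_sleep_onset = pd.Timestamp(self.reported_sleep_onset)
            if not self.settling_start < self.reported_sleep_onset:
                raise ValueError(
                    f"settling_start must precede reported_sleep_onset "
                    f"({self.child_id} {self.night_date})"
                )
        if night_date_of(self.settling_start) != self.night_date:
            raise ValueError(
                f"night_date {self.night_date} does not own settling_start "
                f"{self.settling_start} ({self.child_id})"
            )


@dataclass
class ChildRecord:
    child_id: str
    group: str
    age_years: float
    sex: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}; expected M or F")


@dataclass
class RestPeriod:
    """Nightly rest (in-bed) interval delimited from scored epochs."""

    child_id: str
    night_date: Optional[date]
    start: pd.Timestamp
    end: pd.Timestamp
    source: str = "algorithm"  # or "diary_adjusted"

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if not self.start < self.end:
            raise ValueError("rest period start must precede end")


@dataclass
class SleepOnset:
    child_id: str
    night_date: Optional[date]
    onset: pd.Timestamp
    method: str = "sadeh"  # or "fallback"

    def __post_init__(self) -> None:
        self.onset = pd.Timestamp(self.onset)


@dataclass
class SettlingPeriod:
    """Per-night settling-down window with its epoch counts."""

    child_id: str
    night_date: date
    group: Optional[str]
    start: pd.Timestamp
    end: pd.Timestamp
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        self.counts = np.asarray(self.counts, dtype=float)
        n_min = int(round((self.end - self.start).total_seconds() / EPOCH_SECONDS))
        if len(self.counts) != n_min:
            raise ValueError(
                f"counts length {len(self.counts)} != window minutes {n_min}"
            )
        if n_min < 1:
            raise ValueError("settling period must span at least one epoch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration_min(self) -> int:
        return len(self.counts)


@dataclass
class CohortDataset:
    """Per-child bundle of activity series, diary entries and label record."""

    children: dict  # child_id -> ChildRecord
    series: dict  # child_id -> ActivitySeries
    diaries: dict  # child_id -> {night_date: DiaryEntry}

    def child_ids(self) -> list:
        return sorted(self.children)
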