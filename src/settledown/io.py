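"""Readers/writers for the epoch-activity, diary and label CSV dialects.

Dialects (header included, ISO-8601 local times, no timezone):

* epoch CSV:  ``timestamp,axis1,axis2,axis3,vector_magnitude`` (axis columns
  optional; minimal form is ``timestamp,vector_magnitude``)
* diary CSV:  ``child_id,night_date,settling_start,reported_sleep_onset``
  (empty ``reported_sleep_onset`` allowed)
* labels CSV: ``child_id,group,age_years,sex``

Epoch rows must be time-sorted, strictly contiguous at 60 s and non-negative;
violations raise :class:`~settledown.types.FormatError` naming the row.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from .types import (
    EPOCH_SECONDS,
    ActivitySeries,
    AssemblyError,
    ChildRecord,
    CohortDataset,
    DiaryEntry,
    FormatError,
    night_date_of,
)

log = logging.getLogger(__name__)


def read_epoch_csv(path, child_id: str | None = None) -> ActivitySeries:
    """Parse an ActiLife-style epoch export into a validated series.

    ``child_id`` defaults to the file stem.
    """
    df = pd.read_csv(path, comment="#")
    if "timestamp" not in df.columns or "vector_magnitude" not in df.columns:
        raise FormatError(f"{path}: need columns timestamp, vector_magnitude")
    if len(df) == 0:
        raise FormatError(f"{path}: empty epoch file")
    try:
        times = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    deltas = times.diff().dt.total_seconds().to_numpy()
    for i in range(1, len(times)):
        if deltas[i] == 0:
            raise FormatError(f"{path}: duplicate timestamp at row {i + 1}")
        if deltas[i] != EPOCH_SECONDS:
            raise FormatError(
                f"{path}: non-contiguous epoch at row {i + 1} "
                f"(gap of {deltas[i]:.0f} s, expected {EPOCH_SECONDS} s)"
            )
    counts = pd.to_numeric(df["vector_magnitude"], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(counts)):
        row = int(np.flatnonzero(~np.isfinite(counts))[0]) + 1
        raise FormatError(f"{path}: non-numeric vector_magnitude at row {row}")
    if np.any(counts < 0):
        row = int(np.flatnonzero(counts < 0)[0]) + 1
        raise FormatError(f"{path}: negative count at row {row}")
    axis = None
    if {"axis1", "axis2", "axis3"}.issubset(df.columns):
        axis = df[["axis1", "axis2", "axis3"]].to_numpy(float).T
    if child_id is None:
        from pathlib import Path

        child_id = Path(path).stem
    return ActivitySeries(child_id=child_id, start_time=times.iloc[0], counts=counts, axis_counts=axis)


def write_epoch_csv(path, series: ActivitySeries, header_comment: str | None = None) -> None:
    data = {"timestamp": series.times().strftime("%Y-%m-%dT%H:%M:%S")}
    if series.axis_counts is not None:
        for i in range(3):
            data[f"axis{i + 1}"] = series.axis_counts[i]
    data["vector_magnitude"] = series.counts
    _write_csv(pd.DataFrame(data), path, header_comment)


def read_diary_csv(path) -> List[DiaryEntry]:
    df = pd.read_csv(path, comment="#", dtype=str)
    need = {"child_id", "night_date", "settling_start", "reported_sleep_onset"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    entries = []
    for i, row in df.iterrows():
        try:
            onset = row["reported_sleep_onset"]
            onset_ts = pd.Timestamp(onset) if isinstance(onset, str) and onset else None
            entries.append(
                DiaryEntry(
                    child_id=row["child_id"],
                    night_date=pd.Timestamp(row["night_date"]).date(),
                    settling_start=pd.Timestamp(row["settling_start"]),
                    reported_sleep_onset=onset_ts,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: bad diary row {i + 2}: {exc}") from exc
    return entries


def write_diary_csv(path, entries: Iterable[DiaryEntry], header_comment: str | None = None) -> None:
    rows = [
        {
            "child_id": e.child_id,
            "night_date": e.night_date.isoformat(),
            "settling_start": e.settling_start.strftime("%Y-%m-%dT%H:%M:%S"),
            "reported_sleep_onset": (
                e.reported_sleep_onset.strftime("%Y-%m-%dT%H:%M:%S")
                if e.reported_sleep_onset is not None
                else ""
            ),
        }
        for e in entries
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def read_labels_csv(path) -> List[ChildRecord]:
    df = pd.read_csv(path, comment="#", dtype={"child_id": str, "group": str, "sex": str})
    need = {"child_id", "group", "age_years", "sex"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ChildRecord(
                    child_id=row["child_id"],
                    group=row["group"],
                    age_years=float(row["age_years"]),
                    sex=row["sex"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad label row {i + 2}: {exc}") from exc
    return records


def write_labels_csv(path, records: Iterable[ChildRecord], header_comment: str | None = None) -> None:
    rows = [
        {"child_id": r.child_id, "group": r.group, "age_years": r.age_years, "sex": r.sex}
        for r in records
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def assemble_dataset(
    series: Iterable[ActivitySeries],
    diaries: Iterable[DiaryEntry],
    labels: Iterable[ChildRecord],
) -> CohortDataset:
    """Bundle the three record streams per child; every id must be labelled."""
    children = {r.child_id: r for r in labels}
    series_map: Dict[str, ActivitySeries] = {}
    for s in series:
        if s.child_id not in children:
            raise AssemblyError(f"activity series for unlabelled child {s.child_id!r}")
        if s.child_id in series_map:
            raise AssemblyError(f"duplicate activity series for child {s.child_id!r}")
        series_map[s.child_id] = s
    diary_map: Dict[str, dict] = {cid: {} for cid in children}
    for d in diaries:
        if d.child_id not in children:
            raise AssemblyError(f"diary entry for unlabelled child {d.child_id!r}")
        if d.night_date in diary_map[d.child_id]:
            raise AssemblyError(
                f"duplicate diary night {d.night_date} for child {d.child_id!r}"
            )
        diary_map[d.child_id][d.night_date] = d
    for cid in sorted(series_map):
        log.info("assembled child %s: %d diary nights, %d epochs", cid, len(diary_map[cid]), len(series_map[cid]))
    return CohortDataset(children=children, series=series_map, diaries=diary_map)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
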