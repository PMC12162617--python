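"""Shared fixtures: small toy objects plus the session-scoped calibrated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from settledown import (
    ActivitySeries,
    CohortConfig,
    WindowSpec,
    apply_inclusion,
    assemble_dataset,
    build_feature_table,
    generate_cohort,
)
from settledown.pipeline import extract_cohort_periods


@pytest.fixture(scope="session")
def calibrated_cohort():
    """The reference study-conditions cohort: 17 SS / 18 NSS, 13 nights, seed 1."""
    return generate_cohort(CohortConfig(nights_range=(13, 13), seed=1))


@pytest.fixture(scope="session")
def calibrated_periods(calibrated_cohort):
    co = calibrated_cohort
    dataset = assemble_dataset(co.series, co.diaries, co.records())
    periods, rejections, nights = extract_cohort_periods(dataset)
    included, _ = apply_inclusion(periods)
    return included, rejections, nights, dataset


@pytest.fixture(scope="session")
def calibrated_table(calibrated_periods):
    included, _, _, _ = calibrated_periods
    return build_feature_table(included, WindowSpec(window_min=11, stride_min=1))


@pytest.fixture
def tiny_series():
    """Three-minute series starting 22:00 with counts 0, 100, 50."""
    return ActivitySeries(
        child_id="c1",
        start_time=pd.Timestamp("2021-10-01 22:00:00"),
        counts=np.array([0.0, 100.0, 50.0]),
    )


def make_series(counts, child_id="c1", start="2021-10-01 20:00:00"):
    return ActivitySeries(
        child_id=child_id, start_time=pd.Timestamp(start),
        counts=np.asarray(counts, dtype=float),
    )
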