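"""End-to-end orchestration: generate/ingest -> score -> extract -> featurize
-> sweep/classify -> importance & statistics, with persisted CSV artifacts.

Every stage artifact is a plain CSV carrying a ``# config=<hash> seed=<n>``
provenance comment; a JSON manifest indexes them. Identical config + seed
reproduces every table byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import classify, features, io, settling, sleep, stats, synthetic
from .types import NSS, SS, ActivitySeries, CohortDataset, DiaryEntry, SettlingPeriod, night_date_of

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of data_dir / synthetic."""

    data_dir: Optional[str] = None
    synthetic: Optional[synthetic.CohortConfig] = None
    scoring: sleep.ScoringParams = field(default_factory=sleep.ScoringParams)
    extraction_mode: str = "diary"  # or "fixed_offset"
    min_duration: int = 3
    min_nights: int = 4
    window: features.WindowSpec = field(default_factory=features.WindowSpec)
    sweep_grid: List[Tuple[int, int]] = field(
        default_factory=lambda: list(classify.DEFAULT_SWEEP_GRID)
    )
    run_sweep: bool = False
    grid_search: bool = False
    rf: classify.RFParams = field(default_factory=classify.RFParams)
    k_folds: int = 10
    fold_mode: str = "paper"
    n_importance_repeats: int = 10
    seed: int = 0
    out_dir: str = "run_out"

    def __post_init__(self) -> None:
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of data_dir / synthetic config")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["start_date"] = self.synthetic.start_date.isoformat()
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash identifies the run, not where it lands
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        syn = dict(raw["synthetic"])
        if "group_params" in syn:
            syn["group_params"] = {
                g: synthetic.GroupParams(**p) for g, p in syn["group_params"].items()
            }
        if "nights_range" in syn:
            syn["nights_range"] = tuple(syn["nights_range"])
        if "start_date" in syn:
            syn["start_date"] = pd.Timestamp(syn["start_date"]).date()
        kwargs["synthetic"] = synthetic.CohortConfig(**syn)
    if "sleep_scoring" in raw:
        kwargs["scoring"] = sleep.ScoringParams(**raw["sleep_scoring"])
    if "window" in raw:
        kwargs["window"] = features.WindowSpec(**raw["window"])
    if "rf" in raw:
        kwargs["rf"] = classify.RFParams(**raw["rf"])
    if "sweep_grid" in raw:
        kwargs["sweep_grid"] = [tuple(cell) for cell in raw["sweep_grid"]]
    for key in (
        "data_dir", "extraction_mode", "min_duration", "min_nights", "run_sweep",
        "grid_search", "k_folds", "fold_mode", "n_importance_repeats", "seed", "out_dir",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def load_dataset(data_dir) -> CohortDataset:
    """Assemble a cohort from a directory of epoch_<id>.csv + diary/labels."""
    d = Path(data_dir)
    labels = io.read_labels_csv(d / "labels.csv")
    diaries = io.read_diary_csv(d / "diary.csv")
    series = [
        io.read_epoch_csv(f, child_id=f.stem.removeprefix("epoch_"))
        for f in sorted(d.glob("epoch_*.csv"))
    ]
    return io.assemble_dataset(series, diaries, labels)


def write_cohort(cohort: synthetic.SyntheticCohort, out_dir, tag: str = "synthetic") -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    io.write_labels_csv(d / "labels.csv", cohort.records(), header_comment=tag)
    io.write_diary_csv(d / "diary.csv", cohort.diaries, header_comment=tag)
    for s in cohort.series:
        io.write_epoch_csv(d / f"epoch_{s.child_id}.csv", s, header_comment=tag)
    (d / "truth.json").write_text(cohort.truth_json())


def extract_cohort_periods(
    dataset: CohortDataset,
    scoring: sleep.ScoringParams = sleep.ScoringParams(),
    mode: str = "diary",
    min_duration: int = 3,
) -> Tuple[List[SettlingPeriod], List[dict], pd.DataFrame]:
    """Score every child, delimit nightly rest, and cut settling windows.

    Returns (settling periods, rejection log, per-night table). One rest
    period is kept per night (the longest whose start falls between that
    civil day's noon and the next); the diary onset adjusts its start under
    the 30-minute rule before the Sadeh onset search.
    """
    periods: List[SettlingPeriod] = []
    rejections: List[dict] = []
    night_rows: List[dict] = []
    for cid in dataset.child_ids():
        if cid not in dataset.series:
            continue
        series = dataset.series[cid]
        group = dataset.children[cid].group
        states = sleep.sleep_states(series.counts)
        rest = sleep.detect_rest_periods(series, scoring, states=states)
        diary_by_night: Dict[object, DiaryEntry] = dataset.diaries.get(cid, {})

        by_night: Dict[object, list] = {}
        for rp in rest:
            by_night.setdefault(night_date_of(rp.start), []).append(rp)
        for nd in sorted(by_night):
            cands = by_night[nd]
            cands.sort(key=lambda r: (-(r.end - r.start).total_seconds(), r.start))
            rp = cands[0]
            rp = sleep.RestPeriod(cid, nd, rp.start, rp.end, rp.source)
            diary = diary_by_night.get(nd)
            if diary is not None:
                rp = sleep.reconcile_with_diary(rp, diary)
            onset = sleep.sleep_onset(rp, series, scoring, states=states)
            if onset is None:
                rejections.append(
                    {"child_id": cid, "night_date": nd, "reason": "onset_not_found"}
                )
                continue
            onset.night_date = nd
            result = settling.extract_settling(
                series, diary, onset, mode=mode, min_duration=min_duration, group=group
            )
            if isinstance(result, settling.Rejection):
                rejections.append(dataclasses.asdict(result))
            else:
                periods.append(result)
            night_rows.append(
                {
                    "child_id": cid,
                    "night_date": nd,
                    "rest_start": rp.start,
                    "rest_end": rp.end,
                    "rest_source": rp.source,
                    "sleep_onset": onset.onset,
                    "valid": not isinstance(result, settling.Rejection),
                }
            )
    return periods, rejections, pd.DataFrame(night_rows)


@dataclass
class RunReport:
    config: PipelineConfig
    n_subjects: Dict[str, int]
    n_nights: int
    exclusions: List[dict]
    duration_summaries: Dict[str, settling.DurationSummary]
    hedges_g_subject: float
    hedges_g_pooled: float
    sweep: Optional[classify.SweepReport]
    cv: classify.CVReport
    importance: pd.DataFrame
    aggregates: pd.DataFrame
    group_tests: pd.DataFrame
    regressions: pd.DataFrame

    def to_markdown(self) -> str:
        ss, nss = self.duration_summaries[SS], self.duration_summaries[NSS]
        lines = [
            "# Settling-down pipeline run report",
            "",
            f"- config hash: `{self.config.config_hash()}`  seed: {self.config.seed}",
            f"- subjects included: {self.n_subjects}  nights: {self.n_nights}  "
            f"exclusions: {len(self.exclusions)}",
            "",
            "## Settling durations (minutes)",
            "",
            f"- SS:  subject-level mean {ss.mean_min:.2f} (SD {ss.sd_min:.2f}, "
            f"n={ss.n_subjects}); pooled-over-nights {ss.pooled_mean_min:.2f} "
            f"(SD {ss.pooled_sd_min:.2f}, {ss.n_nights} nights)",
            f"- NSS: subject-level mean {nss.mean_min:.2f} (SD {nss.sd_min:.2f}, "
            f"n={nss.n_subjects}); pooled-over-nights {nss.pooled_mean_min:.2f} "
            f"(SD {nss.pooled_sd_min:.2f}, {nss.n_nights} nights)",
            f"- Hedges' g (subject-level) = {self.hedges_g_subject:.3f}; "
            f"(pooled) = {self.hedges_g_pooled:.3f}",
            "",
            "## Cross-validated classification "
            f"(window {self.cv.spec.window_min}/{self.cv.spec.stride_min}, "
            f"{self.config.k_folds}-fold, mode={self.cv.mode})",
            "",
            self.cv.folds.to_markdown(index=False),
            "",
            f"**Averages**: accuracy {self.cv.accuracy:.3f}, sensitivity "
            f"{self.cv.sensitivity:.3f}, specificity {self.cv.specificity:.3f}, "
            f"AUC {self.cv.auc:.3f}",
            "",
        ]
        if self.sweep is not None:
            lines += ["## Window/stride sweep (mean AUC)", "",
                      self.sweep.rows.to_markdown(index=False),
                      f"\nbest cell: {self.sweep.best}", ""]
        lines += [
            "## Permutation feature importance (AUC decrease)", "",
            self.importance.to_markdown(index=False), "",
            "## Subject-aggregate group tests", "",
            self.group_tests.to_markdown(index=False), "",
            "## Post-hoc standardized regressions", "",
            self.regressions.round(4).to_markdown(), "",
        ]
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and persist artifacts under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config={config.config_hash()} seed={config.seed}"

    if config.synthetic is not None:
        cohort = synthetic.generate_cohort(config.synthetic)
        dataset = io.assemble_dataset(cohort.series, cohort.diaries, cohort.records())
        (out / "truth.json").write_text(cohort.truth_json())
    else:
        dataset = load_dataset(config.data_dir)

    periods, rejections, nights = extract_cohort_periods(
        dataset, config.scoring, config.extraction_mode, config.min_duration
    )
    included, excl = settling.apply_inclusion(periods, config.min_nights)
    exclusions = rejections + excl
    if not included:
        raise RuntimeError("extraction stage produced no includable settling periods")
    for p in included:
        p.group = dataset.children[p.child_id].group

    groups_present = {p.group for p in included}
    if groups_present != {SS, NSS}:
        raise RuntimeError(
            f"classification stage needs both groups; found {sorted(groups_present)}"
        )

    summaries = {g: settling.duration_summary(included, g) for g in (SS, NSS)}
    g_subj = settling.hedges_g(
        summaries[SS].mean_min, summaries[SS].sd_min, summaries[SS].n_subjects,
        summaries[NSS].mean_min, summaries[NSS].sd_min, summaries[NSS].n_subjects,
    )
    g_pool = settling.hedges_g(
        summaries[SS].pooled_mean_min, summaries[SS].pooled_sd_min, summaries[SS].n_nights,
        summaries[NSS].pooled_mean_min, summaries[NSS].pooled_sd_min, summaries[NSS].n_nights,
    )

    table = features.build_feature_table(included, config.window)

    rf = config.rf
    if config.grid_search:
        train, _ = classify.split_4to1(table, seed=config.seed)
        rf = classify.grid_search_params(train, seed=config.seed)

    sweep_report = None
    if config.run_sweep:
        sweep_report = classify.sweep_window_stride(
            included, config.sweep_grid, rf, config.k_folds, config.fold_mode, config.seed
        )

    cv = classify.run_cv(
        table, rf, k=config.k_folds, mode=config.fold_mode, seed=config.seed,
        spec=config.window,
    )
    importance = stats.permutation_importance(
        table, rf, n_repeats=config.n_importance_repeats, seed=config.seed
    )
    records = list(dataset.children.values())
    aggregates = stats.subject_aggregates(table, included, records)
    gtests = stats.group_tests(aggregates)
    regs = stats.regression_table(aggregates)

    report = RunReport(
        config=config,
        n_subjects={
            g: sum(1 for c in {p.child_id for p in included}
                   if dataset.children[c].group == g)
            for g in (SS, NSS)
        },
        n_nights=len(included),
        exclusions=exclusions,
        duration_summaries=summaries,
        hedges_g_subject=g_subj,
        hedges_g_pooled=g_pool,
        sweep=sweep_report,
        cv=cv,
        importance=importance,
        aggregates=aggregates,
        group_tests=gtests,
        regressions=regs,
    )
    _persist(report, included, table, nights, out, tag)
    return report


def _persist(report: RunReport, included: List[SettlingPeriod], table: pd.DataFrame,
             nights: pd.DataFrame, out: Path, tag: str) -> None:
    def dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        with open(out / name, "w", newline="") as fh:
            fh.write(f"# {tag}\n")
            df.to_csv(fh, index=index)

    dump(nights, "nights.csv")
    dump(settling.periods_frame(included), "settling_periods.csv")
    dump(table, "features.csv")
    dump(report.cv.folds, "cv_report.csv")
    if report.sweep is not None:
        dump(report.sweep.rows, "sweep.csv")
    dump(report.importance, "importance.csv")
    dump(report.aggregates, "subject_aggregates.csv")
    dump(report.group_tests, "group_tests.csv")
    dump(report.regressions, "regressions.csv", index=True)
    if report.exclusions:
        dump(pd.DataFrame(report.exclusions), "exclusions.csv")
    manifest = {
        "provenance": tag,
        "config": report.config.to_dict(),
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
        "summary": report.cv.summary(),
        "hedges_g_subject": report.hedges_g_subject,
        "hedges_g_pooled": report.hedges_g_pooled,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "report.md").write_text(report.to_markdown())
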