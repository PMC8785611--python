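"""Pipeline orchestration: trials -> metric table -> statistics -> report.

Composes the per-trial analyses (static sway, perturbation responses, step
detection, dual-task and counting costs) into a tidy
:class:`~posturolab.group_stats.CohortTable` and a group-comparison
report. The analysis is fail-soft per trial — a corrupt file is logged and
skipped, mirroring the per-perturbation discard practice of the protocol —
and fail-fast on cohort-level schema problems. Every analysis parameter is
echoed into the output directory for reproducibility.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dualtask, perturbation_response as pr, step_analysis as sa
from .errors import PosturolabError
from .group_stats import CohortTable, CohortReport, build_report, write_report
from .signal_io import TrialRecord, read_trial
from .static_sway import sway_metrics

log = logging.getLogger("posturolab")


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, with protocol defaults."""

    sway_min_duration_s: float = 30.0
    sway_window_s: float = 20.0  # centred analysis window of a sway trial
    envelope_lowpass_hz: float = 10.0
    band_k: float = 2.0  # steady-state band = mean + band_k * SD
    dwell_s: float = 0.5  # required time inside the band
    pre_window_s: float = 5.0
    post_window_s: float = 4.5
    force_threshold_n: float = 5.0
    min_step_duration_s: float = 0.05
    merge_gap_s: float = 0.03
    min_landing_offset_mm: float = 20.0
    offset_window_s: float = 0.1
    outlier_k: float = 1.5
    quartile_method: str = "linear"
    exact_max_n: int = 16
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PosturolabError(f"unknown analysis options: {sorted(unknown)}")
        return cls(**data)


def analyze_sway_trial(trial: TrialRecord, cfg: AnalysisConfig) -> list:
    """Rows (dicts) for one quiet-stance trial."""
    m = sway_metrics(trial, min_duration_s=cfg.sway_min_duration_s)
    base = dict(participant_id=trial.participant_id, group=trial.group,
                condition=trial.condition)
    return [
        dict(base, metric="ellipse_area", value=m.ellipse_area),
        dict(base, metric="mean_velocity", value=m.mean_velocity),
    ]


def analyze_perturbation_trial(trial: TrialRecord,
                               cfg: AnalysisConfig) -> list:
    """Per-event rows for one perturbation trial.

    Censored recoveries (envelope never back in the band within the post
    window) and truncated or off-plate segments are flagged discarded so
    they are excluded from statistics but still counted.
    """
    task = trial.condition.split("_", 1)[1] if "_" in trial.condition \
        else trial.condition
    condition = f"PERT_{task}"
    base = dict(participant_id=trial.participant_id, group=trial.group,
                condition=condition)
    rows = []
    for event in trial.events:
        seg = pr.segment_perturbation(
            trial, event, pre_s=cfg.pre_window_s, post_s=cfg.post_window_s,
            envelope_lowpass_hz=cfg.envelope_lowpass_hz)
        steps = sa.analyze_steps(
            trial.left, trial.right,
            window=(event.onset_s, event.onset_s + cfg.post_window_s),
            force_threshold_n=cfg.force_threshold_n,
            min_duration_s=cfg.min_step_duration_s,
            merge_gap_s=cfg.merge_gap_s,
            min_offset_mm=cfg.min_landing_offset_mm,
            offset_window_s=cfg.offset_window_s)
        metrics = pr.response_metrics(seg, steps=steps, band_k=cfg.band_k,
                                      dwell_s=cfg.dwell_s)
        discarded = metrics.discarded or metrics.censored
        note = metrics.discard_reason or ("censored" if metrics.censored
                                          else "")
        ev = dict(base, ptype=event.ptype, discarded=discarded, note=note)
        rows.append(dict(ev, metric="recovery_time",
                         value=metrics.recovery_time))
        rows.append(dict(ev, metric="cop_max", value=metrics.cop_max))
        rows.append(dict(ev, metric="mean_recovery_velocity",
                         value=metrics.mean_recovery_velocity))
        rows.append(dict(ev, metric="n_steps", value=metrics.n_steps))
        rows.append(dict(ev, metric="step_response",
                         value=float(metrics.n_steps > 0)))
        if metrics.n_steps > 0:
            rows.append(dict(ev, metric="step_total_displacement",
                             value=metrics.step_total_displacement))
        if not seg.discarded:
            prior = pr.pre_perturbation_sway(seg)
            pev = dict(base, ptype=event.ptype)
            rows.append(dict(pev, metric="prior_ellipse_area",
                             value=prior.ellipse_area))
            rows.append(dict(pev, metric="prior_mean_velocity",
                             value=prior.mean_velocity))
    return rows


def dtc_rows(table: CohortTable) -> list:
    """Balance dual-task-cost rows derived from the sway metric rows."""
    df = table.valid()
    sway = df[df["metric"].isin(["ellipse_area", "mean_velocity"])]
    short = {"ellipse_area": "area", "mean_velocity": "vel"}
    rows = []
    piv = sway.pivot_table(index=["participant_id", "group"],
                           columns=["metric", "condition"], values="value")
    for (pid, group), rec in piv.iterrows():
        for metric in ("ellipse_area", "mean_velocity"):
            for eyes in ("EO", "EC"):
                try:
                    single = rec[(metric, f"{eyes}_NoDT")]
                    dual = rec[(metric, f"{eyes}_DT")]
                except KeyError:
                    continue
                if np.isnan(single) or np.isnan(dual) or single == 0:
                    continue
                rows.append(dict(
                    participant_id=pid, group=group, condition="all",
                    metric=f"dtc_{short[metric]}_{eyes}",
                    value=dualtask.dtc(single, dual)))
    return rows


def counting_rows(counting: list) -> list:
    """Counting-rate and cognitive dual-task-cost rows.

    ``counting`` holds dicts with participant_id, group, context and a
    :class:`~posturolab.dualtask.CountingRecord` (several sway/perturbation
    records per participant are pooled by total counts over total time,
    matching rate semantics when the timed period varies).
    """
    pooled: dict = {}
    for item in counting:
        key = (item["participant_id"], item["group"], item["context"])
        rec = item["record"]
        counts, dur = pooled.get(key, (0, 0.0))
        pooled[key] = (counts + rec.n_correct_counts, dur + rec.duration_s)
    rates: dict = {}
    rows = []
    for (pid, group, context), (counts, dur) in pooled.items():
        rate = dualtask.counting_rate(
            dualtask.CountingRecord(counts, dur, context))
        rates.setdefault((pid, group), {})[context] = rate
        rows.append(dict(participant_id=pid, group=group, condition=context,
                         metric="counting_rate", value=rate))
    for (pid, group), ctx in rates.items():
        if {"reference", "sway", "perturbation"} <= set(ctx) \
                and ctx["reference"] > 0 and ctx["sway"] > 0:
            for name, value in dualtask.cognitive_dtc_set(
                    ctx["reference"], ctx["sway"],
                    ctx["perturbation"]).items():
                rows.append(dict(participant_id=pid, group=group,
                                 condition="all", metric=name, value=value))
    return rows


def analyze_trials(trials, cfg: AnalysisConfig | None = None,
                   counting: list | None = None,
                   fail_soft: bool = True) -> CohortTable:
    """Build the cohort metric table from in-memory trials."""
    cfg = cfg or AnalysisConfig()
    table = CohortTable()
    n_failed = 0
    for trial in trials:
        try:
            if trial.trial_kind == "sway":
                rows = analyze_sway_trial(trial, cfg)
            else:
                rows = analyze_perturbation_trial(trial, cfg)
        except PosturolabError as exc:
            if not fail_soft:
                raise
            n_failed += 1
            log.warning("trial %s/%s discarded: %s", trial.participant_id,
                        trial.condition, exc)
            continue
        table.extend(rows)
    table.extend(dtc_rows(table))
    if counting:
        table.extend(counting_rows(counting))
    if n_failed:
        log.warning("%d trial(s) discarded during analysis", n_failed)
    return table


def analyze_cohort(cohort, cfg: AnalysisConfig | None = None) -> CohortTable:
    """Analyze a :class:`~posturolab.synthetic_cohort.SyntheticCohort`."""
    return analyze_trials(cohort.trials, cfg=cfg, counting=cohort.counting)


def load_trials(input_dir, fail_soft: bool = True) -> list:
    """Read every trial CSV (with optional ``*_events.csv``) in a directory."""
    input_dir = Path(input_dir)
    trials = []
    paths = sorted(p for p in input_dir.glob("*.csv")
                   if not p.name.endswith("_events.csv")
                   and p.name != "counting.csv")
    if not paths:
        raise PosturolabError(f"no trial CSV files found in {input_dir}")
    for path in paths:
        events = path.with_name(path.stem + "_events.csv")
        try:
            trials.append(read_trial(
                path, events_path=events if events.exists() else None))
        except (PosturolabError, ValueError) as exc:
            if not fail_soft:
                raise
            log.warning("skipping %s: %s", path.name, exc)
    return trials


def load_counting(input_dir) -> list:
    """Read the cohort counting CSV, if present."""
    path = Path(input_dir) / "counting.csv"
    if not path.exists():
        return []
    import pandas as pd

    df = pd.read_csv(path)
    return [dict(participant_id=str(r.participant_id), group=str(r.group),
                 context=str(r.context),
                 record=dualtask.CountingRecord(
                     int(r.n_correct_counts), float(r.duration_s),
                     str(r.context)))
            for r in df.itertuples(index=False)]


def run_analysis(input_dir, cfg: AnalysisConfig | None = None,
                 out_dir=None) -> tuple:
    """Full directory-to-report run; returns (CohortTable, CohortReport).

    When ``out_dir`` is given, writes ``cohort_table.csv``, the report in
    CSV/JSON/markdown forms, and an ``analysis_config.yaml`` echo of every
    parameter used.
    """
    cfg = cfg or AnalysisConfig()
    trials = load_trials(input_dir)
    counting = load_counting(input_dir)
    table = analyze_trials(trials, cfg=cfg, counting=counting)
    report = build_report(table, outlier_k=cfg.outlier_k,
                          exact_max_n=cfg.exact_max_n)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv")
        write_report(report, out)
        cfg.to_yaml(out / "analysis_config.yaml")
    return table, report
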