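"""End-to-end orchestration: read → segment → validate → aggregate → metrics
→ statistics → report.

:func:`analyze` is the in-memory core used by library callers and tests;
:func:`run_pipeline` wraps it with file I/O, stage outputs and a
machine-readable ``report.json`` (input hashes, configuration echo, stage
counts, all statistics).  Every protocol threshold is configurable but
defaults to the standard protocol: 3-day gap rule, 900-second minimum
session, 3-hour resume window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from . import bouts as bouts_mod
from . import focal as focal_mod
from . import metrics as metrics_mod
from . import stats as stats_mod
from .ethogram import EthogramCatalog, load_ethogram
from .observations import (
    FocalEvent,
    FocalSessionHeader,
    Individual,
    ScanRecord,
    read_focal_log,
    read_roster,
    read_scan_log,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the literal protocol."""

    roster_path: str = "roster.csv"
    scans_path: str = "scans.csv"
    focal_sessions_path: str = "focal_sessions.csv"
    focal_events_path: str = "focal_events.csv"
    ethogram: str = "default"
    gap_days: int = bouts_mod.DEFAULT_GAP_DAYS
    min_session_seconds: float = focal_mod.MIN_SESSION_SECONDS
    resume_hours: float = focal_mod.RESUME_WINDOW_HOURS
    variables: tuple[str, ...] = tuple(metrics_mod.STABILITY_VARIABLES)
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class AnalysisResult:
    bout_summaries: list
    activity: pd.DataFrame
    session_validity: list
    pair_summaries: list
    pair_metrics: list
    metrics_table: pd.DataFrame
    correlation: stats_mod.CorrelationMatrixResult | None
    demographics: dict
    access: dict | None
    group_comparisons: list
    recurrence: dict
    notices: list[str] = field(default_factory=list)


def analyze(
    roster: list[Individual],
    scans: list[ScanRecord],
    headers: list[FocalSessionHeader],
    events: list[FocalEvent],
    catalog: EthogramCatalog | None = None,
    gap_days: int = bouts_mod.DEFAULT_GAP_DAYS,
    min_session_seconds: float = focal_mod.MIN_SESSION_SECONDS,
    resume_hours: float = focal_mod.RESUME_WINDOW_HOURS,
    variables: tuple[str, ...] = tuple(metrics_mod.STABILITY_VARIABLES),
    seed: int = 0,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    catalog = catalog or load_ethogram("default")
    notices: list[str] = []

    retained = bouts_mod.attach_vd_contact_days(scans)
    bout_summaries = bouts_mod.segment_bouts(retained, gap_days=gap_days)
    ff_summaries = [s for s in bout_summaries if s.pair_type == "FF"]
    activity = bouts_mod.consort_activity(scans, roster, gap_days=gap_days)

    validity = focal_mod.validate_sessions(
        headers, min_seconds=min_session_seconds, resume_hours=resume_hours
    )
    pair_summaries = focal_mod.aggregate_pairs(
        headers, events, validity, ff_summaries, catalog
    )
    pair_metrics = [metrics_mod.compute_metrics(s) for s in pair_summaries]
    metrics_table = metrics_mod.metrics_frame(pair_metrics)

    correlation = None
    if len(metrics_table) >= 4:
        correlation = stats_mod.spearman_matrix(
            metrics_table, list(variables), seed=seed
        )
    else:
        notices.append(
            f"correlation matrix skipped: only {len(metrics_table)} pairs "
            "with focal metrics (need >= 4)"
        )

    demographics = stats_mod.demographic_summary(roster, activity)
    access = None
    if len(activity) >= 4:
        access = stats_mod.access_to_males(activity, seed=seed)
    else:
        notices.append("access-to-males correlations skipped: too few females")

    comparisons = []
    for grouping in ("age_class", "reproductive_status"):
        try:
            comparisons.extend(
                stats_mod.compare_groups(activity, roster, grouping)
            )
        except ValueError as exc:
            notices.append(f"group comparison {grouping} skipped: {exc}")

    return AnalysisResult(
        bout_summaries=bout_summaries,
        activity=activity,
        session_validity=validity,
        pair_summaries=pair_summaries,
        pair_metrics=pair_metrics,
        metrics_table=metrics_table,
        correlation=correlation,
        demographics=demographics,
        access=access,
        group_comparisons=comparisons,
        recurrence=bouts_mod.recurrence_summary(ff_summaries),
        notices=notices,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _clean(obj):
    """Make a report JSON-serializable (NaN → None, numpy → python)."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if hasattr(obj, "item"):
        return _clean(obj.item())
    return obj


def build_report(result: AnalysisResult, config: RunConfig,
                 input_hashes: dict[str, str]) -> dict:
    valid = [v for v in result.session_validity if v.valid]
    discarded: dict[str, int] = {}
    for v in result.session_validity:
        if not v.valid:
            discarded[v.reason] = discarded.get(v.reason, 0) + 1
    report = {
        "config": _clean(dataclasses.asdict(config)),
        "input_hashes": input_hashes,
        "counts": {
            "pairs_with_bouts": len(result.bout_summaries),
            "ff_pairs_with_bouts": sum(
                1 for s in result.bout_summaries if s.pair_type == "FF"
            ),
            "bouts": sum(s.recurrence_rate for s in result.bout_summaries),
            "sessions_total": len(result.session_validity),
            "sessions_valid": len(valid),
            "sessions_discarded": discarded,
            "pairs_analyzed": len(result.pair_summaries),
        },
        "demographics": _clean(result.demographics),
        "recurrence_rate": _clean(result.recurrence),
        "access_to_males": _clean(result.access),
        "group_comparisons": [
            _clean(dataclasses.asdict(g)) for g in result.group_comparisons
        ],
        "notices": list(result.notices),
    }
    if result.correlation is not None:
        corr = result.correlation
        report["correlations"] = {
            "variables": corr.variables,
            "rho": _clean(corr.rho.values.tolist()),
            "p_raw": _clean(corr.p_raw.values.tolist()),
            "p_adjusted": _clean(corr.p_adjusted.values.tolist()),
            "n_used": corr.n_used.values.tolist(),
            "significant_adj_05": [
                list(p) for p in corr.significant(0.05)
            ],
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline run; writes all stage outputs and report.json."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    catalog = load_ethogram(config.ethogram)
    roster = read_roster(config.roster_path)
    scans = read_scan_log(config.scans_path, roster)
    headers, events = read_focal_log(
        config.focal_sessions_path, config.focal_events_path, catalog, roster
    )
    input_hashes = {
        os.path.basename(p): _sha256(p)
        for p in (config.roster_path, config.scans_path,
                  config.focal_sessions_path, config.focal_events_path)
    }
    result = analyze(
        roster, scans, headers, events, catalog,
        gap_days=config.gap_days,
        min_session_seconds=config.min_session_seconds,
        resume_hours=config.resume_hours,
        variables=config.variables,
        seed=config.seed,
    )

    os.makedirs(config.out_dir, exist_ok=True)

    def _out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    bouts_mod.bouts_frame(result.bout_summaries).to_csv(_out("bouts.csv"),
                                                        index=False)
    bouts_mod.summary_frame(result.bout_summaries).to_csv(
        _out("pair_bout_summary.csv"), index=False
    )
    result.activity.to_csv(_out("activity.csv"), index=False)
    pd.DataFrame(
        [dataclasses.asdict(v) for v in result.session_validity]
    ).to_csv(_out("session_validity.csv"), index=False)
    result.metrics_table.to_csv(_out("pair_metrics.csv"), index=False)
    if result.correlation is not None:
        result.correlation.rho.to_csv(_out("correlation_matrix.csv"))
        result.correlation.p_adjusted.to_csv(_out("correlation_p_adjusted.csv"))
    rows = []
    for g in result.group_comparisons:
        rows.append(
            {
                "grouping": g.grouping, "response": g.response, "test": g.test,
                "statistic": g.statistic, "df": g.df, "p_raw": g.p_raw,
            }
        )
    pd.DataFrame(rows).to_csv(_out("group_comparisons.csv"), index=False)
    with open(_out("demographics.json"), "w", encoding="utf-8") as fh:
        json.dump(_clean(result.demographics), fh, indent=1)

    report = build_report(result, config, input_hashes)
    with open(_out("report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return report
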