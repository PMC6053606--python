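"""End-to-end orchestration: simulate -> cluster -> label -> features -> analyze -> predict.

`process_bundle` runs the analysis stages over an in-memory cohort;
`run_pipeline` drives everything from a config mapping and writes CSV/JSON
artifacts plus a manifest carrying the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date as _date
from pathlib import Path

import pandas as pd

from . import association, clustering, features as feat, labeling, prediction, synth
from .clustering import Gap, Stay, extract_stays
from .features import FeatureTable, build_feature_table
from .io import write_manifest
from .labeling import DayTimeline, LabeledTimeline, build_timeline, split_by_day
from .synth import CohortBundle, CohortConfig, EffectConfig, GapConfig, MapConfig, NoiseConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "ProcessedCohort", "process_bundle", "run_pipeline",
           "make_fixtures", "config_hash"]


@dataclass(frozen=True)
class PipelineParams:
    d_m: float = clustering.DEFAULT_D_M
    t_s: float = clustering.DEFAULT_T_S
    gap_detect_s: float = clustering.GAP_DETECT_S
    gap_removable_s: float = clustering.GAP_REMOVABLE_S
    match_radius_m: float = labeling.DEFAULT_MATCH_RADIUS_M


@dataclass
class ProcessedCohort:
    """All intermediate products of the analysis stages for one cohort."""

    bundle: CohortBundle
    stays: dict[str, list[Stay]]
    gaps: dict[str, list[Gap]]
    timelines: dict[str, LabeledTimeline]
    day_timelines: dict[str, list[DayTimeline]]
    table: FeatureTable

    @property
    def sias(self) -> dict[str, int]:
        return self.bundle.sias


def process_bundle(bundle: CohortBundle, params: PipelineParams | None = None) -> ProcessedCohort:
    """Run clustering, labeling and feature extraction over a cohort."""
    params = params or PipelineParams()
    stays_d, gaps_d, tls, days_d = {}, {}, {}, {}
    for pid, trace in bundle.traces.items():
        stays, gaps = extract_stays(
            trace, d=params.d_m, t=params.t_s,
            gap_detect_s=params.gap_detect_s, removable_s=params.gap_removable_s,
        )
        span = (int(trace.times[0]), int(trace.times[-1])) if len(trace) else None
        tl = build_timeline(pid, stays, gaps, bundle.place_map,
                            observed_span=span, match_radius_m=params.match_radius_m)
        stays_d[pid] = stays
        gaps_d[pid] = gaps
        tls[pid] = tl
        days_d[pid] = split_by_day(tl)
    table = build_feature_table(days_d)
    return ProcessedCohort(bundle, stays_d, gaps_d, tls, days_d, table)


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping (key order independent)."""
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


_REQUIRED_KEYS = ("n_participants", "n_days", "seed")


def cohort_config_from_dict(cfg: dict) -> CohortConfig:
    effects = cfg.get("effects", "default")
    if effects == "zero":
        eff = EffectConfig.zero()
    elif isinstance(effects, dict):
        eff = EffectConfig(**effects)
    else:
        eff = EffectConfig()
    noise = NoiseConfig(
        jitter_sigma_m=float(cfg.get("jitter_sigma_m", 10.0)),
        gaps=GapConfig(rate_per_day=float(cfg.get("gap_rate_per_day", 0.5))),
    )
    start = cfg.get("start_date", "2018-03-05")
    if isinstance(start, str):
        start = _date.fromisoformat(start)
    return CohortConfig(
        n_participants=int(cfg["n_participants"]),
        n_days=int(cfg["n_days"]),
        start_date=start,
        effects=eff,
        noise=noise,
        cutoff=int(cfg.get("cutoff", 34)),
    )


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full pipeline from a config mapping; write artifacts.

    Produces trace/stay/timeline/feature/analysis CSVs plus evaluation
    summaries and a manifest recording the config hash.
    """
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cc = cohort_config_from_dict(config)

    logger.info("simulate: n=%d days=%d", cc.n_participants, cc.n_days)
    bundle = generate_cohort(cc, seed)
    proc = process_bundle(bundle, PipelineParams(
        d_m=float(config.get("d_m", 60.0)), t_s=float(config.get("t_s", 600.0)),
    ))

    write_manifest(bundle.sias, out / "manifest.csv")
    _write_stays(proc, out / "stays.csv")
    _write_timelines(proc, out / "timelines.csv", out / "removed.csv")
    proc.table.features.to_csv(out / "features.csv")
    proc.table.minutes.to_csv(out / "minutes.csv")
    with open(out / "feature_schema.json", "w") as fh:
        json.dump({"version": 1, "columns": list(feat.FEATURE_NAMES)}, fh, indent=2)

    # association tables
    association.epoch_correlation_table(proc.table, proc.sias, "evening").to_csv(
        out / "correlations_evening.csv"
    )
    for day_type in ("weekday", "weekend"):
        try:
            tab = association.group_comparison(proc.table, proc.sias, day_type)
        except ValueError as e:  # e.g. one SIAS group empty in a tiny demo cohort
            logger.warning("group comparison (%s) skipped: %s", day_type, e)
            tab = pd.DataFrame()
        tab.to_csv(out / f"group_{day_type}.csv")
    association.transition_correlation_table(proc.table, proc.sias, filtered=False).to_csv(
        out / "transition_correlations.csv", index=False
    )
    ent = {
        dt: association.entropy_correlation(proc.table, proc.sias, dt)
        for dt in ("weekday", "weekend")
    }

    eval_summary = {}
    if config.get("predict", True):
        for task in ("regression", "classification"):
            rep = prediction.evaluate(
                proc.table.features, proc.sias, method=config.get("method", "om"),
                task=task, scheme=config.get("scheme", "fcv10"), seed=seed,
            )
            if task == "regression":
                eval_summary["rmse"] = rep.rmse
                eval_summary["rmse_sd"] = rep.rmse_sd
            else:
                eval_summary["accuracy"] = rep.accuracy
                eval_summary["f1"] = rep.f1
            rep.fold_metrics.to_csv(out / f"eval_{task}.csv", index=False)

    manifest = {
        "config": {k: str(v) for k, v in config.items()},
        "config_hash": config_hash(config),
        "n_participants": cc.n_participants,
        "n_days": cc.n_days,
        "entropy_correlation": ent,
        "evaluation": eval_summary,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _write_stays(proc: ProcessedCohort, path: Path) -> None:
    rows = []
    for pid, stays in proc.stays.items():
        for s in stays:
            rows.append(
                {"participant_id": pid, "start": s.start, "end": s.end,
                 "lat": round(s.lat, 7), "lon": round(s.lon, 7),
                 "occupied_s": s.occupied_s}
            )
    pd.DataFrame(rows, columns=["participant_id", "start", "end", "lat", "lon",
                                "occupied_s"]).to_csv(path, index=False)


def _write_timelines(proc: ProcessedCohort, path: Path, removed_path: Path) -> None:
    rows, removed = [], []
    for pid, days in proc.day_timelines.items():
        for day in days:
            for iv in day.intervals:
                rows.append(
                    {"participant_id": pid, "date": day.date.isoformat(),
                     "class": iv.cls, "start": iv.start, "end": iv.end,
                     "place_id": iv.place_id or ""}
                )
            for lo, hi in day.removed:
                removed.append(
                    {"participant_id": pid, "date": day.date.isoformat(),
                     "start": lo, "end": hi}
                )
    pd.DataFrame(rows, columns=["participant_id", "date", "class", "start",
                                "end", "place_id"]).to_csv(path, index=False)
    pd.DataFrame(removed, columns=["participant_id", "date", "start", "end"]).to_csv(
        removed_path, index=False
    )


def make_fixtures(seed: int = 7) -> ProcessedCohort:
    """A tiny deterministic cohort (3 participants, 2 days) for tests/docs."""
    cfg = CohortConfig(
        n_participants=3,
        n_days=2,
        noise=NoiseConfig(jitter_sigma_m=5.0, gaps=GapConfig.none()),
        map=MapConfig(n_houses=6),
    )
    return process_bundle(generate_cohort(cfg, seed))
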