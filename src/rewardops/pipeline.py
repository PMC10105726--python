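"""Reproducible simulate -> behaviour -> photometry -> stats pipeline.

Each stage reads its inputs from, and writes its outputs to, a fixed output
tree (events/, traces/, metrics/, phase_activity/, stats/, report/), so
stages can be toggled and resumed; a manifest (config hash, seed, file
checksums, exclusion counts, decisions) makes a completed run reproducible
bit-for-bit for fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, photometry, stats
from .config import CohortConfig, config_to_dict, save_config
from .io import (
    EventLog,
    PhotometryTrace,
    read_events,
    read_trace_h5,
    write_events,
    write_trace_csv,
    write_trace_h5,
)
from .simulate import Cohort, generate_cohort

__all__ = ["RunConfig", "Manifest", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "behavior", "photometry", "stats")


@dataclass
class RunConfig:
    """Pipeline run options."""

    cohort: CohortConfig
    outdir: Path
    stages: tuple[str, ...] = ALL_STAGES
    trace_format: str = "h5"  # "h5" | "csv"
    drlm_window: tuple[int, int] = (11, 20)
    pr_block: int = 5
    first_k: int = 20

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class Manifest:
    """Run record: checksums, exclusions and decisions per stage."""

    seed: int
    config_sha256: str
    stages: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)
    decisions: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_sha256": self.config_sha256,
            "stages": self.stages,
            "checksums": self.checksums,
            "exclusions": self.exclusions,
            "decisions": self.decisions,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: Manifest, outdir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)


def run_pipeline(run: RunConfig) -> Manifest:
    """Execute the configured stages and return the manifest (also written
    to ``report/manifest.json``)."""
    cfg = run.cohort
    cfg.validate()
    out = run.outdir
    for sub in ("events", "traces", "metrics", "phase_activity", "stats", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    cfg_json = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    manifest = Manifest(
        seed=cfg.seed,
        config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
        decisions={
            "iti_distribution": "uniform on [iti_min_s, iti_max_s]",
            "learning_ratio": "ratio of medians (per-trial mode also reported)",
            "sd_convention": "population SD (ddof=0) for SD0",
            "missing_within_cells": "subjects dropped listwise per ANOVA",
        },
    )
    save_config(cfg, out / "report" / "config.yaml")
    _register(manifest, out, out / "report" / "config.yaml")

    if "simulate" in run.stages:
        _stage_simulate(run, manifest)
        manifest.stages.append("simulate")
    if "behavior" in run.stages:
        _stage_behavior(run, manifest)
        manifest.stages.append("behavior")
    if "photometry" in run.stages:
        _stage_photometry(run, manifest)
        manifest.stages.append("photometry")
    if "stats" in run.stages:
        _stage_stats(run, manifest)
        manifest.stages.append("stats")

    (out / "report" / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True)
    )
    return manifest


def _stage_simulate(run: RunConfig, manifest: Manifest) -> None:
    logger.info("simulate: generating cohort (seed=%d)", run.cohort.seed)
    cohort = generate_cohort(run.cohort, photometry=True)
    out = run.outdir
    events_path = out / "events" / "events.csv"
    write_events(cohort.logs, events_path)
    written = [events_path]
    if run.trace_format == "h5":
        tpath = out / "traces" / "traces.h5"
        write_trace_h5(cohort.traces, tpath)
        written.append(tpath)
    else:
        for key, trace in cohort.traces.items():
            tpath = out / "traces" / (key.replace("/", "_") + ".csv")
            write_trace_csv(trace, tpath)
            written.append(tpath)
    _register(manifest, out, *written)


def _load_traces(run: RunConfig) -> dict[str, PhotometryTrace]:
    tdir = run.outdir / "traces"
    h5 = tdir / "traces.h5"
    if h5.exists():
        return read_trace_h5(h5)
    from .io import read_trace_csv

    out = {}
    for p in sorted(tdir.glob("*.csv")):
        mouse, session = p.stem.split("_", 1)
        out[f"{mouse}/{session}"] = read_trace_csv(p)
    return out


def _stage_behavior(run: RunConfig, manifest: Manifest) -> None:
    out = run.outdir
    logs = read_events(out / "events" / "events.csv")
    drlm = behavior.drlm_metrics_table(logs, first_k=run.first_k)
    rev = behavior.rev_metrics_table(logs, pr_block=run.pr_block)
    paths = []
    for name, df in (("metrics_drlm.csv", drlm), ("metrics_rev.csv", rev)):
        p = out / "metrics" / name
        df.to_csv(p, index=False)
        paths.append(p)
    _register(manifest, out, *paths)


def _stage_photometry(run: RunConfig, manifest: Manifest) -> None:
    out = run.outdir
    logs = read_events(out / "events" / "events.csv")
    traces = _load_traces(run)
    frames = []
    qc_counts = {"short_baseline": 0, "degenerate_baseline": 0, "short_phase": 0,
                 "truncated_phase": 0, "n_trials": 0, "missing_trace": 0}
    for log in logs:
        key = Cohort.trace_key(log)
        if key not in traces:
            qc_counts["missing_trace"] += 1
            continue
        df, qc = photometry.session_phase_activity(log, traces[key])
        frames.append(df)
        qc_counts["n_trials"] += qc.n_trials
        qc_counts["short_baseline"] += qc.short_baseline
        qc_counts["degenerate_baseline"] += qc.degenerate_baseline
        qc_counts["short_phase"] += sum(qc.short_phase.values())
        qc_counts["truncated_phase"] += sum(qc.truncated_phase.values())
    per_trial = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    p = out / "phase_activity" / "per_trial.csv"
    per_trial.to_csv(p, index=False)
    manifest.exclusions.update({f"photometry.{k}": v for k, v in qc_counts.items()})
    _register(manifest, out, p)


def _stage_stats(run: RunConfig, manifest: Manifest) -> None:
    out = run.outdir
    report: dict = {"anova": {}, "qc": {}}
    paths = []

    drlm = pd.read_csv(out / "metrics" / "metrics_drlm.csv")
    anova_rows = []
    for dv in ("pellets", "median_latency_s", "median_iti_interval_s", "learning_ratio"):
        spec = stats.AnovaSpec(dv=dv, subject="mouse_id", between="group", within=("test",))
        try:
            table = stats.mixed_anova(drlm, spec)
        except ValueError as err:
            report["qc"][f"drlm.{dv}_anova_skipped"] = str(err)
            continue
        table.insert(0, "dv", dv)
        anova_rows.append(table)
        report["anova"][f"drlm.{dv}"] = {
            r["effect"]: {"F": r["F"], "p": r["p"], "df1": r["df1"], "df2": r["df2"]}
            for r in table.to_dict("records")
        }
    p = out / "stats" / "anova_drlm_behavior.csv"
    (pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()).to_csv(
        p, index=False
    )
    paths.append(p)

    rev = pd.read_csv(out / "metrics" / "metrics_rev.csv")
    # analysed REV test: mean of tests >= 2 per mouse (test 1 is adjustment)
    analysed = rev[rev["test"] >= 2] if (rev["test"] >= 2).any() else rev
    per_mouse = analysed.groupby(["mouse_id", "group"], as_index=False).mean(
        numeric_only=True
    )
    trows = []
    for dv in ("total_operant", "pellets_earned", "final_ratio",
               "retrieval_latency_s", "post_reinforcement_pause_s"):
        groups = [g[dv].dropna().to_numpy() for _, g in per_mouse.groupby("group")]
        labels = [name for name, _ in per_mouse.groupby("group")]
        if len(groups) == 2 and all(len(g) > 1 for g in groups):
            from scipy import stats as sps

            t, pval = sps.ttest_ind(*groups)
            trows.append({"dv": dv, "groups": " vs ".join(map(str, labels)),
                          "t": float(t), "p": float(pval)})
    p = out / "stats" / "ttests_rev_behavior.csv"
    pd.DataFrame(trows).to_csv(p, index=False)
    paths.append(p)

    pa_path = out / "phase_activity" / "per_trial.csv"
    if pa_path.exists():
        per_trial = pd.read_csv(pa_path)
        # DS-on phase, responded trials 11-20, tests 1 and 3: group x test x interval
        agg = photometry.aggregate(
            per_trial, "ds_on", window=run.drlm_window, responded_only=True,
            tests=(1, 3) if set(per_trial["test"]) >= {1, 3} else None,
        )
        if not agg.empty and agg["test"].nunique() >= 2:
            long = photometry.activity_long(agg, "ds_on")
            spec = stats.AnovaSpec(
                dv="z", subject="mouse_id", between="group",
                within=("test", "interval"),
            )
            try:
                table = stats.mixed_anova(long, spec)
                p2 = out / "stats" / "anova_dson_photometry.csv"
                table.to_csv(p2, index=False)
                paths.append(p2)
                report["anova"]["photometry.ds_on"] = {
                    r["effect"]: {"F": r["F"], "p": r["p"]}
                    for r in table.to_dict("records")
                }
                report["qc"]["ds_on_dropped_subjects"] = table.attrs["n_dropped"]
            except ValueError as err:
                report["qc"]["ds_on_anova_skipped"] = str(err)
        # REV operant phase at PR 5 (tests >= 2 averaged): group x interval
        rev_pt = per_trial[per_trial["session_type"] == "REV"]
        if not rev_pt.empty:
            sel = rev_pt[rev_pt["test"] >= 2] if (rev_pt["test"] >= 2).any() else rev_pt
            agg_op = photometry.aggregate(
                sel, "operant", responded_only=True, pr_block=run.pr_block
            )
            if not agg_op.empty:
                per_mouse_op = agg_op.groupby(
                    ["mouse_id", "group"], as_index=False
                ).mean(numeric_only=True)
                per_mouse_op["test"] = 0  # tests averaged; single within factor
                long = photometry.activity_long(per_mouse_op, "operant")
                spec = stats.AnovaSpec(
                    dv="z", subject="mouse_id", between="group", within=("interval",)
                )
                try:
                    table = stats.mixed_anova(long, spec)
                    p3 = out / "stats" / "anova_operant_pr5_photometry.csv"
                    table.to_csv(p3, index=False)
                    paths.append(p3)
                    report["anova"]["photometry.operant_pr5"] = {
                        r["effect"]: {"F": r["F"], "p": r["p"]}
                        for r in table.to_dict("records")
                    }
                except ValueError as err:
                    report["qc"]["operant_anova_skipped"] = str(err)

    p = out / "report" / "stats_report.json"
    p.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    paths.append(p)
    _register(manifest, out, *paths)


def make_fixtures(kind: str, outdir: str | Path) -> Path:
    """Write the small hand-checkable inputs used in examples and tests.

    ``toy_events``: a two-trial DRLM log with DS at t=100 and a feeder
    response at t=103.  ``toy_trace``: a 100-s constant trace with a single
    unit transient at t=50.  ``anova_2x2``: a balanced 8-subject
    2 (group) x 2 (test) table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_events":
        rows = [
            ("ds_on", 100.0), ("feeder", 103.0), ("pellet", 103.5),
            ("ds_off", 104.0), ("feeder", 120.0), ("feeder", 140.0),
            ("ds_on", 160.0), ("ds_off", 190.0),
        ]
        log = EventLog(
            mouse_id="toy01", group="CON", session_type="DRLM", test_index=1,
            events=pd.DataFrame(rows, columns=["event", "time_s"]),
        )
        path = outdir / "toy_events.csv"
        write_events(log, path)
        return path
    if kind == "toy_trace":
        from .config import PhotoParams
        from .simulate import transient_kernel

        rate = 100.0
        t = np.arange(int(100 * rate)) / rate
        F = 10.0 + transient_kernel(t - 50.0, 0.1, 1.0)
        path = outdir / "toy_trace.csv"
        write_trace_csv(PhotometryTrace(F=F, rate_hz=rate), path)
        return path
    if kind == "anova_2x2":
        rows = []
        data = {
            ("g1", "s1"): (3.0, 5.0), ("g1", "s2"): (4.0, 6.0),
            ("g1", "s3"): (5.0, 9.0), ("g1", "s4"): (6.0, 8.0),
            ("g2", "s5"): (7.0, 10.0), ("g2", "s6"): (8.0, 12.0),
            ("g2", "s7"): (9.0, 11.0), ("g2", "s8"): (10.0, 13.0),
        }
        for (g, s), (t1, t2) in data.items():
            rows.append({"mouse_id": s, "group": g, "test": 1, "dv": t1})
            rows.append({"mouse_id": s, "group": g, "test": 2, "dv": t2})
        path = outdir / "anova_2x2.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")
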