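"""End-to-end orchestration: simulate/ingest -> QC -> SRI -> metrics -> stats.

``run_full_analysis`` drives every stage on one configuration, writes all
stage outputs as sorted, fixed-precision CSVs under the output directory,
and returns a manifest (also written as JSON) sufficient to re-run the
analysis identically: seed, configuration echo, per-stage row counts and
output paths. Stages after QC operate only on included participants.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    DEFAULT_DAY_START,
    ParticipantRecord,
    build_day_matrix,
    read_covariates_csv,
    read_diary_csv,
    read_epoch_csv,
    read_intervals_csv,
    write_cohort_table,
    write_covariates_csv,
    write_diary_csv,
    write_intervals_csv,
)
from .metrics import (
    LIGHT_THRESHOLD_LUX,
    alcohol_summary,
    light_window_minutes,
    nightly_metrics,
    subjective_sleep_efficiency,
    weekly_averages,
)
from .qc import QCRule, filter_cohort
from .simulate import GeneratorConfig, cohort_covariates_frame, generate_cohort
from .sri import DEFAULT_WEEKS, weekly_and_total_sri
from .stats import (
    DEFAULT_LOGISTIC_BLOCKS,
    StatsRefusal,
    bivariate_tests,
    correlate_sri_metrics,
    lmm_weekly_sri,
    stepwise_logistic_relapse,
)

logger = logging.getLogger("sleepreg")

__all__ = ["RunConfig", "run_full_analysis", "build_cohort_tables", "recode_race"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    n_participants: int = 120
    generator_overrides: dict = field(default_factory=dict)
    # ... or ingest canonical CSVs
    epochs_path: str | None = None
    intervals_path: str | None = None
    diary_path: str | None = None
    covariates_path: str | None = None
    # analysis options
    day_start: str = "17:00"
    weeks: tuple[tuple[int, int], ...] = DEFAULT_WEEKS
    light_threshold: float = LIGHT_THRESHOLD_LUX
    excluded_policy: str = "renormalize"
    logistic_blocks: tuple[tuple[str, ...], ...] = DEFAULT_LOGISTIC_BLOCKS
    continuous_test: str = "t"
    write_epochs: bool = False
    log_level: str = "INFO"


def recode_race(raw: str) -> str:
    """Collapse detailed race labels to White / Black-African American / Other."""
    if raw == "White":
        return "White"
    if raw in ("Black or African American", "Black/African American"):
        return "Black/African American"
    return "Other"


def _load_records(config: RunConfig) -> list[ParticipantRecord]:
    day_start = dt.time(*map(int, config.day_start.split(":")))
    epoch_series = read_epoch_csv(config.epochs_path)
    intervals = dict(read_intervals_csv(config.intervals_path)) if config.intervals_path else {}
    diaries = dict(read_diary_csv(config.diary_path)) if config.diary_path else {}
    cov = read_covariates_csv(config.covariates_path) if config.covariates_path else None
    records = []
    for pid, frame in epoch_series:
        rec = ParticipantRecord(id=pid, epochs=frame)
        rec.day_matrix = build_day_matrix(frame, pid, day_start)
        rec.rest_intervals = list(intervals.get(pid, []))
        rec.diary = diaries.get(pid)
        if cov is not None and pid in cov.index:
            row = cov.loc[pid]
            rec.sex = str(row.get("sex", "M"))
            rec.age = float(row.get("age", np.nan))
            rec.married = bool(row.get("married", False))
            rec.covariates = {
                k: row[k] for k in cov.columns if k not in ("sex", "age", "married")
            }
        records.append(rec)
    return records


def build_cohort_tables(
    records: list[ParticipantRecord],
    weeks=DEFAULT_WEEKS,
    excluded_policy: str = "renormalize",
    light_threshold: float = LIGHT_THRESHOLD_LUX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the wide per-participant table and the long weekly table.

    The wide table carries relapse, demographics, total/weekly SRI, weekly
    nap duration, light averages, subjective measures; the long table has
    one row per participant-week (sri, nap_duration, relapse) for the
    repeated-measures model.
    """
    wide_rows, long_rows = [], []
    for rec in records:
        sri = weekly_and_total_sri(rec.day_matrix, weeks, excluded_policy)
        nightly = nightly_metrics(rec)
        weekly = weekly_averages(nightly, weeks)
        row: dict = {
            "participant_id": rec.id,
            "age": rec.age,
            "sex": rec.sex,
            "marital": "Married" if rec.married else "Other",
            "total_sri": sri.total_sri,
        }
        if "race" in rec.covariates:
            row["race"] = recode_race(str(rec.covariates["race"]))
        for w in range(len(weeks)):
            row[f"sri_w{w + 1}"] = sri.weekly_sri[w]
            row[f"nap_w{w + 1}"] = weekly["nap_duration"].iloc[w]
            for var in ("sleep_duration", "waso", "sol", "sleep_efficiency"):
                row[f"{var}_w{w + 1}"] = weekly[var].iloc[w]
        row["sleep_duration_mean"] = float(np.nanmean(nightly["sleep_duration"]))
        if rec.epochs is not None and rec.epochs["lux"].notna().any():
            light = light_window_minutes(rec.epochs, light_threshold)
            for col, name in (
                ("minutes_24h", "light_24h"),
                ("minutes_daytime", "light_daytime"),
                ("minutes_nighttime", "light_nighttime"),
            ):
                row[name] = float(light[col].mean())
        if rec.diary is not None:
            summary = alcohol_summary(rec.diary, rec.sex if rec.sex in "MF" else "M")
            row["relapse"] = summary.relapse
            row["total_drinks"] = summary.total_drinks
            row["drinking_days"] = summary.drinking_days
            row["heavy_drinking_days"] = summary.heavy_drinking_days
            row["days_to_first_drink"] = summary.days_to_first_drink
            row["pct_days_abstinent"] = summary.pct_days_abstinent
        cov = rec.covariates
        row["psqi"] = cov.get("psqi", np.nan)
        if "subjective_sleep_efficiency" in cov:
            row["subjective_sleep_efficiency"] = cov["subjective_sleep_efficiency"]
        elif "hours_slept" in cov and "hours_in_bed" in cov:
            row["subjective_sleep_efficiency"] = subjective_sleep_efficiency(
                cov["hours_slept"], cov["hours_in_bed"]
            )
        wide_rows.append(row)
        for w in range(len(weeks)):
            long_rows.append(
                {
                    "participant_id": rec.id,
                    "week": w + 1,
                    "sri": sri.weekly_sri[w],
                    "nap_duration": weekly["nap_duration"].iloc[w],
                    "relapse": row.get("relapse"),
                }
            )
    wide = pd.DataFrame(wide_rows).sort_values("participant_id").reset_index(drop=True)
    long = (
        pd.DataFrame(long_rows)
        .sort_values(["participant_id", "week"])
        .reset_index(drop=True)
    )
    return wide, long


def _stats_stage(wide, long, config, out, manifest):
    try:
        biv = bivariate_tests(
            wide,
            variables=[
                c
                for c in wide.columns
                if c not in ("participant_id", "relapse")
                and not c.startswith(("total_drinks", "drinking", "heavy", "days_to", "pct_"))
            ],
            continuous_test=config.continuous_test,
        )
        biv.to_csv(out / "bivariate_tests.csv", index=False, float_format="%.6g")
        manifest["stages"]["bivariate"] = len(biv)
    except StatsRefusal as exc:
        manifest["stages"]["bivariate"] = f"refused: {exc}"
    try:
        blocks = stepwise_logistic_relapse(wide, config.logistic_blocks)
        rows = []
        for rep in blocks:
            t = rep.terms.copy()
            t.insert(0, "block", rep.block)
            t["deviance"] = rep.deviance
            t["converged"] = rep.converged
            rows.append(t)
        pd.concat(rows).to_csv(out / "logistic_blocks.csv", index=False, float_format="%.6g")
        manifest["stages"]["logistic_blocks"] = len(blocks)
    except StatsRefusal as exc:
        manifest["stages"]["logistic_blocks"] = f"refused: {exc}"
    try:
        lmm = lmm_weekly_sri(long.dropna(subset=["sri", "relapse"]))
        t = lmm.terms.copy()
        t["structure"] = lmm.structure
        t["aic"] = lmm.aic
        t["bic"] = lmm.bic
        t.to_csv(out / "lmm_weekly_sri.csv", index=False, float_format="%.6g")
        manifest["stages"]["lmm"] = len(t)
    except (StatsRefusal, RuntimeError) as exc:
        manifest["stages"]["lmm"] = f"refused: {exc}"
    pairs = [("total_sri", "psqi"), ("total_sri", "subjective_sleep_efficiency")]
    pairs += [
        ("total_sri", c) for c in ("light_24h", "light_daytime", "light_nighttime") if c in wide
    ]
    pairs += [(f"sri_w{w}", f"nap_w{w}") for w in range(1, 5) if f"sri_w{w}" in wide]
    pairs += [("total_sri", "sleep_duration_mean")]
    corr = correlate_sri_metrics(wide, [p for p in pairs if p[0] in wide and p[1] in wide])
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.6g")
    manifest["stages"]["correlations"] = len(corr)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "stages": {},
        "status": "running",
    }
    try:
        if config.simulate:
            gen = GeneratorConfig(
                seed=config.seed,
                n_participants=config.n_participants,
                **config.generator_overrides,
            )
            records, truth = generate_cohort(gen)
            truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
            write_covariates_csv(cohort_covariates_frame(records), out / "covariates.csv")
            write_diary_csv([(r.id, r.diary) for r in records], out / "diary.csv")
            write_intervals_csv(
                [(r.id, r.rest_intervals) for r in records], out / "intervals.csv"
            )
            manifest["stages"]["simulate"] = len(records)
        else:
            records = _load_records(config)
            manifest["stages"]["ingest"] = len(records)

        included, reports = filter_cohort(records, QCRule())
        qc_df = pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "n_days_with_data": r.n_days_with_data,
                    "n_days_with_ge6h_excluded": r.n_days_with_ge6h_excluded,
                    "included": int(r.included),
                    "reasons": ";".join(r.reasons),
                }
                for r in reports
            ]
        ).sort_values("participant_id")
        qc_df.to_csv(out / "qc_report.csv", index=False)
        manifest["stages"]["qc_included"] = len(included)
        manifest["stages"]["qc_total"] = len(reports)

        if not included:
            manifest["status"] = "empty_cohort"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            logger.warning("no participants passed QC; stopping")
            return manifest

        wide, long = build_cohort_tables(
            included, config.weeks, config.excluded_policy, config.light_threshold
        )
        sri_cols = ["participant_id", "total_sri"] + [
            f"sri_w{w}" for w in range(1, len(config.weeks) + 1)
        ]
        write_cohort_table(wide[sri_cols], out / "sri.csv")
        write_cohort_table(wide, out / "cohort.csv")
        write_cohort_table(long, out / "weekly.csv")
        manifest["stages"]["cohort_rows"] = len(wide)
        manifest["stages"]["weekly_rows"] = len(long)

        _stats_stage(wide, long, config, out, manifest)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
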