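"""End-to-end pipeline: simulate or ingest, then run every analysis stage.

Stages: growth-curve fit, birth-week back-calculation and peak detection,
adult/juvenile/TL body-mass models, diet composition, and the hibernation
energy budget. Each stage writes its own CSV; a JSON metrics index links
the headline numbers back to the stage files. Stages whose required inputs
are missing are skipped with an explicit notice.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bodymass, diet, energy, growth, io, phenology, simulate
from .records import DIET_CATEGORIES, PeriodMap

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger("quercinus.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int | None = 0
    output_dir: str = "quercinus_out"
    captures_path: str | None = None
    fecal_path: str | None = None
    temperature_path: str | None = None
    synthetic: simulate.SyntheticConfig = field(
        default_factory=simulate.SyntheticConfig
    )
    peak_bandwidth: float = 0.5
    peak_prominence_fraction: float = 0.1
    peak_min_separation: int = 3
    deficit_g: float = 10.0
    period_map: PeriodMap = field(default_factory=PeriodMap)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")
        if self.mode == "files" and not self.captures_path:
            raise ValueError("files mode requires a captures path")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = simulate.SyntheticConfig(**raw.pop("synthetic", {}))
    cfg = PipelineConfig(synthetic=syn, **raw)
    cfg.validate()
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write stage CSVs plus a JSON metrics index.

    Deterministic under a fixed seed in synthetic mode. Returns the metrics
    index as a dict (also written to ``metrics.json``).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"mode": config.mode, "seed": config.seed, "stages": {}, "notices": []}

    # ------------------------------------------------------------------ input
    if config.mode == "synthetic":
        seed = int(config.seed)
        roster = simulate.simulate_population(config.synthetic, seed)
        records = simulate.simulate_captures(roster, config.synthetic, seed + 1)
        fecal = simulate.simulate_fecal(roster, config.synthetic, seed + 2)
        temps = simulate.simulate_daily_temperature(config.synthetic, seed + 3)
        io.write_captures(records, out / "captures.csv")
        io.write_fecal_samples(fecal, out / "fecal_samples.csv")
        io.write_daily_min_temperature(temps, out / "temperatures.csv")
        litter = simulate.simulate_reference_litter(config.synthetic, seed + 4)
    else:
        records = io.read_captures(config.captures_path, config.period_map)
        fecal = (
            io.read_fecal_samples(config.fecal_path) if config.fecal_path else None
        )
        temps = (
            io.read_daily_min_temperature(config.temperature_path)
            if config.temperature_path
            else None
        )
        litter = None
    captures = io.captures_to_frame(records)
    log.info("input: %d capture records", len(captures))

    # ------------------------------------------------------------ growth fit
    if litter is not None:
        params = growth.fit_gompertz(litter["age_days"], litter["tibia_length"])
        litter.to_csv(out / "reference_litter.csv", index=False)
        metrics["stages"]["growth_fit"] = {
            "a_mm": params.a,
            "b": params.b,
            "c_per_day": params.c,
            "r_squared": params.r_squared,
            "n_points": params.n_points,
            "file": "reference_litter.csv",
        }
    else:
        params = growth.REFERENCE_PARAMS
        metrics["notices"].append(
            "growth_fit: no reference litter supplied; using published parameters"
        )
        metrics["stages"]["growth_fit"] = {
            "a_mm": params.a,
            "b": params.b,
            "c_per_day": params.c,
            "source": "published",
        }

    # ------------------------------------------------- birth weeks and peaks
    estimates, exclusions = growth.estimate_birth_weeks(captures, params)
    est_df = pd.DataFrame(
        {
            "individual_id": [e.individual_id for e in estimates],
            "period": [e.period for e in estimates],
            "first_capture_date": [e.first_capture_date for e in estimates],
            "tl_at_first_capture": [e.tl_at_first_capture for e in estimates],
            "estimated_age_days": [e.estimated_age_days for e in estimates],
            "birth_date": [e.birth_date for e in estimates],
            "birth_week": [e.birth_week for e in estimates],
        }
    )
    est_df.to_csv(out / "birth_estimates.csv", index=False)
    exclusions.to_csv(out / "birth_exclusions.csv", index=False)
    peak_info = {}
    for period in sorted(est_df["period"].dropna().unique()):
        cohort = [e for e in estimates if e.period == period]
        if not cohort:
            continue
        dist = phenology.summarize_cohort(
            cohort,
            bandwidth=config.peak_bandwidth,
            prominence_fraction=config.peak_prominence_fraction,
            min_separation=config.peak_min_separation,
        )
        peak_info[str(int(period))] = {
            "n": len(cohort),
            "peak_weeks": list(dist.peak_weeks),
            "earliest_week": dist.earliest_week,
            "latest_week": dist.latest_week,
        }
    metrics["stages"]["phenology"] = {
        "per_period": peak_info,
        "n_excluded": len(exclusions),
        "file": "birth_estimates.csv",
    }
    captures = captures.merge(
        est_df[["individual_id", "birth_week"]], on="individual_id", how="left"
    )

    # U-test: TL (age) at first capture, period 1 vs period 2
    by_period = {
        int(p): est_df.loc[est_df["period"] == p, "tl_at_first_capture"].to_numpy()
        for p in sorted(est_df["period"].dropna().unique())
    }
    if len(by_period) == 2 and all(v.size for v in by_period.values()):
        u, p_val = phenology.compare_first_capture_tl(by_period[1], by_period[2])
        metrics["stages"]["phenology"]["first_capture_tl_u"] = u
        metrics["stages"]["phenology"]["first_capture_tl_p"] = p_val

    # ------------------------------------------------------ temperature stage
    winter_medians: dict[int, float] = {}
    if temps is not None:
        years = sorted({d.year for d in temps.dates})
        for year in years:
            try:
                summary = io.compute_t_aminhib(temps, year)
            except Exception:
                continue
            winter_medians[year] = summary.t_aminhib_c
        pd.DataFrame(
            {
                "winter_start_year": list(winter_medians),
                "t_aminhib_c": list(winter_medians.values()),
            }
        ).to_csv(out / "winter_summaries.csv", index=False)
        metrics["stages"]["temperature"] = {
            "n_winters": len(winter_medians),
            "file": "winter_summaries.csv",
        }
        captures = bodymass.attach_t_aminhib(captures, winter_medians)
    else:
        metrics["notices"].append("temperature: no series supplied; stage skipped")

    # ------------------------------------------------------- body-mass models
    bm_metrics = {}
    for sex in ("female", "male"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = bodymass.fit_adult_bm(captures, sex)
                con = bodymass.september_period_contrast(fit)
            coef = pd.DataFrame(
                {"estimate": fit.params, "se": fit.bse}
            )
            coef.to_csv(out / f"adult_bm_{sex}_coefficients.csv")
            bm_metrics[sex] = {
                "september_period_difference_g": con.estimate,
                "se": con.se,
                "p_tukey": con.p_tukey,
                "file": f"adult_bm_{sex}_coefficients.csv",
            }
        except ValueError as exc:
            metrics["notices"].append(f"adult_bm[{sex}] skipped: {exc}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            juv_fit = bodymass.fit_juvenile_logbm(captures)
        pd.DataFrame({"estimate": juv_fit.params, "se": juv_fit.bse}).to_csv(
            out / "juvenile_logbm_coefficients.csv"
        )
        bm_metrics["juvenile_logbm"] = {
            name: float(juv_fit.params[name])
            for name in juv_fit.params.index
        } | {"file": "juvenile_logbm_coefficients.csv"}
    except ValueError as exc:
        metrics["notices"].append(f"juvenile_logbm skipped: {exc}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tl_fit = bodymass.fit_tl_model(captures)
        pd.DataFrame({"estimate": tl_fit.params, "se": tl_fit.bse}).to_csv(
            out / "adult_tl_coefficients.csv"
        )
        bm_metrics["tl_model"] = {
            "sex_male_mm": float(tl_fit.params.get("sex[male]", np.nan)),
            "file": "adult_tl_coefficients.csv",
        }
    except ValueError as exc:
        metrics["notices"].append(f"tl_model skipped: {exc}")
    if bm_metrics:
        metrics["stages"]["body_mass"] = bm_metrics

    # --------------------------------------------------------------- diet
    if fecal:
        rows = []
        for age_class in ("adult", "juvenile"):
            for summary in diet.monthly_composition(fecal, age_class):
                for cat in DIET_CATEGORIES:
                    rows.append(
                        {
                            "age_class": age_class,
                            "stratum": summary.stratum,
                            "category": cat,
                            "median_pct": summary.median[cat],
                            "q25_pct": summary.q25[cat],
                            "q75_pct": summary.q75[cat],
                            "n": summary.n,
                        }
                    )
        comp = pd.DataFrame(rows)
        comp.to_csv(out / "diet_composition.csv", index=False)
        foo = diet.frequency_of_occurrence(fecal)
        foo.to_csv(out / "diet_foo.csv", index=False)
        sept = comp[
            (comp["age_class"] == "adult")
            & (comp["stratum"] == "September")
            & (comp["category"] == "arthropods")
        ]
        metrics["stages"]["diet"] = {
            "n_samples": len(fecal),
            "adult_september_arthropod_median_pct": (
                float(sept["median_pct"].iloc[0]) if len(sept) else None
            ),
            "files": ["diet_composition.csv", "diet_foo.csv"],
        }
    else:
        metrics["notices"].append("diet: no fecal table supplied; stage skipped")

    # ------------------------------------------------------- energy budget
    male = bm_metrics.get("male")
    entry_exit = None
    if config.mode == "synthetic":
        means = config.synthetic.adult_bm_means
        entry_exit = (means[("male", "September")][0], means[("male", "May")][0])
    else:
        adult_m = captures[
            (captures["age_class"] == "adult") & (captures["sex"] == "male")
        ].copy()
        if not adult_m.empty:
            adult_m["month"] = [pd.Timestamp(d).month for d in adult_m["capture_date"]]
            sept = adult_m.loc[adult_m["month"] == 9, "body_mass"]
            may = adult_m.loc[adult_m["month"] == 5, "body_mass"]
            if len(sept) and len(may):
                entry_exit = (float(sept.mean()), float(may.mean()))
    if entry_exit and entry_exit[0] > entry_exit[1]:
        start, end = energy.DEFAULT_WINDOW
        duration = energy.hibernation_duration(start, end)
        budget = energy.daily_loss(entry_exit[0], entry_exit[1], duration, (start, end))
        shift = energy.depletion_shift(config.deficit_g, budget)
        emergence = energy.projected_emergence(end, shift, start)
        budget_row = {
            "bm_entry_g": budget.bm_entry,
            "bm_exit_g": budget.bm_exit,
            "window_start": start,
            "window_end": end,
            "duration_days": duration,
            "total_loss_g": budget.total_loss,
            "daily_loss_g_per_day": budget.daily_loss,
            "relative_daily_loss_pct_per_day": budget.relative_daily_loss,
            "deficit_g": config.deficit_g,
            "depletion_shift_days": shift,
            "projected_emergence": emergence,
        }
        pd.DataFrame([budget_row]).to_csv(out / "energy_budget.csv", index=False)
        metrics["stages"]["energy_budget"] = _jsonable(
            budget_row | {"file": "energy_budget.csv"}
        )
    else:
        metrics["notices"].append(
            "energy_budget: no usable September/May male means; stage skipped"
        )

    metrics = _jsonable(metrics)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    write_report(metrics, out / "report.md")
    return metrics


def write_report(metrics: dict, path: str | Path) -> None:
    """Render the metrics index as a small markdown report.

    Every number in the report also appears in exactly one stage CSV; the
    report only relays the metrics index, so regenerating it from the same
    index is byte-identical.
    """
    lines = ["# Pipeline report", ""]
    lines.append(f"Mode: {metrics.get('mode')}, seed: {metrics.get('seed')}")
    lines.append("")
    stages = metrics.get("stages", {})
    if not stages:
        lines.append("No stages produced output.")
    for name, info in sorted(stages.items()):
        lines.append(f"## {name}")
        lines.append("")
        for key, value in sorted(info.items(), key=lambda kv: str(kv[0])):
            lines.append(f"- {key}: {value}")
        lines.append("")
    notices = metrics.get("notices", [])
    if notices:
        lines.append("## Notices")
        lines.append("")
        lines.extend(f"- {n}" for n in notices)
        lines.append("")
    Path(path).write_text("\n".join(lines))
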