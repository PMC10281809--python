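"""End-to-end pipeline: collections → ages → hatch dates → spawning
curves → peaks → closure evaluation.

Each stage is a thin orchestration of the corresponding module; the run
report carries stage-by-stage accounting (the identity
aged + imputed + dropped = collected is asserted) and every output is
deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agelength, ageing, closures, env, io, synthetic, trends

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    config: io.RunConfig
    fish: pd.DataFrame
    cohorts: list
    age_length_fit: object | None
    series_by_year: dict
    trend_fits: dict
    peaks_by_year: dict
    peak_summary: pd.DataFrame
    env_result: object | None
    capture_results: pd.DataFrame
    capture_model: object | None
    report: dict = field(default_factory=dict)


def _austral_year(d: dt.date) -> int:
    return trends.austral_year_of(d)


def run_pipeline(config: io.RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Run every stage of the analysis under one configuration.

    Inputs come from the configured fish/environment tables, or from the
    synthetic generator when the ``synthetic`` block is present. Any stage
    failure raises with a stage-tagged message.
    """
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "stages": {}}

    # ------------------------------------------------------------------ input
    if config.synthetic or config.fish_table is None:
        syn = dict(config.synthetic)
        syn.pop("enabled", None)
        fish, env_table, syn_report = synthetic.simulate_study(seed=config.seed, **syn)
        report["stages"]["input"] = {"source": "synthetic", "n_records": len(fish),
                                     "n_dropped_by_trips": sum(r["n_dropped"] for r in syn_report["per_year"])}
    else:
        fish, rejected = io.read_fish_table(config.fish_table)
        env_table = io.read_env_table(config.env_table) if config.env_table else None
        report["stages"]["input"] = {"source": config.fish_table, "n_records": len(fish),
                                     "n_rejected_rows": len(rejected), "rejections": rejected[:20]}

    # ------------------------------------------------------------------ ageing
    try:
        fish, age_report = ageing.age_fish_table(
            fish, mean_pld_days=config.pld_mean_override, tolerance=config.qc_count_tolerance
        )
    except Exception as e:
        raise RuntimeError(f"[ageing] {e}") from e
    report["stages"]["ageing"] = age_report
    mean_pld = age_report["mean_pld_days"]

    aged = fish[fish["aged"]].copy()
    if len(aged) < 10:
        raise RuntimeError("[ageing] too few aged fish to proceed")

    # ------------------------------------------------------------------ cohorts
    try:
        cohort_windows = agelength.define_cohorts(aged["hatch_date"], config.cohort_gap_days)
    except Exception as e:
        raise RuntimeError(f"[cohorts] {e}") from e
    report["stages"]["cohorts"] = {
        "n_cohorts": len(cohort_windows),
        "windows": [
            {"id": c.cohort_id, "start": c.start_date.isoformat(), "end": c.end_date.isoformat()}
            for c in cohort_windows
        ],
    }

    # ------------------------------------------------------------------ age-length fit
    al_fit = None
    try:
        al_fit = agelength.fit_age_length(aged, cohort_windows)
        report["stages"]["age_length"] = {
            "coefficients": [float(b) for b in al_fit.fixed_coefficients],
            "cohort_sd": al_fit.cohort_sd,
            "random_effect_dropped": al_fit.random_effect_dropped,
            **al_fit.diagnostics,
        }
    except ValueError as e:
        logger.warning("[age-length] %s; imputation skipped", e)
        report["stages"]["age_length"] = {"skipped": str(e)}

    # ------------------------------------------------------------------ imputation
    nonaged = fish[~fish["aged"] & ~fish["qc_rejected"]].copy()
    aged_years = {
        _austral_year(d) for d in aged["collection_date"]
    }
    n_imputed = n_dropped_range = n_dropped_no_aged = 0
    imputed_rows = []
    if al_fit is not None:
        ages_obs = aged["post_settlement_age_days"].to_numpy(dtype=float)
        age_range = (float(ages_obs.min()), float(ages_obs.max()))
        for _, row in nonaged.iterrows():
            cdate = row["collection_date"]
            if _austral_year(cdate) not in aged_years:
                # no ageing data for this period: age-length cannot be trusted
                n_dropped_no_aged += 1
                continue
            cid = agelength.assign_cohort(cdate, cohort_windows, age_range, mean_pld)
            try:
                age_hat, ci = agelength.predict_age(al_fit, float(row["total_length_mm"]), cid)
            except ValueError:
                n_dropped_range += 1
                continue
            try:
                sett, hatch = ageing.back_calculate(cdate, age_hat, mean_pld)
            except ValueError:
                n_dropped_range += 1
                continue
            imputed_rows.append(
                {
                    "fish_id": row["fish_id"],
                    "cohort_id": cid,
                    "predicted_age_days": age_hat,
                    "age_ci_lo": ci[0],
                    "age_ci_hi": ci[1],
                    "settlement_date": sett,
                    "hatch_date": hatch,
                }
            )
        n_imputed = len(imputed_rows)
        imputed = pd.DataFrame(imputed_rows)
        if n_imputed:
            fish = fish.merge(
                imputed[["fish_id", "settlement_date", "hatch_date", "predicted_age_days", "cohort_id"]],
                on="fish_id", how="left", suffixes=("", "_imputed"),
            )
            m = fish["hatch_date"].isna() & fish["hatch_date_imputed"].notna()
            fish.loc[m, "hatch_date"] = fish.loc[m, "hatch_date_imputed"]
            fish.loc[m, "settlement_date"] = fish.loc[m, "settlement_date_imputed"]
            fish.loc[m, "post_settlement_age_days"] = fish.loc[m, "predicted_age_days"]
            fish = fish.drop(columns=["hatch_date_imputed", "settlement_date_imputed", "predicted_age_days"])
    report["stages"]["imputation"] = {
        "n_imputed": n_imputed,
        "n_dropped_out_of_range": n_dropped_range,
        "n_dropped_no_ageing_data": n_dropped_no_aged,
    }

    n_analyzed = int(fish["hatch_date"].notna().sum())
    report["accounting"] = {
        "n_collected": int(len(fish)),
        "n_aged": int(len(aged)),
        "n_imputed": n_imputed,
        "n_analyzed": n_analyzed,
        "identity_aged_plus_imputed_equals_analyzed": bool(len(aged) + n_imputed == n_analyzed),
    }

    # ------------------------------------------------------------------ trends
    hatches = fish.loc[fish["hatch_date"].notna(), "hatch_date"].tolist()
    series_by_year, excluded = trends.split_austral_years(hatches, config.min_fish_per_year)
    p_grid = np.linspace(config.gam_p_min, config.gam_p_max, config.gam_n_p)
    trend_fits, peaks_by_year = {}, {}
    for y, series in series_by_year.items():
        try:
            fit = trends.fit_spawning_smooth(series, k_grid=tuple(config.gam_k_grid), p_grid=p_grid)
        except RuntimeError as e:
            raise RuntimeError(f"[trends] austral year {y}: {e}") from e
        trend_fits[y] = fit
        peaks_by_year[y] = trends.detect_peaks(
            fit, series, n_draws=config.peak_ci_draws, seed=config.seed + y
        )
    peak_summary = trends.summarize_peaks(peaks_by_year, trend_fits)
    report["stages"]["trends"] = {
        "fitted_years": sorted(series_by_year),
        "excluded_years": excluded,
        "deviance_explained": {int(y): round(f.deviance_explained, 3) for y, f in trend_fits.items()},
    }

    # ------------------------------------------------------------------ environment
    env_result = None
    if env_table is not None and len(series_by_year) >= 2:
        try:
            bins = env.build_env_bins(env_table, list(series_by_year.values()))
            env_result = env.fit_env_smooth(bins)
            report["stages"]["environment"] = {
                "best_model": env_result.best_name,
                "candidates": env_result.candidate_table.to_dict("records"),
                "concurvity_flags": env_result.flagged_pairs,
            }
        except (ValueError, RuntimeError) as e:
            logger.warning("[environment] %s; stage skipped", e)
            report["stages"]["environment"] = {"skipped": str(e)}

    # ------------------------------------------------------------------ closures
    capture_rows = []
    for y, series in series_by_year.items():
        season = closures.season_range(y)
        moons = closures.new_moons(*season)
        activity = closures.daily_activity_from_fit(trend_fits[y], series, season)
        for dur in config.closure_durations:
            for n in config.closure_counts:
                if n > len(moons):
                    continue
                wins = closures.make_closures(
                    moons, dur, n, season, anchor_offset_days=config.closure_anchor_offset_days
                )
                res = closures.capture_proportion(activity, wins, season, year_label=y, duration_days=dur)
                capture_rows.append(dataclasses.asdict(res))
    capture_results = pd.DataFrame(capture_rows)
    capture_model = None
    if (
        not capture_results.empty
        and capture_results["duration_days"].nunique() >= 2
        and capture_results["n_closures"].nunique() >= 2
        and capture_results["year_label"].nunique() >= 2
    ):
        capture_model = closures.fit_capture_model(capture_results)
        report["stages"]["closures"] = {
            "duration_ratio": capture_model.duration_ratio,
            "interaction_dropped": capture_model.interaction_dropped,
            "year_sd": capture_model.year_sd,
            "contrasts": capture_model.contrasts.to_dict("records"),
        }

    result = PipelineResult(
        config=config,
        fish=fish,
        cohorts=cohort_windows,
        age_length_fit=al_fit,
        series_by_year=series_by_year,
        trend_fits=trend_fits,
        peaks_by_year=peaks_by_year,
        peak_summary=peak_summary,
        env_result=env_result,
        capture_results=capture_results,
        capture_model=capture_model,
        report=report,
    )
    if write_outputs:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "resolved_config.yaml")
    io.write_table(result.fish, out / "fish_with_hatch_dates.csv")
    io.write_table(result.peak_summary, out / "peak_summary.csv")
    if not result.capture_results.empty:
        io.write_table(result.capture_results, out / "capture_proportions.csv")
    rows = []
    for y, s in result.series_by_year.items():
        for start, w, c in zip(s.bin_starts, s.bin_days, s.counts):
            rows.append({"austral_year": y, "bin_start": start, "n_days": int(w), "count": int(c)})
    if rows:
        io.write_table(pd.DataFrame(rows), out / "spawning_bins.csv")
    with open(out / "run_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
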