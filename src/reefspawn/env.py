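"""Environmental covariates of spawning activity.

Aligns environmental series with the 5-day spawning bins (lunar
illumination averaged with a +10 h east-Australian time shift, night-time
SST as 8-day averages mapped to bin midpoints, rainfall summed), then fits
and compares Tweedie smooths of spawn counts:

    y = β0 + s(SST|Month) + γ_year + ε,   ε ~ Tw_p(μ, σ²)

where s(SST|Month) is a tensor-product interaction between a continuous
SST smooth and a cyclic month smooth, and γ_year is a ridge-penalized
year intercept (the random year term). Candidate models with and without
lunar illumination and rainfall smooths are compared by AICc, and
pairwise concurvity — the smooth-model analogue of collinearity — is
computed for all candidate covariates; pairs above 0.7 are flagged
(flood-gauge height is ingested but excluded from the default model: it
is largely reproducible from SST and month).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lunar
from .smoothing import (
    CyclicSplineTerm,
    RandomInterceptTerm,
    SplineTerm,
    TensorTerm,
    TweedieGAMFit,
    concurvity_matrix,
    fit_tweedie_gam,
)
from .trends import SpawningSeries

__all__ = ["build_env_bins", "fit_env_smooth", "EnvModelResult", "CONCURVITY_FLAG"]

CONCURVITY_FLAG = 0.7  # flag threshold; the smooth analogue of collinearity
MAX_SST_GAP_DAYS = 16


def _eight_day_averages(env: pd.DataFrame) -> pd.DataFrame:
    """Collapse the daily SST series into 8-day block averages (the MODIS
    night-time product convention), blocks anchored at the series start."""
    env = env.sort_values("date").reset_index(drop=True)
    d0 = env["date"].iloc[0]
    block = env["date"].map(lambda d: (d - d0).days // 8)
    grp = env.groupby(block)
    out = pd.DataFrame(
        {
            "block_start": grp["date"].min(),
            "block_end": grp["date"].max(),
            "sst_C": grp["sst_C"].mean(),
        }
    )
    return out.reset_index(drop=True)


def build_env_bins(
    env: pd.DataFrame,
    series_list: list[SpawningSeries],
    shift_hours: float = 10.0,
) -> pd.DataFrame:
    """Join environmental covariates onto the 5-day spawning bins.

    Per bin: SST from the 8-day average overlapping the bin midpoint
    (linear interpolation across SST gaps up to 16 days, longer gaps flag
    the bin), rainfall summed, flood height averaged, lunar illumination
    averaged over the bin's days with the +10 h shift. Returns one row per
    bin with an ``ok`` flag; the model stage uses only ok rows.
    """
    env = env.copy()
    env["date"] = pd.to_datetime(env["date"]).dt.date
    env_start, env_end = env["date"].min(), env["date"].max()
    blocks = _eight_day_averages(env[env["sst_C"].notna()][["date", "sst_C"]])
    block_mid = np.array([
        (b + (e - b) / 2 - env_start).days for b, e in zip(blocks["block_start"], blocks["block_end"])
    ], dtype=float)
    daily = env.set_index("date")

    rows = []
    for series in series_list:
        illum_cache = lunar.mean_illumination_series(
            [series.bin_starts[0] + dt.timedelta(days=i) for i in range(int(series.bin_days.sum()))],
            shift_hours,
        )
        for i, (start, width, count) in enumerate(
            zip(series.bin_starts, series.bin_days, series.counts)
        ):
            width = int(width)
            days = [start + dt.timedelta(days=j) for j in range(width)]
            mid = start + dt.timedelta(days=width // 2)
            ok = env_start <= start and days[-1] <= env_end
            sst = np.nan
            if ok and len(blocks):
                mid_off = (mid - env_start).days
                j = int(np.argmin(np.abs(block_mid - mid_off)))
                gap = abs(block_mid[j] - mid_off)
                if gap <= 8:
                    sst = float(blocks["sst_C"].iloc[j])
                elif gap <= MAX_SST_GAP_DAYS:
                    sst = float(np.interp(mid_off, block_mid, blocks["sst_C"].to_numpy()))
                else:
                    ok = False
            rain = flood = np.nan
            if ok:
                sub = daily.loc[[d for d in days if d in daily.index]]
                if len(sub) == width:
                    rain = float(sub["rainfall_mm"].sum())
                    flood = float(sub["flood_height_m"].mean())
                else:
                    ok = False
            off = (start - series.bin_starts[0]).days
            rows.append(
                {
                    "start_date": start,
                    "n_days": width,
                    "year_label": series.austral_year_label,
                    "month": mid.month,
                    "spawn_count": int(count),
                    "sst_C": sst,
                    "rainfall_mm": rain,
                    "flood_height_m": flood,
                    "lunar_illumination": float(np.mean(illum_cache[off : off + width])),
                    "ok": bool(ok),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EnvModelResult:
    """Outcome of environmental model selection."""

    best_name: str
    best_fit: TweedieGAMFit
    candidate_table: pd.DataFrame  # model name, aicc, edf, deviance_explained
    concurvity: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    inputs: dict = field(default_factory=dict, repr=False)


def _sst_month_terms(k_sst: int = 6, k_month: int = 6):
    return TensorTerm(
        SplineTerm(k=k_sst, name="s(SST)"),
        CyclicSplineTerm(k=k_month, period=12.0, name="s(month)"),
        name="te(SST,month)",
    )


def fit_env_smooth(
    bins: pd.DataFrame,
    p_grid: np.ndarray | None = None,
    candidates: tuple[str, ...] = ("null", "sst_month", "sst_month+lunar", "sst_month+rain"),
    k_sst: int = 6,
    k_month: int = 6,
) -> EnvModelResult:
    """Fit and compare candidate environmental smooths by AICc.

    Every candidate includes the year random intercept; "null" is
    intercept + year only. The tensor-product SST-by-month smooth carries
    the seasonal temperature interaction; lunar illumination and rainfall
    enter as univariate smooths in the extended candidates. The selected
    model is the AICc minimum (asserted, never overridden). Requires bins
    from >= 2 years.
    """
    ok = bins[bins["ok"]].reset_index(drop=True)
    if ok["year_label"].nunique() < 2:
        raise ValueError("need bins from at least 2 years")
    if p_grid is None:
        p_grid = np.linspace(1.1, 1.9, 5)
    y = ok["spawn_count"].to_numpy(dtype=float)
    sst = ok["sst_C"].to_numpy(dtype=float)
    month = ok["month"].to_numpy(dtype=float)
    years = ok["year_label"].to_numpy()
    illum = ok["lunar_illumination"].to_numpy(dtype=float)
    rain = ok["rainfall_mm"].to_numpy(dtype=float)

    def build(name):
        terms = []
        inputs = []
        if "sst_month" in name:
            terms.append(_sst_month_terms(k_sst, k_month))
            inputs.append((sst, month))
        if "lunar" in name:
            terms.append(SplineTerm(k=6, name="s(lunar)"))
            inputs.append(illum)
        if "rain" in name:
            terms.append(SplineTerm(k=6, name="s(rain)"))
            inputs.append(rain)
        terms.append(RandomInterceptTerm(name="re(year)"))
        inputs.append(years)
        return terms, inputs

    fits = {}
    rows = []
    for name in candidates:
        terms, inputs = build(name)
        try:
            fit = fit_tweedie_gam(y, terms, inputs, p_grid=p_grid, n_sweeps=1)
        except RuntimeError:
            continue
        fits[name] = fit
        rows.append(
            {
                "model": name,
                "aicc": fit.aicc,
                "edf": fit.edf,
                "deviance_explained": fit.deviance_explained,
                "tweedie_p": fit.tweedie_power_p,
            }
        )
    if not fits:
        raise RuntimeError("no environmental candidate model converged")
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best_name = table["model"].iloc[0]

    # concurvity over the full covariate set, flood included even though it
    # is excluded from the default candidates
    designs = {}
    te = _sst_month_terms(k_sst, k_month)
    designs["te(SST,month)"] = te.fit_design(sst, month)
    designs["s(lunar)"] = SplineTerm(k=6, name="s(lunar)").fit_design(illum)
    designs["s(rain)"] = SplineTerm(k=6, name="s(rain)").fit_design(rain)
    flood = ok["flood_height_m"].to_numpy(dtype=float)
    if np.isfinite(flood).all() and np.ptp(flood) > 0:
        designs["s(flood)"] = SplineTerm(k=6, name="s(flood)").fit_design(flood)
    conc = concurvity_matrix(designs)
    flagged = [
        (a, b, float(conc.loc[a, b]))
        for a in conc.index
        for b in conc.columns
        if a != b and conc.loc[a, b] > CONCURVITY_FLAG
    ]
    return EnvModelResult(
        best_name=best_name,
        best_fit=fits[best_name],
        candidate_table=table,
        concurvity=conc,
        flagged_pairs=flagged,
        inputs={"sst": sst, "month": month, "years": years, "y": y},
    )
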