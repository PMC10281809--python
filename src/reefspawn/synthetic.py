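"""Synthetic juvenile-fish collections and environmental series.

Generates data with the statistical structure the downstream pipeline
assumes, so every stage is testable without field collections:

* hatch dates drawn from a mixture of truncated-normal spawning pulses
  (cohorts spanning weeks to months) over a uniform background;
* juvenile growth following a von Bertalanffy curve — near-linear over
  the sampled 23–248 mm range, hence invertible for the age–length stage;
* replicate otolith increment counts with a configurable coefficient of
  variation, and pelagic larval durations drawn N(27.9, 1.6²) days;
* 2–3 collection trips per multi-year period, with a configurable
  fraction of fish aged (default 0.43);
* sinusoidal sea-surface temperature with noise, gamma-mixture rainfall
  and a rainfall-driven flood-gauge series.

Columns prefixed ``true_`` carry generator truth (hatch date, age, PLD)
for testing only; analysis modules never read them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpawningRegime",
    "GrowthModel",
    "AgeingErrorModel",
    "sample_hatch_dates",
    "draw_pld_counts",
    "realize_fish",
    "generate_env_series",
    "simulate_study",
]


@dataclass
class SpawningRegime:
    """Mixture spawning intensity: truncated-normal pulses + uniform background.

    components: list of (peak_date, spread_days, weight); weight is the
    expected share of spawns relative to other components. background_rate
    is in spawns/day and is converted to a mixture weight by multiplying by
    the span of date_range.
    """

    components: list[tuple[dt.date, float, float]]
    background_rate: float = 0.0
    date_range: tuple[dt.date, dt.date] = (dt.date(2020, 7, 1), dt.date(2021, 6, 30))

    def __post_init__(self) -> None:
        lo, hi = self.date_range
        if hi < lo:
            raise ValueError("empty date_range")
        for peak, spread, w in self.components:
            if spread <= 0 or w <= 0 or not np.isfinite(w):
                raise ValueError("component spreads and weights must be positive finite")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not self.components and self.background_rate == 0:
            raise ValueError("empty regime: no components and zero background")


@dataclass
class GrowthModel:
    """Von Bertalanffy juvenile growth from settlement.

    L(a) = L∞ − (L∞ − L_settle)·exp(−K·a), a = post-settlement age in days.
    Defaults give ≈0.6 mm/day initial growth, keeping lengths within the
    observed 23–248 mm for ages up to about 500 days.
    """

    length_at_settlement_mm: float = 23.0
    asymptotic_length_mm: float = 520.0
    growth_rate_per_day: float = 0.0012
    length_noise_sd_mm: float = 3.0

    def length_at_age(self, age_days):
        a = np.asarray(age_days, dtype=float)
        linf, l0 = self.asymptotic_length_mm, self.length_at_settlement_mm
        return linf - (linf - l0) * np.exp(-self.growth_rate_per_day * a)

    def age_at_length(self, length_mm):
        length = np.asarray(length_mm, dtype=float)
        linf, l0 = self.asymptotic_length_mm, self.length_at_settlement_mm
        return -np.log((linf - length) / (linf - l0)) / self.growth_rate_per_day


@dataclass
class AgeingErrorModel:
    """Replicate-count noise and the pelagic larval duration distribution."""

    count_cv: float = 0.03
    pld_mean_days: float = 27.9
    pld_sd_days: float = 1.6


def _date_to_day(d: dt.date, epoch: dt.date) -> float:
    return (d - epoch).days


def draw_pld_counts(error: AgeingErrorModel, n: int, seed: int) -> np.ndarray:
    """Integer pre-settlement increment counts from the PLD distribution
    (whole increments: values are rounded half-up and floored at 1)."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(error.pld_mean_days, error.pld_sd_days, size=n)
    return np.maximum(1, np.floor(raw + 0.5)).astype(int)


def sample_hatch_dates(regime: SpawningRegime, n: int, seed: int) -> list[dt.date]:
    """Draw n hatch dates from the regime's mixture intensity.

    Components are truncated normals in days-since-epoch, truncated at the
    regime's date_range; the background is uniform over the range. Output
    is deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = regime.date_range
    span = (hi - lo).days + 1

    weights = [w for _, _, w in regime.components]
    weights.append(regime.background_rate * span)
    weights = np.asarray(weights, dtype=float)
    probs = weights / weights.sum()

    which = rng.choice(len(probs), size=n, p=probs)
    days = np.empty(n)
    for k, (peak, spread, _) in enumerate(regime.components):
        mask = which == k
        if not mask.any():
            continue
        mu = _date_to_day(peak, lo)
        a, b = (0 - mu) / spread, (span - 1 - mu) / spread
        days[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=spread,
                                         size=mask.sum(), random_state=rng)
    bg = which == len(regime.components)
    if bg.any():
        days[bg] = rng.uniform(0, span, size=bg.sum())
    days = np.clip(np.floor(days), 0, span - 1).astype(int)
    return [lo + dt.timedelta(days=int(d)) for d in days]


def realize_fish(
    hatch_dates: list[dt.date],
    growth: GrowthModel,
    error: AgeingErrorModel,
    trip_dates: list[dt.date],
    seed: int,
    aged_fraction: float = 0.43,
    pld_counted_fraction: float = 0.09,
    max_length_mm: float = 250.0,
) -> tuple[pd.DataFrame, dict]:
    """Turn hatch dates into collected fish records.

    Each fish is assigned to the first trip at which it has settled
    (post-settlement age > 0, i.e. collection after hatch + PLD) and its
    length is still <= max_length_mm. Fish admitted by no trip are dropped
    and counted in the report. Aged fish (Bernoulli thinning at
    aged_fraction, stratified by trip) carry three replicate counts of the
    true post-settlement age with CV = count_cv; a sub-fraction also
    carries a pre-settlement increment count drawn from the PLD
    distribution.
    """
    trips = sorted(trip_dates)
    if trips and hatch_dates and trips[0] <= min(hatch_dates):
        raise ValueError("every trip date must be after the earliest hatch date")
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for i, hatch in enumerate(hatch_dates):
        pld = max(1.0, rng.normal(error.pld_mean_days, error.pld_sd_days))
        settlement = hatch + dt.timedelta(days=int(np.floor(pld + 0.5)))
        assigned = None
        for trip in trips:
            age = (trip - settlement).days
            if age <= 0:
                continue
            length = float(growth.length_at_age(age))
            if length <= max_length_mm:
                assigned = (trip, age, length)
                break
        if assigned is None:
            n_dropped += 1
            continue
        trip, age, length = assigned
        obs_length = length + rng.normal(0.0, growth.length_noise_sd_mm)
        obs_length = float(np.clip(obs_length, 1.0, max_length_mm))
        rows.append(
            {
                "fish_id": f"F{i:05d}",
                "collection_date": trip,
                "total_length_mm": round(obs_length, 1),
                "fork_length_mm": round(obs_length * 0.93, 1),
                "weight_g": round(1.1e-5 * obs_length**3.0, 1),
                "true_hatch_date": hatch,
                "true_settlement_date": settlement,
                "true_age_days": age,
                "true_pld_days": pld,
            }
        )
    fish = pd.DataFrame(rows)
    report = {"n_input": len(hatch_dates), "n_collected": len(fish), "n_dropped": n_dropped}
    if fish.empty:
        return fish, report

    n = len(fish)
    aged = np.zeros(n, dtype=bool)
    # Bernoulli thinning stratified by trip: one draw per record, same rate
    # in every trip, so trip-level aged fractions are unbiased.
    for trip in trips:
        mask = (fish["collection_date"] == trip).to_numpy()
        aged[mask] = rng.random(mask.sum()) < aged_fraction
    true_age = fish["true_age_days"].to_numpy(dtype=float)
    for c in ("count1", "count2", "count3"):
        noisy = true_age * (1.0 + error.count_cv * rng.standard_normal(n))
        counts = np.maximum(1, np.floor(noisy + 0.5)).astype(float)
        fish[c] = np.where(aged, counts, np.nan)
    pld_counted = aged & (rng.random(n) < pld_counted_fraction / max(aged_fraction, 1e-12))
    pld_counts = np.maximum(1, np.floor(
        rng.normal(error.pld_mean_days, error.pld_sd_days, size=n) + 0.5)).astype(float)
    fish["pre_settlement_count"] = np.where(pld_counted, pld_counts, np.nan)
    report["n_aged"] = int(aged.sum())
    report["n_pld_counted"] = int(pld_counted.sum())
    return fish, report


def generate_env_series(
    date_range: tuple[dt.date, dt.date],
    seed: int,
    sst_mean_C: float = 24.5,
    sst_amplitude_C: float = 3.5,
    sst_peak_doy: int = 32,
    sst_noise_sd_C: float = 0.3,
    rain_prob: float = 0.25,
    rain_shape: float = 0.6,
    rain_scale_mm: float = 18.0,
) -> pd.DataFrame:
    """Daily environmental table: date, sst_C, rainfall_mm, flood_height_m.

    SST is a sinusoid peaking at day-of-year ``sst_peak_doy`` (Feb 1 by
    default, a southern-hemisphere summer peak) plus Gaussian noise.
    Rainfall is a gamma mixture with dry days; flood height is an
    exponentially smoothed, saturating transform of recent rainfall.
    """
    lo, hi = date_range
    if hi < lo:
        raise ValueError("empty date_range")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(lo, hi, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    sst = (
        sst_mean_C
        + sst_amplitude_C * np.cos(2 * np.pi * (doy - sst_peak_doy) / 365.25)
        + (sst_noise_sd_C * rng.standard_normal(len(dates)) if sst_noise_sd_C > 0 else 0.0)
    )
    wet = rng.random(len(dates)) < rain_prob
    rain = np.where(wet, rng.gamma(rain_shape, rain_scale_mm, size=len(dates)), 0.0)
    flood = np.zeros(len(dates))
    level = 0.0
    for i, r in enumerate(rain):
        level = 0.85 * level + 0.02 * r
        flood[i] = 1.5 * (1.0 - np.exp(-level))
    return pd.DataFrame(
        {
            "date": dates.date,
            "sst_C": np.round(sst, 3),
            "rainfall_mm": np.round(rain, 2),
            "flood_height_m": np.round(flood, 3),
        }
    )


def _study_regime(start_year: int) -> SpawningRegime:
    """One austral year of spawning: 1–2 summer-leaning pulses + background."""
    lo = dt.date(start_year, 7, 1)
    hi = dt.date(start_year + 1, 6, 30)
    comps = [
        (dt.date(start_year, 11, 10), 18.0, 1.0),
        (dt.date(start_year + 1, 2, 5), 25.0, 0.8),
    ]
    return SpawningRegime(comps, background_rate=0.15 / 365, date_range=(lo, hi))


def simulate_study(
    seed: int,
    n_fish: int = 1763,
    start_years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020),
    aged_fraction: float = 0.43,
    growth: GrowthModel | None = None,
    error: AgeingErrorModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full multi-year study: fish table + environmental table.

    Spawning follows 1–2 pulses per austral year (pulse spreads 18–25 d,
    so cohorts span roughly 1–4 months) over a weak year-round background.
    Each year is sampled by 2–3 trips placed in the following winter and
    autumn so both pulses are catchable below 250 mm.
    """
    growth = growth or GrowthModel()
    error = error or AgeingErrorModel()
    rng = np.random.default_rng(seed)
    per_year = np.floor(np.full(len(start_years), n_fish / len(start_years))).astype(int)
    per_year[: n_fish - per_year.sum()] += 1

    all_fish = []
    reports = []
    for k, (y, ny) in enumerate(zip(start_years, per_year)):
        regime = _study_regime(y)
        hatches = sample_hatch_dates(regime, int(ny), int(rng.integers(2**31 - 1)))
        n_trips = 2 + (k % 2)  # alternate 2 and 3 trips per year
        trips = [dt.date(y + 1, 3, 15), dt.date(y + 1, 6, 10), dt.date(y + 1, 9, 5)][:n_trips]
        fish, rep = realize_fish(
            hatches, growth, error, trips, int(rng.integers(2**31 - 1)),
            aged_fraction=aged_fraction,
        )
        all_fish.append(fish)
        reports.append(rep)
    fish = pd.concat(all_fish, ignore_index=True)
    fish["fish_id"] = [f"F{i:05d}" for i in range(len(fish))]
    env = generate_env_series(
        (dt.date(start_years[0], 7, 1), dt.date(start_years[-1] + 2, 9, 30)),
        seed=int(rng.integers(2**31 - 1)),
    )
    report = {
        "per_year": reports,
        "n_collected": int(len(fish)),
        "n_aged": int(sum(r.get("n_aged", 0) for r in reports)),
    }
    return fish, env, report
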