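"""Replicate increment-count QC, pelagic larval duration, and hatch-date
back-calculation.

Post-settlement age of a juvenile is read three times from the daily
growth increments between the settlement mark and the otolith edge. The
three counts are accepted when each lies within 10% of their median
(inclusive), and the accepted age is their arithmetic mean. The pelagic
larval duration (PLD) — days between hatching and settlement — is
estimated as the mean of pre-settlement increment counts (primordium to
settlement mark) over the fish for which that count exists.

Back-calculation then walks the calendar backwards:

    settlement_date = collection_date − round(post_settlement_age)
    hatch_date      = settlement_date − round(mean_PLD)

Ages are rounded half-up to whole days before the subtraction (calendar
dates are integral); embryonic development (≈ half a day) is deliberately
not accounted for.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCResult",
    "qc_counts",
    "estimate_pld",
    "back_calculate",
    "age_fish_table",
    "FISH_COLUMNS",
]

#: Canonical fish-table schema (delimited text, ISO dates, lengths in mm).
FISH_COLUMNS = [
    "fish_id",
    "collection_date",
    "total_length_mm",
    "fork_length_mm",
    "weight_g",
    "count1",
    "count2",
    "count3",
    "pre_settlement_count",
]

MAX_TOTAL_LENGTH_MM = 250.0
QC_TOLERANCE = 0.10  # |count − median| / median, inclusive


@dataclass
class QCResult:
    """Outcome of the three-count quality rule."""

    accepted: bool
    mean_age_days: float | None
    offending_counts: list[int] = field(default_factory=list)


def qc_counts(counts, tolerance: float = QC_TOLERANCE) -> QCResult:
    """Apply the 10%-of-median rule to exactly three replicate counts.

    Accepts when every count c satisfies |c − median| / median <= tolerance
    (boundary inclusive); the accepted age is the arithmetic mean of the
    three counts. Otherwise the deviating counts are reported.

    Raises ValueError unless exactly three strictly positive counts are
    given — callers flag such records un-ageable rather than propagate the
    exception.
    """
    counts = list(counts)
    if len(counts) != 3:
        raise ValueError(f"qc_counts requires exactly three counts, got {len(counts)}")
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be strictly positive")
    med = float(np.median(counts))
    offending = [c for c in counts if abs(c - med) / med > tolerance]
    if offending:
        return QCResult(False, None, offending)
    return QCResult(True, float(np.mean(counts)))


def estimate_pld(pre_settlement_counts) -> tuple[float, float, int]:
    """Sample mean and s.d. of pre-settlement increment counts.

    Returns (mean_days, sd_days, n). The study's 70 counted fish gave
    27.9 ± 1.6 d. Requires n >= 2 (sd undefined below that).
    """
    counts = np.asarray(
        [c for c in pre_settlement_counts if c is not None and not (isinstance(c, float) and math.isnan(c))],
        dtype=float,
    )
    n = counts.size
    if n < 2:
        raise ValueError(f"PLD estimation needs at least 2 counts, got {n}")
    return float(counts.mean()), float(counts.std(ddof=1)), int(n)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def back_calculate(
    collection_date: dt.date, post_settlement_age_days: float, mean_pld_days: float
) -> tuple[dt.date, dt.date]:
    """Settlement and hatch dates from collection date, age and mean PLD.

    Both the age and the mean PLD are rounded half-up to whole days before
    the calendar subtraction. A hatch date after the collection date
    signals a corrupt age and raises.
    """
    if post_settlement_age_days < 0 or mean_pld_days < 0:
        raise ValueError("age and PLD must be non-negative")
    settlement = collection_date - dt.timedelta(days=_round_half_up(post_settlement_age_days))
    hatch = settlement - dt.timedelta(days=_round_half_up(mean_pld_days))
    if hatch > collection_date:
        raise ValueError(f"hatch date {hatch} after collection date {collection_date}")
    return settlement, hatch


def age_fish_table(
    fish: pd.DataFrame,
    mean_pld_days: float | None = None,
    tolerance: float = QC_TOLERANCE,
) -> tuple[pd.DataFrame, dict]:
    """Run QC + PLD estimation + back-calculation over a fish table.

    Parameters
    ----------
    fish
        Table with the `FISH_COLUMNS` schema; count columns may be blank
        for non-aged fish.
    mean_pld_days
        Override for the mean PLD; when None it is estimated from the
        table's own pre-settlement counts.

    Returns the table with derived columns
    (``aged``, ``qc_rejected``, ``post_settlement_age_days``, ``pld_days``,
    ``settlement_date``, ``hatch_date``) plus a report dict with counts of
    aged / rejected / un-ageable fish and the PLD used.
    """
    out = fish.copy()
    n = len(out)
    ages = np.full(n, np.nan)
    rejected = np.zeros(n, dtype=bool)
    aged = np.zeros(n, dtype=bool)

    count_cols = ["count1", "count2", "count3"]
    for i, row in enumerate(out.itertuples(index=False)):
        counts = [getattr(row, c) for c in count_cols]
        counts = [c for c in counts if c is not None and not pd.isna(c)]
        if len(counts) != 3:
            continue  # un-ageable: fewer than three replicate counts
        res = qc_counts(counts, tolerance)
        if res.accepted:
            ages[i] = res.mean_age_days
            aged[i] = True
        else:
            rejected[i] = True

    if mean_pld_days is None:
        mean_pld, sd_pld, n_pld = estimate_pld(out.get("pre_settlement_count", pd.Series(dtype=float)))
    else:
        mean_pld, sd_pld, n_pld = float(mean_pld_days), float("nan"), 0

    out["aged"] = aged
    out["qc_rejected"] = rejected
    out["post_settlement_age_days"] = ages
    out["pld_days"] = np.where(aged, mean_pld, np.nan)

    settlement = np.full(n, pd.NaT, dtype=object)
    hatch = np.full(n, pd.NaT, dtype=object)
    coll = pd.to_datetime(out["collection_date"]).dt.date.to_numpy()
    for i in range(n):
        if aged[i]:
            s, h = back_calculate(coll[i], float(ages[i]), mean_pld)
            settlement[i], hatch[i] = s, h
    out["settlement_date"] = settlement
    out["hatch_date"] = hatch

    report = {
        "n_records": n,
        "n_aged": int(aged.sum()),
        "n_qc_rejected": int(rejected.sum()),
        "n_unageable": int(n - aged.sum() - rejected.sum()),
        "mean_pld_days": mean_pld,
        "sd_pld_days": sd_pld,
        "n_pld": n_pld,
    }
    return out, report
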