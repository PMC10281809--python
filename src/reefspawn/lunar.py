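"""Low-precision lunar ephemeris: illuminated fraction and new-moon dates.

Geocentric ecliptic longitudes of the Sun and Moon are computed from
truncated trigonometric series (Meeus-style, the largest periodic terms
only). The resulting elongation is accurate to a fraction of a degree,
which bounds the error of the illuminated fraction well below 0.01 —
ample for averaging illumination over 5-day bins and for locating new
moons to within an hour.

All public entry points accept naive datetimes interpreted as UTC plus an
explicit ``shift_hours`` offset (default +10 h, Australian Eastern
Standard Time), so "the new moon of 4 December" means the civil date in
Queensland on which the syzygy instant falls.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Iterable

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["illuminated_fraction", "phase_angle_deg", "new_moons", "SYNODIC_MONTH_DAYS"]

SYNODIC_MONTH_DAYS = 29.530588

_J2000 = dt.datetime(2000, 1, 1, 12, 0, 0)


def _julian_centuries(instant: dt.datetime) -> float:
    delta = instant - _J2000
    days = delta.days + delta.seconds / 86400.0 + delta.microseconds / 86.4e9
    return days / 36525.0


def _sun_longitude_deg(T: float) -> float:
    # Geometric mean longitude and equation of centre, two terms.
    L0 = 280.46646 + 36000.76983 * T
    M = math.radians(357.52911 + 35999.05029 * T)
    C = 1.914602 * math.sin(M) + 0.019993 * math.sin(2 * M) + 0.000289 * math.sin(3 * M)
    return (L0 + C) % 360.0


def _moon_position_deg(T: float) -> tuple[float, float]:
    """Ecliptic longitude and latitude of the Moon, main periodic terms."""
    Lp = 218.3164477 + 481267.88123421 * T  # mean longitude
    D = math.radians(297.8501921 + 445267.1114034 * T)  # mean elongation
    M = math.radians(357.5291092 + 35999.0502909 * T)  # sun mean anomaly
    Mp = math.radians(134.9633964 + 477198.8675055 * T)  # moon mean anomaly
    F = math.radians(93.2720950 + 483202.0175233 * T)  # argument of latitude

    lon = (
        Lp
        + 6.288774 * math.sin(Mp)
        + 1.274027 * math.sin(2 * D - Mp)
        + 0.658314 * math.sin(2 * D)
        + 0.213618 * math.sin(2 * Mp)
        - 0.185116 * math.sin(M)
        - 0.114332 * math.sin(2 * F)
        + 0.058793 * math.sin(2 * D - 2 * Mp)
        + 0.057066 * math.sin(2 * D - M - Mp)
        + 0.053322 * math.sin(2 * D + Mp)
        + 0.045758 * math.sin(2 * D - M)
        - 0.040923 * math.sin(M - Mp)
        - 0.034720 * math.sin(D)
        - 0.030383 * math.sin(M + Mp)
    )
    lat = (
        5.128122 * math.sin(F)
        + 0.280602 * math.sin(Mp + F)
        + 0.277693 * math.sin(Mp - F)
        + 0.173237 * math.sin(2 * D - F)
    )
    return lon % 360.0, lat


def phase_angle_deg(instant: dt.datetime, shift_hours: float = 10.0) -> float:
    """Selenocentric phase angle (deg): 0 at full moon, 180 at new moon.

    ``instant`` is local time; the shift converts it back to UTC before
    evaluating the ephemeris.
    """
    utc = instant - dt.timedelta(hours=shift_hours)
    T = _julian_centuries(utc)
    lam_sun = _sun_longitude_deg(T)
    lam_moon, beta_moon = _moon_position_deg(T)
    # Elongation-derived phase angle; lunar distance variation contributes
    # < 0.005 to the illuminated fraction and is neglected.
    cos_psi = math.cos(math.radians(beta_moon)) * math.cos(math.radians(lam_moon - lam_sun))
    psi = math.degrees(math.acos(max(-1.0, min(1.0, cos_psi))))
    return 180.0 - psi


def illuminated_fraction(instant: dt.datetime, shift_hours: float = 10.0) -> float:
    """Fraction of the lunar disc illuminated at a local instant, in [0, 1].

    k = (1 + cos i)/2 with i the phase angle: 0 at new moon, 1 at full.
    """
    i = math.radians(phase_angle_deg(instant, shift_hours))
    return (1.0 + math.cos(i)) / 2.0


def mean_illumination(day: dt.date, shift_hours: float = 10.0, samples_per_day: int = 8) -> float:
    """Daily mean illuminated fraction (local civil day)."""
    vals = [
        illuminated_fraction(
            dt.datetime(day.year, day.month, day.day) + dt.timedelta(hours=24.0 * k / samples_per_day),
            shift_hours,
        )
        for k in range(samples_per_day)
    ]
    return float(np.mean(vals))


def _refine_new_moon(guess: dt.datetime, shift_hours: float) -> dt.datetime:
    """Minimise illumination near a coarse guess; returns local instant."""

    def obj(hours: float) -> float:
        return illuminated_fraction(guess + dt.timedelta(hours=hours), shift_hours)

    res = minimize_scalar(obj, bounds=(-36.0, 36.0), method="bounded",
                          options={"xatol": 1e-3})
    return guess + dt.timedelta(hours=float(res.x))


def new_moons(start: dt.date, end: dt.date, shift_hours: float = 10.0) -> list[dt.date]:
    """Local civil dates of new moons in the closed range [start, end].

    Scans daily illumination for local minima, then refines each syzygy
    instant by bounded minimisation. Consecutive results are one synodic
    month (29.27–29.83 d) apart.
    """
    if end < start:
        raise ValueError("end before start")
    # Pad the scan so moons just outside the range anchor the search.
    scan_start = start - dt.timedelta(days=2)
    n_days = (end - scan_start).days + 5
    days = [scan_start + dt.timedelta(days=i) for i in range(n_days)]
    illum = np.array([
        illuminated_fraction(dt.datetime(d.year, d.month, d.day, 12), shift_hours) for d in days
    ])
    moons: list[dt.date] = []
    for i in range(1, len(days) - 1):
        if illum[i] <= illum[i - 1] and illum[i] < illum[i + 1] and illum[i] < 0.05:
            instant = _refine_new_moon(dt.datetime(days[i].year, days[i].month, days[i].day, 12), shift_hours)
            d = instant.date()
            if start <= d <= end and (not moons or (d - moons[-1]).days > 15):
                moons.append(d)
    return moons


def mean_illumination_series(dates: Iterable[dt.date], shift_hours: float = 10.0) -> np.ndarray:
    """Vector of daily mean illuminated fractions for an iterable of dates."""
    return np.array([mean_illumination(d, shift_hours) for d in dates])
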