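"""Smooth one austral year of hatch dates and find spawning peaks.

Bins hatch dates into 5-day windows (July-June austral year), fits the
Tweedie penalized-spline smooth, and reports peaks from the first
derivative of the fitted curve.
"""

import datetime as dt

import numpy as np

from reefspawn import (
    SpawningRegime,
    bin_hatch_dates,
    detect_peaks,
    fit_spawning_smooth,
    sample_hatch_dates,
    summarize_peaks,
)

regime = SpawningRegime(
    components=[(dt.date(2020, 11, 1), 12.0, 1.0), (dt.date(2021, 2, 9), 12.0, 1.0)],
    background_rate=0.0,
    date_range=(dt.date(2020, 7, 1), dt.date(2021, 6, 30)),
)
series = bin_hatch_dates(sample_hatch_dates(regime, 500, seed=6), austral_year=2020)
print(f"austral year 2020: {series.total} fish in {len(series.counts)} five-day bins")

fit = fit_spawning_smooth(series)
print(f"Tweedie power p={fit.tweedie_power_p:.2f}, edf={fit.edf:.1f}, "
      f"deviance explained {100 * fit.deviance_explained:.1f}%")
print(f"mean fitted activity {np.mean(fit.fitted):.2f} fish per 5-day bin")

peaks = detect_peaks(fit, series, seed=6)
for p in peaks:
    print(f"peak {p.date}: {p.height:.1f} fish/bin (95% {p.ci95[0]:.1f}..{p.ci95[1]:.1f})")
print(summarize_peaks({2020: peaks}, {2020: fit}).to_string(index=False))
# Two pulses 100 days apart should appear as two peaks near Nov 1 and
# Feb 9, and a strong-signal year explains >80% of the null deviance.
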