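# reefspawn

Spawning phenology of reef fish reconstructed from otolith daily
increments, and the evaluation of lunar-anchored seasonal fishery
closures against it.

Harvested coral groupers on the Great Barrier Reef are managed partly
through short fishing closures placed around the October–December new
moons, on the assumption that spawning concentrates there. This package
implements the analysis chain that tests that assumption from juvenile
collections: replicate otolith increment counts are quality-controlled
and turned into post-settlement ages, hatch dates are back-calculated
through the pelagic larval duration, ages of non-sectioned fish are
imputed from a cohort-aware age–length model, hatch-date counts are
smoothed per austral year, spawning peaks are read off the smooth's first
derivative, and the share of predicted spawning activity falling inside
closure windows is computed and modelled. A synthetic-data generator with
the same statistical structure as field collections makes every stage
testable end to end.

## Models

**Back-calculation.** Each aged fish has three replicate increment counts
accepted when every count is within 10% of their median (inclusive); the
post-settlement age is their mean. With mean pelagic larval duration
$\overline{PLD}$ (estimated from pre-settlement increment counts,
default-calibrated to 27.9 ± 1.6 d):

$$t_{settle} = t_{collect} - \mathrm{round}(age), \qquad
  t_{hatch} = t_{settle} - \mathrm{round}(\overline{PLD}).$$

**Age–length imputation.** For non-aged fish, post-settlement age is
predicted from total length by a hierarchical Gaussian model

$$age_i = \beta_0 + \beta_1 TL_i + \beta_2 TL_i^2 + \beta_3 TL_i^3
          + b_{c(i)} + \varepsilon_i,\quad
  b_c \sim N(0, \tau^2),\quad
  \varepsilon_i \sim N\!\big(0, e^{\lambda_0 + \lambda_1 TL_i + \delta_{c(i)}}\big),$$

with recruitment cohorts $c$ defined by a 30-day gap rule on hatch dates
and a log-linear dispersion model (ageing precision degrades with
length).

**Spawning curves and peaks.** Hatch dates are tallied into 5-day bins of
each austral year (July–June) and smoothed with a penalized-spline
Tweedie GAM on a log link,

$$y = \beta_0 + s(time) + \varepsilon, \qquad \varepsilon \sim Tw_p(\mu, \sigma^2),\; p \in (1,2),$$

the compound Poisson–gamma family that accommodates exact zeros in quiet
periods. Basis dimension, smoothing penalty and the power $p$ are chosen
by AICc. Peaks are + → − sign changes of the finite-difference first
derivative of the fitted curve on a daily grid. The environmental variant
replaces $s(time)$ with a tensor-product interaction of SST and a cyclic
month smooth plus a year random intercept, compared by AICc against
candidates with lunar-illumination and rainfall smooths, with pairwise
concurvity checks.

**Closure evaluation.** Closure windows of 5 or 9 days are centred on the
new moons (found by a built-in low-precision lunar ephemeris with a +10 h
east-Australian shift). The capture proportion of a year is the share of
predicted daily spawning activity in October–December falling on closed
days; under uniform spawning it equals closed days / 92 (27/92 ≈ 29% for
three 9-day closures, 10/92 ≈ 11% for two 5-day ones). Capture
proportions across years and designs are modelled by a Beta regression
(logit mean link) with a year random intercept.

## Worked example

`examples/` holds one short script per capability. The full chain on the
default synthetic study (`python examples/05_full_pipeline.py`) prints:

```
accounting: {
  "n_collected": 1751,
  "n_aged": 749,
  "n_imputed": 992,
  "n_analyzed": 1741,
  "identity_aged_plus_imputed_equals_analyzed": true
}

per-year peaks:
 austral_year  n_peaks               peak_dates     peak_heights separations_days
         2016        2 [2016-11-07, 2017-02-06]    [15.15, 9.65]           [91.0]
         ...

9-day vs 5-day capture ratio: 1.79 (uniform-activity expectation 9/5 = 1.8)
```

Reading this: of 1751 simulated collections, 749 fish were aged directly
and 992 got model-imputed ages (the accounting identity holds; the ~10
missing fish were QC-rejected or outside imputable range). Each year
shows spring and late-summer peaks roughly 90–100 days apart — where the
generator put its spawning pulses — and 9-day closures capture about 1.8×
the activity of 5-day ones, the ratio expected from closed days alone.

A thin CLI mirrors the stages (`reefspawn simulate`, `age`, `cohorts`,
`trends`, `report`; global `--seed`/`--config`).

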