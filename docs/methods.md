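# Methods

This note documents the models implemented in `reefspawn`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic studies do and do not demonstrate.

## Ageing and back-calculation

Post-settlement age is read three times per otolith; a triple is accepted
when every count satisfies |c − median| / median ≤ 0.10. The rule is
deliberately **inclusive at the boundary** (a closed condition), so
(90, 100, 110) is accepted. The accepted age is the arithmetic mean of
the three counts. Records with fewer than three counts are flagged
un-ageable rather than raising.

Pelagic larval duration (PLD) is the sample mean ± s.d. of
pre-settlement increment counts (primordium to settlement mark); the
generator's calibration is 27.9 ± 1.6 d. Back-calculation subtracts the
rounded age, then the rounded mean PLD, from the collection date. Ages
and the mean PLD are **rounded half-up to whole days** before the
calendar subtraction — dates are integral, and a single population-mean
PLD is subtracted for every fish. Embryonic duration (≈ half a day) is
knowingly ignored; it shifts every hatch date equally and cannot affect
peak timing comparisons. Cross-observer validation of counts is a
laboratory QA step and is out of computational scope.

## Cohorts and the age–length model

Recruitment cohorts are defined by a deterministic gap rule: sorted hatch
dates of aged fish are split wherever consecutive dates are more than
`gap_days` (default 30) apart. This replaces visual identification for
reproducibility; the default is long enough to bridge within-pulse gaps
at realistic sample sizes yet shorter than the spacing of distinct
pulses.

The age–length model is a hierarchical Gaussian regression: a cubic
polynomial in total length, a cohort random intercept
(b_c ~ N(0, τ²)), and a log-linear dispersion model in total length plus
per-cohort offsets (recentred to mean zero). The random effect is
intercept-only — nothing in the data structure motivates random slopes.
The marginal likelihood is maximized directly with L-BFGS; each cohort's
covariance is diagonal-plus-rank-one, handled by the Woodbury and
matrix-determinant identities, so the likelihood costs O(n) per
evaluation. The cubic is fitted on an orthogonalized (QR) basis of
standardized length for conditioning and mapped back to raw-scale
coefficients; their covariance comes from the numerical Hessian at the
optimum. If τ̂ collapses below 10⁻³ of the response s.d. the hierarchy is
singular and the model is refitted without the random effect, flagged in
the result.

Predictions: cohort-conditional means add the cohort's BLUP; "marginal"
predictions average over cohorts (zero-mean effects) and use τ² as the
random-effect variance. Intervals combine fixed-effect variance, the
fitted residual variance at that length/cohort, and random-effect
variance. Lengths outside the observed range ± 10% **refuse to predict**:
cubics diverge under extrapolation. Non-aged fish collected in periods
with no aged fish at all are dropped and reported — the age–length
relationship cannot be validated for them.

Cohort assignment of non-aged fish maps a collection date to the cohort
whose plausible collection interval (hatch window shifted by PLD plus the
min–max observed post-settlement age) contains it; overlaps resolve to
the nearest expected collection midpoint, exact ties to the earlier
cohort, and dates outside all intervals to the marginal prediction.

## Tweedie penalized-spline smooths

Hatch dates are binned into 73 contiguous 5-day windows anchored at
July 1; the last bin absorbs the leap day. The austral-year anchor keeps
the southern summer spawning season unsplit. Binned counts are smoothed
with Eilers–Marx P-splines (cubic B-spline basis, second-order difference
penalty) under a Tweedie family with log link, fitted by penalized IRLS.
The Tweedie power p ∈ (1, 2) makes the response a compound Poisson–gamma:
exact zeros in quiet periods with continuous positive mass otherwise.

Model selection: the smoothing parameter is chosen by coordinate descent
on AICc over a log-spaced grid; the basis dimension over {8, 12, 16, 20};
p is profiled on 10 grid points in (1.05, 1.95) and refined locally. The
effective number of parameters in AICc is the trace of the hat matrix
plus two (dispersion and the profiled power). The Tweedie log-likelihood
is statsmodels' Dunn–Smyth series; where the series overflows (very small
dispersion, e.g. near-interpolating fits) a saddle-point approximation of
the same density is substituted so that selection remains defined.
Dispersion is estimated by Pearson χ² / (n − edf). A small conditioning
ridge (10⁻⁸ of the mean diagonal) keeps the penalized system solvable
when IRLS weights collapse in all-zero stretches.

Numerical caveat: in long all-zero runs the log-link mean is driven to
zero and the unpenalized null space of the difference penalty lets the
linear predictor drift (quasi-separation); fits converge by deviance
tolerance and the fitted curve is effectively zero there, but the
intercept alone is not interpretable in such years — the fitted curve is.

**Peaks** are + → − sign changes of the finite-difference first
derivative of the fitted curve on a daily grid with a negative second
difference, excluding the first and last 10 days of the year (derivative
artifacts at spline boundaries). A relative tolerance of 10⁻⁶ of the
curve maximum keeps numerically flat fits peak-free. Peak-height 95%
intervals come from 200 seeded draws of the coefficient posterior
N(β̂, V̂β) of the penalized fit. Years with fewer than 30 usable fish are
excluded from smoothing and reported — small-sample smooths are unstable.

## Environmental model

Covariates are aligned to the same 5-day bins: SST as 8-day block
averages (the night-time satellite product convention) mapped to the bin
midpoint, with linear interpolation across gaps up to 16 days (longer
gaps flag the bin out of the model); rainfall summed; lunar illumination
averaged over the bin with a +10 h shift to east-Australian time.

Lunar illumination is computed from a truncated Meeus-style series for
the solar and lunar ecliptic longitudes and latitude: the illuminated
fraction is (1 + cos i)/2 with i the elongation-derived phase angle.
Sub-degree longitude accuracy bounds the illumination error well below
0.01, which is ample for 5-day averages; new moons are daily illumination
minima refined by bounded scalar minimization. Validated spacing is
29.27–29.83 d (synodic month 29.53 d).

The environmental smooth is y = β0 + s(SST|Month) + γ_year + ε with
s(SST|Month) a tensor-product of a cubic SST smooth (k = 6) and a cyclic
month smooth (k = 6, period 12; wrapped basis and circular penalty), each
margin carrying its own penalty, and γ_year a ridge-penalized year
intercept. Candidates with lunar-illumination and rainfall smooths, and
the intercept + year null, are compared by AICc; the selected model is
the arg-min by construction. Pairwise concurvity — the R² of projecting
one term's centred design onto another's column space — is computed for
all candidate covariates including flood height; pairs above 0.7 are
flagged. Flood-gauge data are ingested but excluded from the default
candidate set: seasonal flood series are largely reproducible from SST
and month, which is precisely what the concurvity check exposes.

## Closure evaluation

The season is fixed at October 1 – December 31 (92 days), the window the
expected-capture arithmetic refers to (27/92 ≈ 29%, 10/92 ≈ 11%).
Windows are centred on the new moon (9-day: ±4 d; 5-day: ±2 d) with a
configurable anchor offset, clipped to the season; when fewer closures
than moons are requested the earliest (October-first) moons are used.
Overlapping windows merge with a warning.

Capture proportion uses **model-predicted** daily activity from the
fitted spawning smooth, not raw binned counts (a raw-count diagnostic
mode exists): closures are judged against the estimated intensity, not
sampling noise. The statistic is invariant to rescaling the activity
curve and is monotone in window enlargement.

The capture model is a Beta regression with logit mean link, duration and
closure-count factors, and a year random intercept integrated by 15-node
Gauss–Hermite quadrature; proportions are pulled off the boundary by the
(y(n − 1) + 0.5)/n transform. Because that transform biases small
proportions upward by ≈ 0.5/n, predictions are reported after inverting
it, which restores e.g. the 9/5 = 1.8 uniform-activity duration ratio.
The duration × count interaction is tested by likelihood ratio and
dropped when non-significant. Pairwise closure-count contrasts are Wald
tests with Holm adjustment — the design is unbalanced across years, so
studentized-range (HSD) theory does not strictly apply. Optimizer failure
falls back to a fixed-effects Beta regression, logged.

## Synthetic data: what it emulates, and what not

The generator draws hatch dates from truncated-normal spawning pulses
(spreads 18–25 d by default, so pulses span roughly 1–4 months) over a
weak uniform background; juvenile growth is von Bertalanffy from 23 mm at
settlement toward a 520 mm asymptote at 0.0012 d⁻¹ (≈ 0.6 mm/d initially,
near-linear and invertible over the sampled 23–248 mm); replicate counts
carry a 3% CV — chosen so the 10% QC rule rejects a small minority of
triples; PLD is N(27.9, 1.6²); collections happen on 2–3 trips per year
with a 0.43 aged fraction (Bernoulli thinning within trips); SST is a
noisy sinusoid peaking Feb 1, rainfall a gamma mixture with dry days, and
flood height a saturating transform of recent rainfall. Generator truth
(hatch date, age, PLD) travels in `true_*` columns that analysis code
never reads.

Not emulated: spatial structure and larval dispersal, parentage,
otolith-reader drift between laboratories, satellite SST gaps and
retrieval artifacts, and any environment→spawning causality beyond what a
test injects. Passing tests therefore demonstrate statistical
correctness of the chain under its own assumptions — not that field data
meet those assumptions.

## Problem sizes and determinism

Default study simulations use 1763 fish over five austral years —
matching the scale the pipeline is designed for — and the repeated-fit
test studies use 300–700 fish per replicate with compact basis/power
grids, sizes at which parameter recovery is already comfortably inside
the asserted tolerances. All randomness flows from explicit integer
seeds: generator streams, peak-CI draws and quadrature are seeded, and
identical seeds reproduce byte-identical numeric outputs.

## Known limitations

- The intercept of a spawning smooth is not interpretable in years whose
  season is mostly empty (quasi-separation; see above); fitted curves and
  peaks are.
- AICc mixing exact-series and saddle-point Tweedie log-likelihoods is
  inconsistent only in the rare fits where the series overflows; such
  fits are near-interpolating and would be rejected by AICc regardless.
- Concurvity uses the observed-projection estimate; it can understate
  worst-case confounding relative to basis-wise bounds.
- The Beta mixed model's non-adaptive quadrature is accurate for the
  moderate random-effect variances seen here; extreme year heterogeneity
  would warrant adaptive quadrature.
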