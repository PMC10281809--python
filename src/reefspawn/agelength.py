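"""Cohort-aware age–length modelling for imputing ages of non-aged fish.

Recruitment cohorts are temporally discrete clusters of hatch dates; they
are defined here by a deterministic gap rule (consecutive hatch dates more
than ``gap_days`` apart split cohorts) replacing visual identification.

The age–length relationship is a hierarchical Gaussian model:

    age_i = β0 + β1·TL_i + β2·TL_i² + β3·TL_i³ + b_{cohort(i)} + ε_i
    b_g ~ N(0, τ²),   ε_i ~ N(0, exp(λ0 + λ1·TL_i + δ_{cohort(i)}))

i.e. a cubic polynomial in total length with a cohort random intercept and
a log-linear dispersion model in total length and cohort — ageing
precision degrades with length, and cohorts differ in early growth. The
marginal likelihood is maximised directly (the random intercept gives each
cohort a rank-one covariance, handled by the matrix-determinant lemma).
The cubic is fitted on an orthogonalized length basis for stability and
reported on the raw scale.

Non-aged fish collected inside a cohort's plausible collection interval
get that cohort's conditional prediction; fish outside all intervals get
the marginal (cohort-averaged) prediction. Lengths outside the observed
range (±10%) refuse to predict — cubics diverge under extrapolation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "CohortWindow",
    "AgeLengthFit",
    "define_cohorts",
    "fit_age_length",
    "assign_cohort",
    "predict_age",
    "MARGINAL",
]

MARGINAL = "marginal"


@dataclass
class CohortWindow:
    cohort_id: str
    start_date: dt.date
    end_date: dt.date

    @property
    def midpoint(self) -> dt.date:
        return self.start_date + (self.end_date - self.start_date) / 2


def define_cohorts(hatch_dates, gap_days: int = 30) -> list[CohortWindow]:
    """Split sorted hatch dates into cohorts wherever consecutive dates are
    more than gap_days apart. Windows span min–max hatch date of members."""
    dates = sorted(
        d.date() if isinstance(d, (pd.Timestamp, dt.datetime)) else d
        for d in hatch_dates
        if d is not None and not pd.isna(d)
    )
    if len(dates) < 2:
        if len(dates) == 1:
            return [CohortWindow("C1", dates[0], dates[0])]
        raise ValueError("need at least one hatch date")
    windows = []
    start = prev = dates[0]
    for d in dates[1:]:
        if (d - prev).days > gap_days:
            windows.append((start, prev))
            start = d
        prev = d
    windows.append((start, prev))
    return [CohortWindow(f"C{i + 1}", s, e) for i, (s, e) in enumerate(windows)]


def _cohort_of_hatch(hatch: dt.date, cohorts: list[CohortWindow]) -> str | None:
    for c in cohorts:
        if c.start_date <= hatch <= c.end_date:
            return c.cohort_id
    return None


@dataclass
class AgeLengthFit:
    """Fitted hierarchical cubic age–length model."""

    fixed_coefficients: np.ndarray  # raw-scale: intercept, TL, TL², TL³
    fixed_cov: np.ndarray
    cohort_effects: dict  # cohort_id -> BLUP random intercept (days)
    cohort_sd: float  # τ
    dispersion_coefficients: dict  # {"intercept": λ0, "tl_slope": λ1(per std. TL), "cohort": {id: δ}}
    length_range: tuple[float, float]
    length_center: float
    length_scale: float
    cohort_ids: list
    cohort_shrinkage: dict  # cohort_id -> conditional variance of b_g
    random_effect_dropped: bool = False
    diagnostics: dict = field(default_factory=dict)
    loglik: float = float("nan")

    def mean_curve(self, total_length_mm) -> np.ndarray:
        tl = np.atleast_1d(np.asarray(total_length_mm, dtype=float))
        R = np.vander(tl, 4, increasing=True)
        return R @ self.fixed_coefficients

    def residual_variance(self, total_length_mm, cohort_id) -> np.ndarray:
        tl = np.atleast_1d(np.asarray(total_length_mm, dtype=float))
        z = (tl - self.length_center) / self.length_scale
        d = self.dispersion_coefficients
        delta = d["cohort"].get(cohort_id, 0.0) if cohort_id != MARGINAL else float(
            np.mean(list(d["cohort"].values()))
        )
        return np.exp(d["intercept"] + d["tl_slope"] * z + delta)


def _design_std(tl: np.ndarray, center: float, scale: float) -> np.ndarray:
    z = (tl - center) / scale
    return np.vander(z, 4, increasing=True)


def _nll_factory(y, Q, z, groups, group_index, drop_random: bool):
    """Marginal Gaussian negative log-likelihood.

    θ = [β(4), λ0, λ1, δ_2..δ_G, log τ]; δ_1 ≡ 0 for identifiability.
    Per cohort, V = diag(exp(·)) + τ²·11ᵀ; the quadratic form and log-det
    use the rank-one Woodbury/determinant identities.
    """
    G = len(groups)

    def nll(theta):
        beta = theta[:4]
        lam0, lam1 = theta[4], theta[5]
        deltas = np.concatenate([[0.0], theta[6 : 6 + G - 1]])
        tau2 = 0.0 if drop_random else np.exp(2.0 * theta[-1])
        r = y - Q @ beta
        logvar = lam0 + lam1 * z + deltas[group_index]
        logvar = np.clip(logvar, -20, 20)
        d = np.exp(logvar)
        total = 0.0
        for g in range(G):
            m = group_index == g
            rg, dg = r[m], d[m]
            s = np.sum(1.0 / dg)
            alpha = np.sum(rg / dg)
            quad = np.sum(rg**2 / dg)
            logdet = np.sum(np.log(dg))
            if tau2 > 0:
                quad -= tau2 * alpha**2 / (1.0 + tau2 * s)
                logdet += np.log1p(tau2 * s)
            total += 0.5 * (quad + logdet)
        return total + 0.5 * len(y) * np.log(2 * np.pi)

    return nll


def fit_age_length(aged: pd.DataFrame, cohorts: list[CohortWindow]) -> AgeLengthFit:
    """Fit the hierarchical cubic age–length model by marginal ML.

    ``aged`` needs columns total_length_mm, post_settlement_age_days and
    hatch_date. Requires >= 2 cohorts with >= 5 aged fish each. If the
    cohort variance collapses (τ → 0, singular hierarchy) the model falls
    back to a fixed-intercept-only fit, flagged in the result.
    """
    df = aged.copy()
    df["_cohort"] = [
        _cohort_of_hatch(
            h.date() if isinstance(h, (pd.Timestamp, dt.datetime)) else h, cohorts
        )
        for h in df["hatch_date"]
    ]
    df = df[df["_cohort"].notna()]
    sizes = df["_cohort"].value_counts()
    usable = sizes[sizes >= 5].index.tolist()
    if len(usable) < 2:
        raise ValueError("need at least 2 cohorts with >= 5 aged fish each")
    df = df[df["_cohort"].isin(usable)]
    order = [c.cohort_id for c in cohorts if c.cohort_id in usable]
    group_index = np.array([order.index(g) for g in df["_cohort"]])
    tl = df["total_length_mm"].to_numpy(dtype=float)
    y = df["post_settlement_age_days"].to_numpy(dtype=float)
    center, scale = float(tl.mean()), float(tl.std() or 1.0)
    z = (tl - center) / scale
    Rz = _design_std(tl, center, scale)
    Q, Rmat = np.linalg.qr(Rz)
    Q *= np.sqrt(len(y))
    Rmat /= np.sqrt(len(y))

    G = len(order)
    beta0, *_ = np.linalg.lstsq(Q, y, rcond=None)
    resid = y - Q @ beta0
    theta0 = np.concatenate([beta0, [np.log(resid.var() + 1e-6), 0.0], np.zeros(G - 1), [np.log(max(resid.std(), 1.0) * 0.3)]])

    nll = _nll_factory(y, Q, z, order, group_index, drop_random=False)
    res = minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": 500})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"age-length optimizer failed: {res.message}")

    tau = float(np.exp(res.x[-1]))
    dropped = False
    if tau < 1e-3 * max(y.std(), 1.0):
        # singular cohort variance: refit without the random effect
        nll_f = _nll_factory(y, Q, z, order, group_index, drop_random=True)
        res = minimize(nll_f, res.x, method="L-BFGS-B", options={"maxiter": 500})
        tau = 0.0
        dropped = True
        nll = nll_f

    theta = res.x
    beta_orth = theta[:4]
    lam0, lam1 = float(theta[4]), float(theta[5])
    deltas = np.concatenate([[0.0], theta[6 : 6 + G - 1]])
    # recenter dispersion offsets so the cohort factor averages to zero
    dbar = float(deltas.mean())
    lam0 += dbar
    deltas = deltas - dbar

    # raw-scale coefficients: mean curve is in standardized length z
    Rinv = np.linalg.inv(Rmat)
    beta_std = Rinv @ beta_orth  # coefficients on [1, z, z², z³]
    # convert polynomial in z=(TL−c)/s to polynomial in TL
    c, s = center, scale
    T = np.zeros((4, 4))
    for j in range(4):  # z^j = ((TL − c)/s)^j expanded in TL powers
        for i in range(j + 1):
            T[i, j] = math.comb(j, i) * ((-c) ** (j - i)) / (s**j)
    beta_raw = T @ beta_std

    # covariance of fixed coefficients from the numerical Hessian
    try:
        Hess = approx_hess1(theta, nll)
        cov_theta = np.linalg.inv(Hess)
        cov_orth = cov_theta[:4, :4]
    except np.linalg.LinAlgError:
        cov_orth = np.full((4, 4), np.nan)
    cov_std = Rinv @ cov_orth @ Rinv.T
    cov_raw = T @ cov_std @ T.T

    # BLUPs of cohort intercepts and their conditional variances
    r = y - Q @ beta_orth
    logvar = np.clip(lam0 + lam1 * z + deltas[group_index], -20, 20)
    d = np.exp(logvar)
    tau2 = tau**2
    blups, shrink = {}, {}
    for g, gid in enumerate(order):
        m = group_index == g
        ssum = np.sum(1.0 / d[m])
        alpha = np.sum(r[m] / d[m])
        blups[gid] = float(tau2 * alpha / (1.0 + tau2 * ssum)) if tau2 > 0 else 0.0
        shrink[gid] = float(tau2 / (1.0 + tau2 * ssum)) if tau2 > 0 else 0.0

    # diagnostics: heteroscedasticity capture and mean-curve monotonicity
    std_res = (r - np.array([blups[order[g]] for g in group_index])) / np.sqrt(d + tau2)
    het_corr = float(np.corrcoef(np.abs(std_res), tl)[0, 1])
    grid = np.linspace(tl.min(), tl.max(), 200)
    mean_grid = np.vander(grid, 4, increasing=True) @ beta_raw
    monotone = bool(np.all(np.diff(mean_grid) >= -1e-9))

    return AgeLengthFit(
        fixed_coefficients=beta_raw,
        fixed_cov=cov_raw,
        cohort_effects=blups,
        cohort_sd=tau,
        dispersion_coefficients={"intercept": lam0, "tl_slope": lam1, "cohort": dict(zip(order, deltas))},
        length_range=(float(tl.min()), float(tl.max())),
        length_center=center,
        length_scale=scale,
        cohort_ids=order,
        cohort_shrinkage=shrink,
        random_effect_dropped=dropped,
        diagnostics={
            "abs_resid_length_corr": het_corr,
            "mean_curve_monotone": monotone,
            "n_fit": int(len(y)),
            "converged": bool(res.success),
        },
        loglik=-float(res.fun),
    )


def assign_cohort(
    collection_date: dt.date,
    cohorts: list[CohortWindow],
    age_range_days: tuple[float, float],
    mean_pld_days: float,
) -> str:
    """Map a collection date to the cohort whose plausible collection
    interval contains it.

    A cohort hatched in [start, end] is catchable between
    start + PLD + min observed age and end + PLD + max observed age. Ties
    (date in several intervals) go to the cohort with the nearest expected
    collection midpoint, earlier cohort winning exact ties. Dates outside
    all intervals map to "marginal".
    """
    lo_age, hi_age = age_range_days
    hits = []
    for c in cohorts:
        lo = c.start_date + dt.timedelta(days=int(np.floor(mean_pld_days + lo_age)))
        hi = c.end_date + dt.timedelta(days=int(np.ceil(mean_pld_days + hi_age)))
        if lo <= collection_date <= hi:
            expected_mid = c.midpoint + dt.timedelta(days=mean_pld_days + (lo_age + hi_age) / 2)
            hits.append((abs((collection_date - expected_mid).days), c.start_date, c.cohort_id))
    if not hits:
        return MARGINAL
    hits.sort(key=lambda t: (t[0], t[1]))
    return hits[0][2]


def predict_age(
    fit: AgeLengthFit,
    total_length_mm: float,
    cohort_id: str = MARGINAL,
    length_tolerance: float = 0.10,
) -> tuple[float, tuple[float, float]]:
    """Predicted post-settlement age (days) with a 95% interval.

    Cohort-conditional predictions add that cohort's BLUP intercept; the
    marginal prediction averages over cohort effects (zero mean). The
    interval combines fixed-effect uncertainty, the fitted residual
    variance at this length and cohort, and random-effect variance
    (conditional shrinkage variance, or τ² for marginal predictions).
    Lengths outside the observed range ± tolerance raise (no cubic
    extrapolation).
    """
    lo, hi = fit.length_range
    span = hi - lo
    if not (lo - length_tolerance * span <= total_length_mm <= hi + length_tolerance * span):
        raise ValueError(
            f"length {total_length_mm} mm outside tolerated range "
            f"[{lo - length_tolerance * span:.1f}, {hi + length_tolerance * span:.1f}]"
        )
    R = np.vander(np.array([float(total_length_mm)]), 4, increasing=True)
    mean = float((R @ fit.fixed_coefficients)[0])
    if cohort_id != MARGINAL and cohort_id in fit.cohort_effects:
        mean += fit.cohort_effects[cohort_id]
        re_var = fit.cohort_shrinkage[cohort_id]
    else:
        cohort_id = MARGINAL
        re_var = fit.cohort_sd**2
    var = float((R @ fit.fixed_cov @ R.T)[0, 0]) if np.isfinite(fit.fixed_cov).all() else 0.0
    var += float(fit.residual_variance(total_length_mm, cohort_id)[0]) + re_var
    half = 1.96 * np.sqrt(var)
    return mean, (mean - half, mean + half)
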