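"""Method-agreement statistics for paired per-beat energies.

Implements the analysis chain applied to (stroke work, power integral)
pairs: per-animal regression through the origin with its uncentered R^2,
Bland-Altman limits of agreement, and a no-intercept mixed model with a
per-condition fixed slope and a per-animal random slope,

    y_ij = (beta_{c(ij)} + b_i) x_ij + eps_ij,
    b_i ~ N(0, tau^2),  eps_ij ~ N(0, sigma^2),

fitted by REML (ML optional) with a 1-D profile search over the variance
ratio lambda = tau^2/sigma^2.  The per-animal covariance is the rank-one
update sigma^2 (I + lambda x_i x_i^T), inverted in closed form, so the
fit is exact and fast for any group size.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError

REGRESSION_DIRECTIONS = ("pwr_on_sw", "sw_on_pwr")


@dataclasses.dataclass(frozen=True)
class OriginFitResult:
    """Least-squares line through the origin.

    ``r2_uncentered`` is the no-constant coefficient of determination
    (sum xy)^2 / (sum x^2 sum y^2); ``pearson_r`` is the conventional
    centered correlation, reported separately.
    """

    slope: float
    ci95_low: float
    ci95_high: float
    r2_uncentered: float
    n: int
    se: float
    pearson_r: float


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray
    diffs: np.ndarray


@dataclasses.dataclass(frozen=True)
class MixedFitResult:
    """No-intercept random-slope mixed-model fit."""

    conditions: tuple[str, ...]
    reference: str
    beta: dict[str, float]
    cov_beta: np.ndarray
    tau2: float
    sigma2: float
    wald_p: dict[str, float]
    lrt_p_random: float
    loglik: float
    method: str
    n_obs: int
    n_groups: int
    converged: bool
    direction: str = "pwr_on_sw"

    def se(self, condition: str) -> float:
        j = self.conditions.index(condition)
        return float(np.sqrt(self.cov_beta[j, j]))


def through_origin_fit(x: np.ndarray, y: np.ndarray) -> OriginFitResult:
    """Fit ``y = slope * x`` by least squares through the origin.

    slope = sum(xy)/sum(x^2); the 95% CI uses the through-origin OLS
    standard error with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape} and {y.shape}")
    n = len(x)
    if n < 2:
        raise FitError(f"need n >= 2 points, got {n}")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise FitError("degenerate fit: all x are zero")
    sxy = float(np.dot(x, y))
    syy = float(np.dot(y, y))
    slope = sxy / sxx
    resid = y - slope * x
    s2 = float(np.dot(resid, resid)) / (n - 1)
    se = math.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    if n >= 3 and np.std(x) > 0 and np.std(y) > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
    else:
        pearson = float("nan")
    return OriginFitResult(
        slope=slope,
        ci95_low=slope - tcrit * se,
        ci95_high=slope + tcrit * se,
        r2_uncentered=min(1.0, r2),
        n=n,
        se=se,
        pearson_r=pearson,
    )


def bland_altman(sw: np.ndarray, pwr: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of SW against the power integral.

    Differences are SW minus power integral (y-axis); the x-axis is the
    pairwise mean.  Limits of agreement are mean +/- 1.96 SD (SD with
    n-1 denominator).
    """
    sw = np.asarray(sw, dtype=float)
    pwr = np.asarray(pwr, dtype=float)
    if sw.shape != pwr.shape or sw.ndim != 1:
        raise ValueError(f"shape mismatch: sw {sw.shape} vs pwr {pwr.shape}")
    n = len(sw)
    if n < 2:
        raise FitError(f"need n >= 2 pairs, got {n}")
    diffs = sw - pwr
    means = 0.5 * (sw + pwr)
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n=n,
        means=means,
        diffs=diffs,
    )


def _reml_pieces(lam, xg, yg, Xg):
    """GLS accumulators at a fixed variance ratio lambda.

    Returns (A, c, logdet_V0, group inverse weights) where
    V0 = I + lam x x^T per group, A = sum X^T V0^-1 X, c = sum X^T V0^-1 y.
    """
    p = Xg[0].shape[1]
    A = np.zeros((p, p))
    c = np.zeros(p)
    logdet = 0.0
    for x, y, X in zip(xg, yg, Xg):
        sxx = float(np.dot(x, x))
        denom = 1.0 + lam * sxx
        # Sherman-Morrison: V0^-1 z = z - lam (x.z) x / denom
        Xtx = X.T @ x
        A += X.T @ X - np.outer(Xtx, Xtx) * (lam / denom)
        c += X.T @ y - Xtx * (lam * float(np.dot(x, y)) / denom)
        logdet += math.log(denom)
    return A, c, logdet


def _quad_form(lam, xg, yg, Xg, beta):
    quad = 0.0
    for x, y, X in zip(xg, yg, Xg):
        r = y - X @ beta
        sxx = float(np.dot(x, x))
        denom = 1.0 + lam * sxx
        quad += float(np.dot(r, r)) - lam * float(np.dot(x, r)) ** 2 / denom
    return quad


def _profile_loglik(lam, xg, yg, Xg, method):
    """Profiled log-likelihood (REML or ML) at a fixed lambda.

    Also returns (beta, sigma2, cov_factor) so the optimum can be reused.
    """
    n_total = sum(len(y) for y in yg)
    p = Xg[0].shape[1]
    A, c, logdet = _reml_pieces(lam, xg, yg, Xg)
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular design in mixed model: {exc}") from exc
    quad = _quad_form(lam, xg, yg, Xg, beta)
    if quad <= 0:
        quad = 1e-300
    if method == "reml":
        df = n_total - p
        sigma2 = quad / df
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise FitError("non-positive-definite design in mixed model")
        ll = -0.5 * (df * (1.0 + math.log(2.0 * math.pi * sigma2)) + logdet + logdet_A)
    else:
        sigma2 = quad / n_total
        ll = -0.5 * (n_total * (1.0 + math.log(2.0 * math.pi * sigma2)) + logdet)
    return ll, beta, sigma2, A


def fit_random_slope(
    x: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    conditions: Sequence,
    reference: str,
    method: str = "reml",
    direction: str = "pwr_on_sw",
) -> MixedFitResult:
    """Fit the no-intercept, per-condition fixed slope + per-animal random
    slope model by profiled (restricted) maximum likelihood.

    Fixed-effect design: one column per condition holding x in rows of
    that condition.  Random effect: a scalar slope per group on x.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"method must be 'reml' or 'ml', got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    conditions = np.asarray(conditions)
    if not (len(x) == len(y) == len(groups) == len(conditions)):
        raise ValueError("x, y, groups, conditions must have equal length")
    cond_levels = tuple(sorted(set(conditions.tolist()), key=lambda c: (c != reference, c)))
    if reference not in cond_levels:
        raise FitError(f"reference condition {reference!r} not present in data")
    group_levels = sorted(set(groups.tolist()))
    if len(group_levels) < 2:
        raise FitError("random-slope variance is inestimable with a single animal")

    p = len(cond_levels)
    cond_idx = {c: j for j, c in enumerate(cond_levels)}
    X_full = np.zeros((len(x), p))
    for i, (xi, ci) in enumerate(zip(x, conditions)):
        X_full[i, cond_idx[ci]] = xi

    xg, yg, Xg = [], [], []
    for g in group_levels:
        mask = groups == g
        xg.append(x[mask])
        yg.append(y[mask])
        Xg.append(X_full[mask])

    def neg_ll(log_lam):
        return -_profile_loglik(math.exp(log_lam), xg, yg, Xg, method)[0]

    converged = True
    try:
        opt = optimize.minimize_scalar(neg_ll, bounds=(-25.0, 10.0), method="bounded")
        lam_hat = math.exp(opt.x) if opt.success else 0.0
        converged = bool(opt.success)
    except FitError:
        raise
    except Exception:
        lam_hat = 0.0
        converged = False

    ll_hat, beta, sigma2, A = _profile_loglik(lam_hat, xg, yg, Xg, method)
    ll_null, *_ = _profile_loglik(0.0, xg, yg, Xg, method)
    if ll_null >= ll_hat:  # boundary optimum: no evidence for tau2 > 0
        lam_hat = 0.0
        ll_hat, beta, sigma2, A = _profile_loglik(0.0, xg, yg, Xg, method)

    cov_beta = sigma2 * np.linalg.inv(A)
    beta_map = {c: float(beta[cond_idx[c]]) for c in cond_levels}

    # Wald z-tests of each condition slope against the reference slope
    jref = cond_idx[reference]
    wald_p = {}
    for c in cond_levels:
        if c == reference:
            continue
        j = cond_idx[c]
        var = cov_beta[j, j] + cov_beta[jref, jref] - 2.0 * cov_beta[j, jref]
        if var <= 0:
            wald_p[c] = float("nan")
            continue
        z = (beta[j] - beta[jref]) / math.sqrt(var)
        wald_p[c] = float(2.0 * stats.norm.sf(abs(z)))

    # boundary-corrected likelihood-ratio test of tau2 = 0
    lr = max(0.0, 2.0 * (ll_hat - ll_null))
    lrt_p = float(0.5 * stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0

    return MixedFitResult(
        conditions=cond_levels,
        reference=reference,
        beta=beta_map,
        cov_beta=cov_beta,
        tau2=float(lam_hat * sigma2),
        sigma2=float(sigma2),
        wald_p=wald_p,
        lrt_p_random=lrt_p,
        loglik=float(ll_hat),
        method=method,
        n_obs=len(x),
        n_groups=len(group_levels),
        converged=converged,
        direction=direction,
    )


def fit_mixed_slope_model(
    beat_table: pd.DataFrame,
    reference: str = "baseline",
    method: str = "reml",
    direction: str = "pwr_on_sw",
) -> MixedFitResult:
    """Fit the mixed model to a beat table.

    ``direction='pwr_on_sw'`` regresses the power integral on stroke
    work (slopes > 1 mean the power integral runs high); the reverse is
    available as a switch.
    """
    if direction not in REGRESSION_DIRECTIONS:
        raise ValueError(f"direction must be one of {REGRESSION_DIRECTIONS}")
    sw = beat_table["sw_J"].to_numpy(dtype=float)
    pwr = beat_table["pwr_integral_J"].to_numpy(dtype=float)
    x, y = (sw, pwr) if direction == "pwr_on_sw" else (pwr, sw)
    return fit_random_slope(
        x,
        y,
        groups=beat_table["animal_id"].to_numpy(),
        conditions=beat_table["condition"].to_numpy(),
        reference=reference,
        method=method,
        direction=direction,
    )


def condition_contrasts(fit: MixedFitResult) -> pd.DataFrame:
    """Per-condition slope table: slope, 95% CI, Wald p vs reference.

    The reference condition appears first with no p-value; the contrast
    of the reference with itself is excluded.
    """
    if not fit.converged:
        raise FitError("cannot tabulate contrasts from a non-converged fit")
    rows = []
    for c in fit.conditions:
        se = fit.se(c)
        rows.append(
            {
                "condition": c,
                "slope": fit.beta[c],
                "ci95_low": fit.beta[c] - 1.96 * se,
                "ci95_high": fit.beta[c] + 1.96 * se,
                "p_vs_reference": fit.wald_p.get(c, float("nan")),
                "is_reference": c == fit.reference,
            }
        )
    return pd.DataFrame(rows)
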