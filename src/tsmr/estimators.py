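"""The two-sample MR estimator battery.

Primary estimator: random-effects inverse-variance-weighted (IVW)
combination of per-SNP Wald ratios, with multiplicative overdispersion
(SE inflated by sqrt(max(1, Q/(J-1)))). Sensitivity estimators: MR-Egger
regression, the weighted median, mode-based estimation (MBE), MR-PRESSO
outlier detection/correction, robust (Tukey-biweight) regression, and
the robust adjusted profile score (MR-RAPS) with a Huber loss.
Heterogeneity is measured by Cochran's Q on the per-SNP ratio estimates.

Conventions used throughout: first-order Wald-ratio standard errors
(se = se_out / |beta_exp|); two-sided p-values from the normal
distribution; 95% confidence intervals as beta ± 1.959964 se; odds
ratios as exp(beta) for binary outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm
from scipy.stats import t as t_dist

from .harmonize import HarmonizedInstrument, HarmonizedSet

Z95 = 1.959964

#: fixed reporting order of the battery
SUITE_METHODS = (
    "ivw_re",
    "egger",
    "weighted_median",
    "presso",
    "mbe",
    "robust",
    "raps",
)


class EstimatorError(ValueError):
    """Base class for estimator failures."""


class ConfigurationError(EstimatorError):
    """An estimator was called with inadmissible settings."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: beta_out / beta_exp with first-order SE."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / (self.se_ratio * self.se_ratio)


@dataclass
class MREstimate:
    """One method's causal estimate with diagnostics.

    ``beta`` is on the outcome scale per unit exposure: log-OR per 1-SD
    exposure increase for binary outcomes, or the SD change per 1-unit
    log-OR in reverse analyses. ``exp(beta)`` is the OR for binary
    outcomes.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    outliers: list[str] | None = None
    distortion_p: float | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, 95% CI low, 95% CI high) — meaningful for binary outcomes."""
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, ...]:
    if len(hset) == 0:
        raise EstimatorError("empty harmonized set")
    g, sx, G, sy = hset.arrays()
    if np.any(g == 0):
        raise EstimatorError("zero SNP-exposure effect: Wald ratio undefined")
    return g, sx, G, sy


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * norm.sf(abs(beta / se)))


def ratio_estimates(hset: HarmonizedSet) -> list[RatioEstimate]:
    g, _, G, sy = _arrays(hset)
    return [
        RatioEstimate(i.snp_id, float(Gj / gj), float(syj / abs(gj)))
        for i, gj, Gj, syj in zip(hset.instruments, g, G, sy)
    ]


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate: ratio of outcome to exposure effect."""
    if inst.beta_exp == 0:
        raise EstimatorError(f"{inst.snp_id}: zero SNP-exposure effect")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return MREstimate("wald", beta, se, _normal_p(beta, se), 1)


def cochran_q(
    ratios: Sequence[RatioEstimate], center: float
) -> tuple[float, int, float]:
    """Weighted heterogeneity statistic about ``center``; chi-square p."""
    if len(ratios) < 2:
        raise EstimatorError("Cochran's Q needs at least 2 ratio estimates")
    w = np.array([r.weight for r in ratios])
    b = np.array([r.ratio for r in ratios])
    q = float(np.sum(w * (b - center) ** 2))
    df = len(ratios) - 1
    return q, df, float(chi2.sf(q, df))


def ivw_random_effects(hset: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects IVW estimate.

    Point estimate: inverse-variance-weighted mean of the Wald ratios,
    identical to weighted least squares of Gamma on gamma through the
    origin with weights 1/se_out². The SE is the fixed-effect SE
    inflated by sqrt(max(1, Q/(J-1))); for a single SNP it reduces to
    the Wald ratio.
    """
    g, _, G, sy = _arrays(hset)
    J = len(g)
    w = g * g / (sy * sy)
    b = G / g
    beta = float(np.sum(w * b) / np.sum(w))
    if J == 1:
        est = wald_ratio(hset.instruments[0])
        return replace(est, method="ivw_re")
    q = float(np.sum(w * (b - beta) ** 2))
    df = J - 1
    se = float(math.sqrt(max(1.0, q / df) / np.sum(w)))
    return MREstimate(
        "ivw_re", beta, se, _normal_p(beta, se), J,
        q=q, q_df=df, q_p=float(chi2.sf(q, df)),
    )


def _oriented(g: np.ndarray, sx: np.ndarray, G: np.ndarray, sy: np.ndarray):
    """Re-sign each instrument so the SNP-exposure effect is non-negative
    (the InSiDE orientation convention for MR-Egger)."""
    s = np.where(g < 0, -1.0, 1.0)
    return g * s, sx, G * s, sy


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    The slope is the pleiotropy-adjusted causal estimate; an intercept
    distinct from zero estimates the average directional pleiotropic
    effect. Multiplicative overdispersion with J-2 degrees of freedom;
    p-values and CIs use the t distribution with J-2 df (the method's
    published convention, because the overdispersion is estimated).
    """
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise EstimatorError("MR-Egger needs at least 3 instruments")
    x, _, y, sy = _oriented(g, sx, G, sy)
    w = 1.0 / (sy * sy)
    X = np.column_stack([np.ones(J), x])
    XtW = X.T * w
    A = XtW @ X
    if np.linalg.cond(A) > 1e12 or np.allclose(x, x[0]):
        raise EstimatorError("MR-Egger: no spread in SNP-exposure effects")
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (J - 2))
    cov = np.linalg.inv(A) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    q, df, q_p = float(rss_w), J - 2, float(chi2.sf(rss_w, J - 2))

    def t_p(b: float, s: float) -> float:
        return float(2.0 * t_dist.sf(abs(b / s), J - 2)) if s > 0 else (0.0 if b else 1.0)

    t_crit = float(t_dist.ppf(0.975, J - 2))
    return MREstimate(
        "egger", slope, se_slope, t_p(slope, se_slope), J,
        ci_low=slope - t_crit * se_slope,
        ci_high=slope + t_crit * se_slope,
        q=q, q_df=df, q_p=q_p,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=t_p(intercept, se_int),
    )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation between the
    bracketing order statistics (midpoint cumulative-weight convention)."""
    order = np.argsort(b, kind="stable")
    bs, ws = b[order], w[order]
    s = (np.cumsum(ws) - 0.5 * ws) / np.sum(ws)
    return float(np.interp(0.5, s, bs))


def _rowwise_weighted_median(B: np.ndarray, W: np.ndarray) -> np.ndarray:
    order = np.argsort(B, axis=1, kind="stable")
    Bs = np.take_along_axis(B, order, 1)
    Ws = np.take_along_axis(W, order, 1)
    S = (np.cumsum(Ws, axis=1) - 0.5 * Ws) / np.sum(Ws, axis=1, keepdims=True)
    idx = np.sum(S < 0.5, axis=1)
    n, J = B.shape
    out = np.empty(n)
    lo_edge = idx == 0
    hi_edge = idx == J
    out[lo_edge] = Bs[lo_edge, 0]
    out[hi_edge] = Bs[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    s0, s1 = S[rows, i - 1], S[rows, i]
    b0, b1 = Bs[rows, i - 1], Bs[rows, i]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out[mid] = b0 + frac * (b1 - b0)
    return out


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: consistent when at least half the
    inverse-variance weight comes from valid instruments. SE by
    parametric bootstrap of the summary associations."""
    if n_boot < 100:
        raise ConfigurationError(f"n_boot={n_boot} too small (need >= 100)")
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise EstimatorError("weighted median needs at least 3 instruments")
    w = g * g / (sy * sy)
    beta = _weighted_median(G / g, w)
    rng = np.random.default_rng(seed)
    gb = rng.normal(g, sx, size=(n_boot, J))
    Gb = rng.normal(G, sy, size=(n_boot, J))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = _rowwise_weighted_median(Gb / gb, gb * gb / (sy * sy))
    se = float(np.std(boots[np.isfinite(boots)], ddof=1))
    return MREstimate("weighted_median", beta, se, _normal_p(beta, se), J)


def _mbe_point(b: np.ndarray, w: np.ndarray, phi: float, n_grid: int = 512):
    """Maximizer of a weighted Gaussian kernel density over the ratios.

    Bandwidth: phi times the modified Silverman rule
    0.9 * min(sd, normalized MAD) * J^(-1/5). Returns (point, grid_step).
    """
    J = len(b)
    sd = float(np.std(b, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(b - np.median(b))) * 1.4826)
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return float(b[0]), 0.0  # all ratios identical
    h = phi * 0.9 * min(candidates) * J ** (-0.2)
    grid = np.linspace(b.min() - 2 * h, b.max() + 2 * h, n_grid)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))]), float(grid[1] - grid[0])


def mode_based_estimate(
    hset: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Mode-based estimation (weighted flavor): the most common causal
    effect among the per-SNP ratios, robust to outlying invalid
    instruments. SE by parametric bootstrap (bandwidth re-estimated per
    replicate)."""
    if phi <= 0:
        raise ConfigurationError(f"phi={phi} must be positive")
    if n_boot < 100:
        raise ConfigurationError(f"n_boot={n_boot} too small (need >= 100)")
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise EstimatorError("mode-based estimation needs at least 3 instruments")
    w = g * g / (sy * sy)
    beta, _ = _mbe_point(G / g, w, phi)
    rng = np.random.default_rng(seed)
    gb = rng.normal(g, sx, size=(n_boot, J))
    Gb = rng.normal(G, sy, size=(n_boot, J))
    boots = np.empty(n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n_boot):
            boots[i], _ = _mbe_point(Gb[i] / gb[i], gb[i] ** 2 / (sy * sy), phi)
    se = float(np.std(boots[np.isfinite(boots)], ddof=1))
    return MREstimate("mbe", beta, se, _normal_p(beta, se), J)


def _loo_ivw_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (WLS through the origin), vectorized."""
    swgg = np.sum(w * g * g)
    swgG = np.sum(w * g * G)
    return (swgG - w * g * G) / (swgg - w * g * g)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> MREstimate:
    """MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier
    correction.

    The observed weighted RSS of each SNP about its leave-one-out IVW
    prediction is compared with a parametric-bootstrap null (summary
    statistics re-drawn under no pleiotropy). Per-SNP outlier p-values
    are Bonferroni-adjusted; when outliers are found the reported
    estimate is the outlier-corrected IVW, with a distortion-test p
    comparing the shift against random same-size removals.
    """
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 4:
        raise EstimatorError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 1000:
        raise ConfigurationError(f"n_sim={n_sim} too small (need >= 1000)")
    rng = np.random.default_rng(seed)
    w = 1.0 / (sy * sy)
    b_loo = _loo_ivw_slopes(g, G, w)
    res_obs = G - b_loo * g
    rss_obs = float(np.sum(w * res_obs**2))

    g_sim = rng.normal(g, sx, size=(n_sim, J))
    G_sim = rng.normal(b_loo * g, sy, size=(n_sim, J))
    swgg = np.sum(w * g_sim * g_sim, axis=1, keepdims=True)
    swgG = np.sum(w * g_sim * G_sim, axis=1, keepdims=True)
    bl_sim = (swgG - w * g_sim * G_sim) / (swgg - w * g_sim * g_sim)
    res_sim = G_sim - bl_sim * g_sim
    rss_sim = np.sum(w * res_sim**2, axis=1)
    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_snp_exceed = np.sum(res_sim**2 >= res_obs[None, :] ** 2, axis=0)
    p_raw = (per_snp_exceed + 1) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * J)
    outlier_idx = np.nonzero(p_bonf < outlier_alpha)[0]
    outliers = [hset.instruments[i].snp_id for i in outlier_idx]

    if outliers and J - len(outliers) >= 2:
        corrected = ivw_random_effects(hset.without(outliers))
        n_out = len(outliers)
        beta_all = ivw_random_effects(hset).beta
        d_obs = (corrected.beta - beta_all) / abs(beta_all) if beta_all != 0 else 0.0
        keep_sets = np.argsort(
            rng.random((n_sim, J)), axis=1
        )[:, n_out:]  # random subsets removing n_out SNPs
        wgg = (w * g * g)[keep_sets]
        wgG = (w * g * G)[keep_sets]
        b_sub = np.sum(wgG, axis=1) / np.sum(wgg, axis=1)
        d_sim = (b_sub - beta_all) / abs(beta_all) if beta_all != 0 else b_sub * 0
        distortion_p = float((np.sum(np.abs(d_sim) >= abs(d_obs)) + 1) / (n_sim + 1))
        est = replace(
            corrected,
            method="presso",
            presso_global_p=global_p,
            outliers=outliers,
            distortion_p=distortion_p,
        )
        return est
    raw = ivw_random_effects(hset)
    return replace(
        raw, method="presso", presso_global_p=global_p, outliers=outliers or []
    )


def _tukey_weights(u: np.ndarray, c: float) -> np.ndarray:
    w = (1.0 - (u / c) ** 2) ** 2
    w[np.abs(u) >= c] = 0.0
    return w


def mr_robust(
    hset: HarmonizedSet,
    tukey_c: float = 4.685,
    tol: float = 1e-10,
    max_iter: int = 200,
    start: float | None = None,
) -> MREstimate:
    """Robust regression of Gamma on gamma through the origin.

    Iteratively reweighted least squares with the Tukey biweight
    (c = 4.685, 95% Gaussian efficiency) on precision-standardized data,
    scale re-estimated by the normalized MAD each iteration. Down-weights
    or removes outlying instruments entirely.
    """
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise EstimatorError("MR-Robust needs at least 3 instruments")
    x = g / sy
    y = G / sy
    sxx = float(np.sum(x * x))
    beta = float(np.sum(x * y) / sxx) if start is None else float(start)

    resid = y - beta * x
    scale = float(np.median(np.abs(resid)) / 0.6744897501960817)
    if scale < 1e-12:
        # exact fit: weighted least squares solution, fixed-effect SE
        se = float(1.0 / math.sqrt(sxx))
        return MREstimate("robust", beta, se, _normal_p(beta, se), J)

    converged = False
    for it in range(1, max_iter + 1):
        resid = y - beta * x
        scale = float(np.median(np.abs(resid)) / 0.6744897501960817)
        if scale < 1e-12:
            converged = True
            break
        wt = _tukey_weights(resid / scale, tukey_c)
        denom = float(np.sum(wt * x * x))
        if denom == 0:
            raise EstimatorError("MR-Robust: all instruments down-weighted to zero")
        beta_new = float(np.sum(wt * x * y) / denom)
        if abs(beta_new - beta) <= tol * max(1.0, abs(beta)):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        raise EstimatorError(f"MR-Robust did not converge in {max_iter} iterations")

    resid = y - beta * x
    scale = float(np.median(np.abs(resid)) / 0.6744897501960817)
    if scale < 1e-12:
        se = float(1.0 / math.sqrt(sxx))
        return MREstimate("robust", beta, se, _normal_p(beta, se), J)
    u = resid / scale
    psi = np.where(np.abs(u) < tukey_c, u * (1 - (u / tukey_c) ** 2) ** 2, 0.0)
    dpsi = np.where(
        np.abs(u) < tukey_c,
        (1 - (u / tukey_c) ** 2) * (1 - 5 * (u / tukey_c) ** 2),
        0.0,
    )
    num = float(np.sum(psi**2 * x * x)) * scale**2
    den = float(np.sum(dpsi * x * x)) ** 2
    se = float(math.sqrt(num / den)) if den > 0 else float("inf")
    return MREstimate("robust", beta, se, _normal_p(beta, se), J)


# Huber consistency constant: E[psi(Z) Z] = 2 Phi(k) - 1 for standard normal Z
def _huber_delta(k: float) -> float:
    return float(2.0 * norm.cdf(k) - 1.0)


def _huber_rho(t: np.ndarray, k: float) -> np.ndarray:
    a = np.abs(t)
    return np.where(a <= k, 0.5 * t * t, k * a - 0.5 * k * k)


def raps_objective(
    beta: float,
    tau2: float,
    g: np.ndarray,
    sx: np.ndarray,
    G: np.ndarray,
    sy: np.ndarray,
    huber_k: float = 1.345,
) -> float:
    """Negative robust adjusted profile log-likelihood (up to a constant).

    Standardized residuals t_j = (Gamma_j - beta gamma_j) / s_j with
    s_j² = se_out² + beta² se_exp² + tau² are scored through the Huber
    rho; the (delta/2) log s² term (delta = 2 Phi(k) - 1, the Huber
    consistency constant) makes the profile score unbiased.
    """
    s2 = sy * sy + beta * beta * sx * sx + tau2
    t = (G - beta * g) / np.sqrt(s2)
    delta = _huber_delta(huber_k)
    return float(np.sum(_huber_rho(t, huber_k)) + 0.5 * delta * np.sum(np.log(s2)))


def mr_raps(hset: HarmonizedSet, huber_k: float = 1.345) -> MREstimate:
    """MR-RAPS: robust adjusted profile score with Huber loss.

    Jointly maximizes the adjusted profile likelihood over the causal
    effect and an additive overdispersion variance tau² >= 0 modelling a
    random-effects distribution of pleiotropic effects. Deterministic.
    """
    g, sx, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise EstimatorError("MR-RAPS needs at least 3 instruments")

    w = g * g / (sy * sy)
    beta0 = float(np.sum(w * (G / g)) / np.sum(w))

    def nll(theta: np.ndarray) -> float:
        return raps_objective(theta[0], theta[1], g, sx, G, sy, huber_k)

    best = None
    for tau0 in (0.0, float(np.mean(sy * sy))):
        res = optimize.minimize(
            nll,
            x0=np.array([beta0, tau0]),
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, None)],
        )
        if best is None or (res.success and res.fun < best.fun):
            if res.success or best is None:
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise EstimatorError(f"MR-RAPS optimizer failed: {getattr(best, 'message', '')}")
    beta_hat, tau2_hat = float(best.x[0]), float(max(0.0, best.x[1]))

    # model-based sandwich SE: Var(U)/E[dU/dbeta]^2 with the Huber
    # expectation constants c1 = E[psi'(Z)] = 2 Phi(k) - 1 and
    # c2 = E[psi(Z)^2] taken under the fitted model rather than the
    # (small-J noisy) empirical score sums
    c1 = _huber_delta(huber_k)
    c2 = float(
        c1
        - 2.0 * huber_k * norm.pdf(huber_k)
        + 2.0 * huber_k**2 * norm.cdf(-huber_k)
    )
    s2 = sy * sy + beta_hat * beta_hat * sx * sx + tau2_hat
    info_kernel = float(np.sum(g * g / s2))
    if info_kernel <= 0:
        raise EstimatorError("MR-RAPS: degenerate information at the optimum")
    se = float(math.sqrt(c2) / (c1 * math.sqrt(info_kernel)))
    return MREstimate(
        "raps", beta_hat, se, _normal_p(beta_hat, se), J, tau2=tau2_hat
    )


@dataclass
class MultiExposureSet:
    """Instruments with effects on several exposures and one outcome."""

    snp_ids: list[str]
    exposure_names: list[str]
    beta_exp: np.ndarray  # (J, K)
    se_exp: np.ndarray  # (J, K)
    beta_out: np.ndarray  # (J,)
    se_out: np.ndarray  # (J,)


def multivariable_ivw(mset: MultiExposureSet) -> list[MREstimate]:
    """Multivariable IVW: weighted multiple regression of the outcome
    effects on all exposure-effect columns, no intercept. Returns one
    conditional estimate per exposure."""
    X = np.asarray(mset.beta_exp, dtype=float)
    y = np.asarray(mset.beta_out, dtype=float)
    sy = np.asarray(mset.se_out, dtype=float)
    J, K = X.shape
    if J < K + 1:
        raise EstimatorError(f"need at least {K + 1} instruments for {K} exposures")
    if np.linalg.matrix_rank(X) < K:
        raise EstimatorError("rank-deficient exposure design (collinear exposures)")
    w = 1.0 / (sy * sy)
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    phi = max(1.0, float(np.sum(w * resid**2)) / (J - K))
    cov = np.linalg.inv(A) * phi
    out = []
    for k in range(K):
        b, s = float(coef[k]), float(math.sqrt(cov[k, k]))
        out.append(
            MREstimate(
                "mv_ivw", b, s, _normal_p(b, s), J,
            )
        )
    return out


@dataclass
class SuiteConfig:
    """Settings for the full estimator battery."""

    seed: int = 0
    n_boot: int = 1000
    phi: float = 1.0
    presso_n_sim: int = 5000
    presso_global_alpha: float = 0.01
    outlier_alpha: float = 0.05
    huber_k: float = 1.345
    tukey_c: float = 4.685
    methods: tuple[str, ...] = SUITE_METHODS


@dataclass
class SuiteResult:
    """All method estimates for one pair, plus recorded failures."""

    exposure_name: str
    outcome_name: str
    estimates: list[MREstimate]
    failures: dict[str, str]

    def get(self, method: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method == method:
                return e
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in SUITE_METHODS:
            est = self.get(m)
            if est is None:
                if m in self.failures:
                    rows.append(
                        {
                            "exposure": self.exposure_name,
                            "outcome": self.outcome_name,
                            "method": m,
                            "status": f"not_applicable: {self.failures[m]}",
                        }
                    )
                continue
            or_, or_lo, or_hi = est.odds_ratio()
            rows.append(
                {
                    "exposure": self.exposure_name,
                    "outcome": self.outcome_name,
                    "method": m,
                    "status": "ok",
                    "n_snps": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or": or_,
                    "ci_low": or_lo,
                    "ci_high": or_hi,
                    "p": est.pvalue,
                    "q": est.q,
                    "q_p": est.q_p,
                    "egger_intercept": est.egger_intercept,
                    "egger_intercept_p": est.egger_intercept_p,
                    "presso_global_p": est.presso_global_p,
                    "outliers": ";".join(est.outliers) if est.outliers else None,
                    "distortion_p": est.distortion_p,
                }
            )
        cols = [
            "exposure", "outcome", "method", "status", "n_snps", "beta", "se",
            "or", "ci_low", "ci_high", "p", "q", "q_p", "egger_intercept",
            "egger_intercept_p", "presso_global_p", "outliers", "distortion_p",
        ]
        return pd.DataFrame(rows).reindex(columns=cols)


def run_estimator_suite(
    hset: HarmonizedSet, config: SuiteConfig | None = None
) -> SuiteResult:
    """Run the full battery in fixed order, isolating per-method failures."""
    cfg = config or SuiteConfig()
    runners: dict[str, Callable[[], MREstimate]] = {
        "ivw_re": lambda: ivw_random_effects(hset),
        "egger": lambda: mr_egger(hset),
        "weighted_median": lambda: weighted_median(hset, cfg.n_boot, cfg.seed),
        "presso": lambda: mr_presso(hset, cfg.presso_n_sim, cfg.seed, cfg.outlier_alpha),
        "mbe": lambda: mode_based_estimate(hset, cfg.phi, cfg.n_boot, cfg.seed),
        "robust": lambda: mr_robust(hset, tukey_c=cfg.tukey_c),
        "raps": lambda: mr_raps(hset, huber_k=cfg.huber_k),
    }
    estimates: list[MREstimate] = []
    failures: dict[str, str] = {}
    for m in cfg.methods:
        try:
            estimates.append(runners[m]())
        except (EstimatorError, ConfigurationError) as exc:
            failures[m] = str(exc)
    if not estimates:
        raise EstimatorError("every estimator failed: " + "; ".join(failures.values()))
    return SuiteResult(hset.exposure_name, hset.outcome_name, estimates, failures)
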