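"""Two-sample MR estimators and heterogeneity diagnostics.

Given J harmonized instruments with SNP-exposure effects β_Xj (SE σ_Xj) and
SNP-outcome effects β_Yj (SE σ_Yj), the per-SNP causal estimate is the Wald
ratio θ_j = β_Yj/β_Xj. The estimators differ in how the ratios are pooled
and which pleiotropy assumptions they tolerate:

* inverse-variance weighted (IVW): precision-weighted mean of the ratios
  with weights w_j = β_Xj²/σ_Yj²; equivalent to a zero-intercept weighted
  regression of β_Y on β_X with weights 1/σ_Yj². Consistent only when all
  instruments are valid. Fixed-effects SE is 1/√Σw; the multiplicative
  random-effects variant inflates it by max(1, √(Q/(J−1))).
* MR-Egger: the same regression with a free intercept. The intercept
  estimates the average pleiotropic effect; the slope is a causal estimate
  that is robust to directional pleiotropy under the InSIDE assumption
  (instrument strength independent of direct effects).
* weighted median: consistent when valid instruments carry more than half
  of the total weight.
* weighted mode: consistent when the largest group of instruments sharing
  the same ratio is valid, so a majority may be pleiotropic.

Heterogeneity among ratios is quantified by Cochran's Q with a χ²(J−1)
reference. Wald-ratio SEs use the first-order delta method (σ_Yj/|β_Xj|),
the standard two-sample default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DomainError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

_MODE_GRID_POINTS = 1024


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-OR (or SD-outcome) scale."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    """Cochran's Q over the per-SNP Wald ratios (χ², J−1 df)."""

    q: float
    df: int
    pvalue: float


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-OR estimate and its CI bounds."""
    lo, hi = est.or_ci
    return est.odds_ratio, lo, hi


def _normal_ci_p(theta: float, se: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else (1.0 if theta == 0 else 0.0)
    return theta - z * se, theta + z * se, float(p)


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with first-order delta-method SE."""
    if beta_x == 0:
        raise DomainError("beta_x = 0: degenerate instrument, Wald ratio undefined")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate("wald", theta, se, lo, hi, p, 1)


def _extract(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx, sx, by, sy = h.arrays()
    nz = bx != 0
    if not np.all(nz):
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d SNP(s) with beta_exposure = 0", int((~nz).sum())
        )
    return bx[nz], sx[nz], by[nz], sy[nz]


def ivw(
    h: HarmonizedSet, effects: str = "fixed"
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``effects`` is ``"fixed"`` or ``"random_multiplicative"`` (SE inflated
    by max(1, √(Q/(J−1)))). A single instrument degenerates to the Wald
    ratio with Q = 0.
    """
    if effects not in ("fixed", "random_multiplicative"):
        raise ConfigurationError(f"unknown effects model {effects!r}")
    bx, sx, by, sy = _extract(h)
    j = len(bx)
    if j < 1:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    ratios = by / bx
    w = bx**2 / sy**2
    sw = w.sum()
    theta = float((w * ratios).sum() / sw)
    q = float((w * (ratios - theta) ** 2).sum())
    df = j - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    se = 1.0 / np.sqrt(sw)
    method = "ivw_fixed"
    if effects == "random_multiplicative":
        method = "ivw_random"
        if df > 0:
            se *= max(1.0, float(np.sqrt(q / df)))
    lo, hi, p = _normal_ci_p(theta, float(se))
    return MREstimate(method, theta, float(se), lo, hi, p, j), HeterogeneityResult(q, df, q_p)


def _orient_positive(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Negate (β_X, β_Y) pairs so every β_X ≥ 0 (allele-orientation choice)."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of β_Y on β_X with a free intercept.

    Rows are first oriented so every β_X ≥ 0. Weights are 1/σ_Y²; both SEs
    are inflated by max(1, estimated residual scale) and referred to a
    t-distribution with J−2 df.
    """
    bx, sx, by, sy = _extract(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, by = _orient_positive(bx, by)
    w = 1.0 / sy**2
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=w).fit()
    # Unscaled covariance (X'WX)^{-1} times max(1, residual scale): the
    # multiplicative floor keeps SEs from shrinking below the fixed-weight
    # ones, and survives exact fits where the residual scale is 0.
    sigma = float(np.sqrt(fit.scale))
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    inter_se, slope_se = se_unscaled * max(1.0, sigma)
    inter, slope = float(fit.params[0]), float(fit.params[1])
    tdf = j - 2
    slope_p = float(2.0 * stats.t.sf(abs(slope) / slope_se, tdf))
    inter_p = float(2.0 * stats.t.sf(abs(inter) / inter_se, tdf))
    tq = stats.t.ppf(0.975, tdf)
    slope_est = MREstimate(
        "egger",
        slope,
        float(slope_se),
        slope - tq * slope_se,
        slope + tq * slope_se,
        slope_p,
        j,
    )
    return EggerResult(slope_est, inter, float(inter_se), inter_p)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, r))


def _bootstrap_draws(
    bx, sx, by, sy, n_boot: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(by)))
    return bx_star, by_star


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator (valid-majority-of-weight assumption).

    Ratios are sorted; the estimate interpolates the weighted empirical CDF
    at 0.5 using standardized cumulative IVW weights. The SE comes from a
    parametric bootstrap resampling β_X and β_Y from their observed normal
    sampling distributions (explicit ``seed`` required).
    """
    if seed is None:
        raise ConfigurationError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _extract(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    ratios = by / bx
    w = bx**2 / sy**2
    theta = _weighted_median(ratios, w)

    bx_star, by_star = _bootstrap_draws(bx, sx, by, sy, n_boot, seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_star[b]
        ok = bxb != 0
        rb = by_star[b, ok] / bxb[ok]
        wb = bxb[ok] ** 2 / sy[ok] ** 2
        boot[b] = _weighted_median(rb, wb)
    se = float(boot.std(ddof=1))
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate("weighted_median", theta, se, lo, hi, p, j)


def _mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    candidates = [v for v in (sd, mad) if v > 0]
    if not candidates:
        return 0.0
    scale = min(sd, mad) if sd > 0 and mad > 0 else candidates[0]
    return bandwidth_factor * 0.9 * scale * j ** (-1.0 / 5.0)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)
    if h == 0.0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, _MODE_GRID_POINTS)
    z = (grid[:, None] - ratios[None, :]) / h
    density = (weights[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)
    return float(grid[np.argmax(density)])


def weighted_mode(
    h: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator (plurality-valid assumption).

    The estimate maximises an IVW-weighted normal-kernel density over the
    Wald ratios; kernel scale is ``bandwidth_factor`` × 0.9 × min(SD,
    MAD/0.6745) × J^(−1/5). SE by parametric bootstrap. Zero dispersion
    returns the common ratio.
    """
    if seed is None:
        raise ConfigurationError("weighted_mode requires an explicit seed")
    bx, sx, by, sy = _extract(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted mode needs at least 3 instruments")
    ratios = by / bx
    w = bx**2 / sy**2
    theta = _weighted_mode(ratios, w, bandwidth_factor)

    bx_star, by_star = _bootstrap_draws(bx, sx, by, sy, n_boot, seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_star[b]
        ok = bxb != 0
        rb = by_star[b, ok] / bxb[ok]
        wb = bxb[ok] ** 2 / sy[ok] ** 2
        boot[b] = _weighted_mode(rb, wb, bandwidth_factor)
    se = float(boot.std(ddof=1))
    lo, hi, p = _normal_ci_p(theta, se)
    return MREstimate("weighted_mode", theta, se, lo, hi, p, j)


def all_estimates(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MREstimate]:
    """Convenience: IVW (fixed), Egger slope, weighted median and mode."""
    est, _ = ivw(h)
    out = [est]
    if h.n_retained >= 3:
        out.append(egger(h).slope)
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(weighted_mode(h, n_boot=n_boot, seed=seed))
    return out
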