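"""MR-PRESSO: pleiotropy residual sum and outlier tests.

The framework asks three questions about an instrument set:

* **global test** — is there more residual heterogeneity around the IVW fit
  than sampling noise explains (any horizontal pleiotropy)?
* **outlier test** — which specific SNPs drive it?
* **distortion test** — does removing the flagged SNPs materially change
  the causal estimate?

The observed statistic is the leave-one-out residual sum of squares
RSS = Σ_j (β_Yj − θ̂₍₋ⱼ₎·β_Xj)², where θ̂₍₋ⱼ₎ is the IVW estimate computed
without SNP j. Its null distribution is built by Monte-Carlo simulation:
each replicate redraws β*_Xj ~ N(β_Xj, σ_Xj) and β*_Yj ~ N(θ̂₍₋ⱼ₎·β_Xj,
σ_Yj) and recomputes the same statistic. Empirical p-values use the
add-one estimator (1 + #{≥ observed})/(n_sim + 1), so they are never zero;
per-SNP p-values are Bonferroni-multiplied by J and capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .exceptions import (
    ConfigurationError,
    EstimationImpossibleError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

MIN_INSTRUMENTS = 4


@dataclass
class PressoResult:
    rss_observed: float
    global_pvalue: float
    per_snp_pvalues: list[float]
    outlier_ids: list[str]
    theta_raw: MREstimate
    theta_outlier_corrected: MREstimate | None
    distortion_pvalue: float | None
    distortion_coefficient: float | None
    n_sim: int
    seed: int


def _loo_ivw_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the left-out index."""
    w = bx**2 / sy**2
    r = by / bx
    sw = w.sum()
    swr = (w * r).sum()
    return (swr - w * r) / (sw - w)


def _rss_and_residuals(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    theta_loo = _loo_ivw_theta(bx, by, sy)
    resid = by - theta_loo * bx
    return float((resid**2).sum()), resid


def _simulate_residuals(
    bx: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    theta_loo: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_sim, J) matrix of simulated leave-one-out residuals under the null."""
    j = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    w = bx_star**2 / sy**2
    r = by_star / bx_star
    sw = w.sum(axis=1, keepdims=True)
    swr = (w * r).sum(axis=1, keepdims=True)
    theta_loo_star = (swr - w * r) / (sw - w)
    return by_star - theta_loo_star * bx_star


def _checked_arrays(h: HarmonizedSet):
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0):
        raise EstimationImpossibleError("beta_exposure = 0 instrument in MR-PRESSO input")
    if len(bx) < MIN_INSTRUMENTS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs at least {MIN_INSTRUMENTS} instruments, got {len(bx)}"
        )
    return bx, sx, by, sy


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    significance: float = 0.05,
    run_distortion: bool = True,
) -> PressoResult:
    """Run the global, outlier and (when outliers exist) distortion tests.

    The three tests share one seeded draw stream, so the result is fully
    determined by (inputs, n_sim, seed).
    """
    if seed is None:
        raise ConfigurationError("mr_presso requires an explicit seed")
    if n_sim < 1:
        raise ConfigurationError(f"n_sim must be >= 1, got {n_sim}")
    bx, sx, by, sy = _checked_arrays(h)
    ids = list(h.retained["variant_id"])
    j = len(bx)
    rng = np.random.default_rng(seed)

    theta_loo = _loo_ivw_theta(bx, by, sy)
    rss_obs, resid_obs = _rss_and_residuals(bx, by, sy)
    resid_star = _simulate_residuals(bx, sx, sy, theta_loo, n_sim, rng)
    rss_star = (resid_star**2).sum(axis=1)

    global_p = (1.0 + np.count_nonzero(rss_star >= rss_obs)) / (n_sim + 1.0)

    exceed = (resid_star**2 >= resid_obs[None, :] ** 2).sum(axis=0)
    per_snp_p = np.minimum(1.0, (1.0 + exceed) / (n_sim + 1.0) * j)
    outlier_mask = per_snp_p < significance
    outlier_ids = [ids[i] for i in np.flatnonzero(outlier_mask)]

    theta_raw, _ = ivw(h)

    theta_corr = None
    distortion_p = None
    distortion_coef = None
    if outlier_ids and run_distortion:
        if len(outlier_ids) == j:
            raise EstimationImpossibleError(
                "all instruments flagged as outliers; cannot compute a corrected estimate"
            )
        theta_corr, distortion_coef, distortion_p = _distortion(
            bx, by, sy, np.flatnonzero(outlier_mask), theta_raw.theta, n_sim, rng
        )

    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=float(global_p),
        per_snp_pvalues=[float(p) for p in per_snp_p],
        outlier_ids=outlier_ids,
        theta_raw=theta_raw,
        theta_outlier_corrected=theta_corr,
        distortion_pvalue=distortion_p,
        distortion_coefficient=distortion_coef,
        n_sim=n_sim,
        seed=seed,
    )


def _ivw_theta_se(bx, by, sy):
    w = bx**2 / sy**2
    theta = float((w * (by / bx)).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return theta, se


def _distortion(bx, by, sy, outlier_idx, theta_raw, n_sim, rng):
    from scipy import stats

    keep = np.setdiff1d(np.arange(len(bx)), outlier_idx)
    theta_c, se_c = _ivw_theta_se(bx[keep], by[keep], sy[keep])
    d_obs = (theta_raw - theta_c) / abs(theta_c) if theta_c != 0 else np.inf

    n_out = len(outlier_idx)
    d_star = np.empty(n_sim)
    for s in range(n_sim):
        drop = rng.choice(len(bx), size=n_out, replace=False)
        k = np.setdiff1d(np.arange(len(bx)), drop)
        t_s, _ = _ivw_theta_se(bx[k], by[k], sy[k])
        d_star[s] = (theta_raw - t_s) / abs(t_s) if t_s != 0 else np.inf
    p = (1.0 + np.count_nonzero(np.abs(d_star) >= abs(d_obs))) / (n_sim + 1.0)

    lo = theta_c - stats.norm.ppf(0.975) * se_c
    hi = theta_c + stats.norm.ppf(0.975) * se_c
    pv = float(2.0 * stats.norm.sf(abs(theta_c) / se_c))
    est = MREstimate("ivw_outlier_corrected", theta_c, se_c, lo, hi, pv, len(keep))
    return est, float(d_obs), float(p)


def presso_global(
    h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """(observed RSS, global empirical p)."""
    res = mr_presso(h, n_sim=n_sim, seed=seed, run_distortion=False)
    return res.rss_observed, res.global_pvalue


def presso_outliers(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    significance: float = 0.05,
) -> tuple[list[float], list[str]]:
    """(Bonferroni-adjusted per-SNP p-values, flagged outlier ids)."""
    res = mr_presso(h, n_sim=n_sim, seed=seed, significance=significance, run_distortion=False)
    return res.per_snp_pvalues, res.outlier_ids


def presso_distortion(
    h: HarmonizedSet,
    outlier_ids: list[str],
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, MREstimate]:
    """Distortion test for a given outlier set.

    Returns (distortion coefficient, empirical two-sided p, outlier-corrected
    IVW estimate). The coefficient is (θ_raw − θ_corrected)/|θ_corrected|;
    its reference distribution removes |outliers| random SNPs repeatedly.
    """
    if seed is None:
        raise ConfigurationError("presso_distortion requires an explicit seed")
    if not outlier_ids:
        raise ConfigurationError("outlier_ids must be non-empty")
    if n_sim < 1:
        raise ConfigurationError(f"n_sim must be >= 1, got {n_sim}")
    bx, sx, by, sy = _checked_arrays(h)
    ids = list(h.retained["variant_id"])
    idx = np.array([ids.index(o) for o in outlier_ids])
    if len(idx) == len(bx):
        raise EstimationImpossibleError("all instruments flagged; cannot correct")
    theta_raw, _ = ivw(h)
    rng = np.random.default_rng(seed)
    est, d_obs, p = _distortion(bx, by, sy, idx, theta_raw.theta, n_sim, rng)
    return d_obs, p, est
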