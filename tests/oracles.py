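"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package: weighted least
squares is solved through the raw normal equations with numpy only, and
clumping is a literal, unoptimised transcription of the greedy rule.
"""

import numpy as np


def wls_normal_equations(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Solve min Σ w(y − Xb)²; returns (coefficients, unscaled covariance)."""
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * y)
    beta = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    return beta, cov


def ivw_via_wls(bx, by, sy):
    """Zero-intercept WLS of beta_y on beta_x with weights 1/se_y²."""
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    beta, cov = wls_normal_equations(np.asarray(bx, float)[:, None], np.asarray(by, float), w)
    return float(beta[0]), float(np.sqrt(cov[0, 0]))


def greedy_clump_reference(entries, r2_lookup, r2_threshold, window_bp):
    """Literal greedy clumping: entries are (variant_id, pvalue, chrom, pos).

    Repeatedly pick the smallest-p remaining entry (ties by id), keep it,
    drop all remaining entries correlated at r² >= threshold on the same
    chromosome within the window. Returns kept ids in pick order.
    """
    remaining = list(entries)
    kept = []
    while remaining:
        remaining.sort(key=lambda e: (e[1], e[0]))
        lead = remaining.pop(0)
        kept.append(lead[0])
        survivors = []
        for e in remaining:
            r2 = r2_lookup(lead[0], e[0])
            same_window = lead[2] == e[2] and abs(lead[3] - e[3]) <= window_bp
            if r2 >= r2_threshold and same_window:
                continue
            survivors.append(e)
        remaining = survivors
    return kept


def weighted_median_reference(ratios, weights):
    """Weighted median by direct scan of the standardized cumulative weights."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    i = np.searchsorted(s, 0.5)
    f = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
    return float(r[i - 1] + f * (r[i] - r[i - 1]))
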