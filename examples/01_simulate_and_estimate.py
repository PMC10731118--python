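"""Simulate a two-sample MR study with a known causal effect and recover it.

Generates GWAS summary statistics for 100 valid instruments with a true
causal effect of theta = 0.3 (OR ~ 1.35 per SD of exposure), harmonizes
the pair, and runs the four standard estimators.
"""

import numpy as np

from mrkit import (
    all_estimates,
    build_instrument_set,
    ivw,
    scenario,
    simulate_two_sample,
)

truth = scenario("effect_valid", seed=1)  # theta = 0.3, J = 100, no pleiotropy
study = simulate_two_sample(truth)
h = study.harmonized()

inst = build_instrument_set(h, exposure_gwas_n=truth.n_exposure)
print(f"instruments: k = {inst.k}, total R2 = {inst.total_r2:.4f}, F = {inst.f_stat:.1f}")

_, q = ivw(h)
print(f"heterogeneity: Q = {q.q:.1f} (df {q.df}), p = {q.pvalue:.3f}\n")

print(f"{'method':<16}{'theta':>8}{'se':>8}{'OR':>7}  {'95% CI':<15}{'p':>10}")
for est in all_estimates(h, seed=7):
    lo, hi = est.or_ci
    print(f"{est.method:<16}{est.theta:>8.3f}{est.se:>8.3f}{est.odds_ratio:>7.3f}"
          f"  ({lo:.2f}, {hi:.2f}) {est.pvalue:>10.2e}")

print(f"\ntrue theta = {truth.theta} (OR {np.exp(truth.theta):.3f}); every method's"
      "\nCI should cover it -- with valid instruments all four agree.")
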