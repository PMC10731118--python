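"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data a two-sample MR study actually consumes:
per-SNP effect estimates with sampling noise, not individual genotypes.
For J independent instruments with effect-allele frequencies ƒ_j, true
SNP-exposure effects γ_j (SD units) and pleiotropic direct effects α_j
(log-odds units), and a true causal effect θ:

* exposure estimates   β_Xj ~ N(γ_j, σ_Xj),  σ_Xj = 1/√(2 n_X ƒ_j(1−ƒ_j))
* outcome estimates    β_Yj ~ N(θγ_j + α_j, σ_Yj),
  σ_Yj = 1/√(2 n_Y K(1−K) ƒ_j(1−ƒ_j)),  K = cases/(cases+controls)

— the standard standardized-trait and case-control log-odds variance
approximations, which make the analytic power formula directly comparable
to empirical power on these data. Instruments are simulated independent
(a post-clumping world); :func:`ld_block` exists solely to exercise the
clumping and proxy-search code.

Pleiotropy modes encode the classic violations of the exclusion
restriction: ``balanced`` (zero-mean direct effects), ``directional``
(one-signed), ``inside_violating`` (direct effects proportional to γ, a
coherent contaminating cluster violating InSIDE), ``outliers`` (a few
gross offsets in units of σ_Y).

Default cohort sizes follow the adolescent-idiopathic-scoliosis study
setting the package targets: a case-control outcome GWAS of 5,327 cases
and 73,884 controls, an exposure GWAS of n = 300,000, and instruments
explaining 8% of the exposure variance in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import HarmonizedSet, SummaryTable, harmonize

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating", "outliers")

#: Default study conditions (see module docstring).
DEFAULT_N_EXPOSURE = 300_000
DEFAULT_N_CASES = 5_327
DEFAULT_N_CONTROLS = 73_884
DEFAULT_TOTAL_R2 = 0.08


@dataclass
class TrueModel:
    """Ground-truth parameters of a simulated two-sample study."""

    theta: float
    J: int
    pleiotropy_mode: str = "none"
    tau: float = 0.0
    prop_invalid: float = 0.0
    outlier_scale: float = 10.0
    total_r2: float = DEFAULT_TOTAL_R2
    n_exposure: int = DEFAULT_N_EXPOSURE
    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    gamma: np.ndarray | None = None
    alpha: np.ndarray | None = None
    eaf: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if self.J < 1:
            raise ConfigurationError(f"J must be >= 1, got {self.J}")
        if not (0 <= self.prop_invalid <= 1):
            raise ConfigurationError(f"prop_invalid must be in [0, 1], got {self.prop_invalid}")
        if self.prop_invalid > 0 and self.pleiotropy_mode == "none":
            raise ConfigurationError("prop_invalid > 0 requires a pleiotropy mode")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)

    @property
    def n_invalid(self) -> int:
        if self.pleiotropy_mode == "none":
            return 0
        return math.ceil(self.prop_invalid * self.J)


@dataclass
class SimulatedStudy:
    """Exposure and outcome summary tables plus the generating truth."""

    exposure: SummaryTable
    outcome: SummaryTable
    truth: TrueModel
    gamma: np.ndarray = field(repr=False, default=None)
    alpha: np.ndarray = field(repr=False, default=None)
    invalid_ids: list[str] = field(default_factory=list)

    def harmonized(self, **kwargs) -> HarmonizedSet:
        """Harmonize the pair (alleles are aligned by construction)."""
        return harmonize(self.exposure, self.outcome, **kwargs)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)


def _table(ids, chrom, pos, eaf, beta, se, p, label, trait_type, gwas_n, n_cases=None, n_controls=None):
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": gwas_n,
            "n_cases": n_cases,
            "n_controls": n_controls,
        }
    )
    return SummaryTable(label, trait_type, df, gwas_n)


def simulate_two_sample(truth: TrueModel) -> SimulatedStudy:
    """Draw one two-sample study; fully determined by ``truth.seed``."""
    if truth.seed is None:
        raise ConfigurationError("TrueModel.seed must be set (no silent global RNG)")
    rng = np.random.default_rng(truth.seed)
    j = truth.J

    eaf = truth.eaf if truth.eaf is not None else rng.uniform(0.05, 0.5, size=j)
    het = 2.0 * eaf * (1.0 - eaf)

    if truth.gamma is not None:
        gamma = np.asarray(truth.gamma, dtype=float)
    else:
        per_snp_r2 = (truth.total_r2 / j) * rng.uniform(0.5, 1.5, size=j)
        gamma = np.sqrt(per_snp_r2 / het)

    k = truth.case_fraction
    n_out = truth.n_cases + truth.n_controls
    se_x = 1.0 / np.sqrt(truth.n_exposure * het)
    se_y = 1.0 / np.sqrt(n_out * k * (1.0 - k) * het)

    n_invalid = truth.n_invalid
    invalid = rng.choice(j, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    if truth.alpha is not None:
        alpha = np.asarray(truth.alpha, dtype=float)
    else:
        alpha = np.zeros(j)
        mode, tau = truth.pleiotropy_mode, truth.tau
        if mode == "balanced":
            alpha[invalid] = rng.normal(0.0, tau, size=n_invalid)
        elif mode == "directional":
            alpha[invalid] = rng.uniform(0.0, tau, size=n_invalid)
        elif mode == "inside_violating":
            # direct effect proportional to instrument strength: the invalid
            # SNPs form a coherent cluster at ratio theta + tau.
            alpha[invalid] = tau * gamma[invalid]
        elif mode == "outliers":
            alpha[invalid] = truth.outlier_scale * se_y[invalid]

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(truth.theta * gamma + alpha, se_y)

    ids = [f"rs{i+1:06d}" for i in range(j)]
    chrom = [str(1 + (i % 22)) for i in range(j)]
    pos = [1_000_000 + 5_000_000 * (i // 22) for i in range(j)]

    exposure = _table(
        ids, chrom, pos, eaf, beta_x, se_x, _two_sided_p(beta_x, se_x),
        "simulated_exposure", "continuous", truth.n_exposure,
    )
    outcome = _table(
        ids, chrom, pos, eaf, beta_y, se_y, _two_sided_p(beta_y, se_y),
        "simulated_outcome", "binary", n_out, truth.n_cases, truth.n_controls,
    )
    return SimulatedStudy(
        exposure, outcome, truth, gamma=gamma, alpha=alpha,
        invalid_ids=[ids[i] for i in sorted(invalid)],
    )


SCENARIOS: dict[str, dict] = {
    "null_valid": dict(theta=0.0, J=50, pleiotropy_mode="none"),
    "effect_valid": dict(theta=0.3, J=100, pleiotropy_mode="none"),
    "balanced_pleiotropy": dict(
        theta=0.3, J=200, pleiotropy_mode="balanced", tau=0.03, prop_invalid=1.0
    ),
    "directional_pleiotropy": dict(
        theta=0.3, J=50, pleiotropy_mode="directional", tau=0.1, prop_invalid=0.4
    ),
    "inside_violation": dict(
        theta=0.3, J=50, pleiotropy_mode="inside_violating", tau=2.0, prop_invalid=0.3
    ),
    "planted_outliers": dict(
        theta=0.3, J=50, pleiotropy_mode="outliers", outlier_scale=10.0, prop_invalid=0.02
    ),
}


def scenario(name: str, **overrides) -> TrueModel:
    """Preset ground-truth models for the standard study conditions.

    ``mediation_pair`` is a two-exposure structure; use
    :func:`mediation_pair` for it.
    """
    if name == "mediation_pair":
        raise ConfigurationError("use mediation_pair() for the two-exposure scenario")
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)} or 'mediation_pair'"
        )
    params = {**SCENARIOS[name], **overrides}
    return TrueModel(**params)


@dataclass
class MediationStudy:
    """Two exposures where X2 fully mediates X1's effect on the outcome."""

    exposures: list[SummaryTable]
    outcome: SummaryTable
    theta_direct: tuple[float, float]
    mediation_coefficient: float
    seed: int


def mediation_pair(
    seed: int,
    theta2: float = 0.4,
    mediation_coefficient: float = 0.6,
    j_per_exposure: int = 30,
    total_r2: float = DEFAULT_TOTAL_R2,
    n_exposure: int = DEFAULT_N_EXPOSURE,
    n_cases: int = DEFAULT_N_CASES,
    n_controls: int = DEFAULT_N_CONTROLS,
) -> MediationStudy:
    """Simulate an exposure pair with complete mediation (X1 → X2 → Y).

    X1 has no direct outcome effect; every unit of X1 moves X2 by
    ``mediation_coefficient`` c, and X2 has direct effect ``theta2`` on the
    outcome. Univariable MR of X1 therefore sees c·θ₂, while the true direct
    effect of X1 is 0 — the pattern multivariable MR should recover.
    """
    rng = np.random.default_rng(seed)
    j = 2 * j_per_exposure
    eaf = rng.uniform(0.05, 0.5, size=j)
    het = 2.0 * eaf * (1.0 - eaf)
    per_snp_r2 = (total_r2 / j_per_exposure) * rng.uniform(0.5, 1.5, size=j)
    g = np.sqrt(per_snp_r2 / het)

    # First half instruments X1 (affecting X2 via mediation), second half X2.
    gamma1 = np.where(np.arange(j) < j_per_exposure, g, 0.0)
    gamma2 = mediation_coefficient * gamma1 + np.where(np.arange(j) >= j_per_exposure, g, 0.0)

    k = n_cases / (n_cases + n_controls)
    n_out = n_cases + n_controls
    se_x = 1.0 / np.sqrt(n_exposure * het)
    se_y = 1.0 / np.sqrt(n_out * k * (1.0 - k) * het)

    beta_1 = rng.normal(gamma1, se_x)
    beta_2 = rng.normal(gamma2, se_x)
    beta_y = rng.normal(theta2 * gamma2, se_y)  # X1 acts only through X2

    ids = [f"rs{i+1:06d}" for i in range(j)]
    chrom = [str(1 + (i % 22)) for i in range(j)]
    pos = [1_000_000 + 5_000_000 * (i // 22) for i in range(j)]

    e1 = _table(ids, chrom, pos, eaf, beta_1, se_x, _two_sided_p(beta_1, se_x),
                "exposure_1", "continuous", n_exposure)
    e2 = _table(ids, chrom, pos, eaf, beta_2, se_x, _two_sided_p(beta_2, se_x),
                "exposure_2", "continuous", n_exposure)
    out = _table(ids, chrom, pos, eaf, beta_y, se_y, _two_sided_p(beta_y, se_y),
                 "simulated_outcome", "binary", n_out, n_cases, n_controls)
    return MediationStudy([e1, e2], out, (0.0, theta2), mediation_coefficient, seed)


def ld_block(
    n_blocks: int,
    block_size: int,
    seed: int,
    within_r2: tuple[float, float] = (0.3, 1.0),
    n_exposure: int = DEFAULT_N_EXPOSURE,
):
    """Correlated instrument blocks for exercising clumping and proxies.

    Returns (SummaryTable, LDTable): ``n_blocks`` blocks of ``block_size``
    SNPs each; within-block pairs get r² drawn from ``within_r2``, across
    blocks r² is 0. Effects are those of the lead SNP plus noise.
    """
    from .instruments import LDTable

    rng = np.random.default_rng(seed)
    j = n_blocks * block_size
    eaf = rng.uniform(0.05, 0.5, size=j)
    het = 2.0 * eaf * (1.0 - eaf)
    se = 1.0 / np.sqrt(n_exposure * het)
    gamma = np.repeat(np.sqrt((0.001) / (2 * 0.25 * 0.75)) * rng.uniform(0.8, 1.2, n_blocks), block_size)
    beta = rng.normal(gamma, se)
    ids = [f"rs{i+1:06d}" for i in range(j)]
    chrom = [str(1 + (b % 22)) for b in range(n_blocks) for _ in range(block_size)]
    pos = [1_000_000 * (1 + b // 22) + 1_000 * i for b in range(n_blocks) for i in range(block_size)]
    table = _table(ids, chrom, pos, eaf, beta, se, _two_sided_p(beta, se),
                   "simulated_ld_exposure", "continuous", n_exposure)
    ld = LDTable()
    for b in range(n_blocks):
        for i in range(block_size):
            for k2 in range(i + 1, block_size):
                a = ids[b * block_size + i]
                c = ids[b * block_size + k2]
                ld.set(a, c, float(rng.uniform(*within_r2)))
    return table, ld
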