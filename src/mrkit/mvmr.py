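"""Multivariable MR: joint direct effects of several exposures.

With E exposures and J > E instruments, the outcome effects are regressed
jointly on the J×E matrix of exposure effects with weights 1/σ_Y² and no
intercept. Each coefficient is the *direct* effect of that exposure on the
outcome, holding the genetically predicted values of the other exposures
fixed — the summary-data analogue of multivariable two-stage least squares.
The typical use is effect modification: an exposure whose univariable MR
estimate is significant but whose multivariable coefficient collapses
toward zero acts on the outcome through (or is confounded by) the other
exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import MREstimate
from .exceptions import (
    CollinearityError,
    ConfigurationError,
    EstimationImpossibleError,
)
from .gwas_io import SummaryTable, harmonize
from .instruments import LDTable, clump, select_by_pvalue

logger = logging.getLogger(__name__)


@dataclass
class MVMRInput:
    """Per-variant exposure-effect matrix plus outcome effects.

    ``exposure_betas``/``exposure_ses`` are J×E arrays, column e belonging
    to ``exposure_labels[e]``.
    """

    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_labels: list[str]
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, dtype=float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, dtype=float))
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        j, e = self.exposure_betas.shape
        if len(self.exposure_labels) != e:
            raise ConfigurationError("exposure_labels length must match beta columns")
        if j <= e:
            raise EstimationImpossibleError(
                f"multivariable MR needs more instruments than exposures (J={j}, E={e})"
            )
        if np.any(np.all(np.isnan(self.exposure_betas), axis=1)):
            raise ConfigurationError("variant with all exposure betas missing")
        if not self.variant_ids:
            self.variant_ids = [f"snp{i+1}" for i in range(j)]

    @property
    def n_snps(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]


def _collinear_columns(xw: np.ndarray, labels: list[str]) -> list[str]:
    """Columns linearly dependent on the preceding ones (for error reporting)."""
    bad = []
    for e in range(1, xw.shape[1]):
        prev = xw[:, :e]
        col = xw[:, e]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-10 * max(1.0, np.linalg.norm(col)):
            bad.append(labels[e])
    return bad


def mvmr_ivw(inp: MVMRInput) -> list[MREstimate]:
    """Weighted zero-intercept regression of outcome betas on exposure betas.

    Weights are 1/σ_Y²; per-coefficient SEs come from the weighted normal
    equations with a multiplicative overdispersion factor floored at 1;
    p-values are two-sided normal. With one exposure this reduces to the
    (multiplicative random-effects) univariable IVW estimate.
    """
    x = inp.exposure_betas
    y = inp.beta_outcome
    w = 1.0 / inp.se_outcome**2
    j, e = x.shape

    xw = np.sqrt(w)[:, None] * x
    if np.linalg.matrix_rank(xw) < e:
        offenders = _collinear_columns(xw, inp.exposure_labels) or inp.exposure_labels
        raise CollinearityError(offenders)

    fit = sm.WLS(y, x, weights=w).fit()
    sigma = float(np.sqrt(fit.scale))  # scale estimated with J - E df
    se = np.sqrt(np.diag(fit.normalized_cov_params)) * max(1.0, sigma)

    zq = stats.norm.ppf(0.975)
    out = []
    for c in range(e):
        theta = float(fit.params[c])
        s = float(se[c])
        p = float(2.0 * stats.norm.sf(abs(theta) / s))
        out.append(
            MREstimate(
                f"mvmr_ivw[{inp.exposure_labels[c]}]",
                theta,
                s,
                theta - zq * s,
                theta + zq * s,
                p,
                j,
            )
        )
    return out


def assemble_mvmr(
    exposure_tables: list[SummaryTable],
    outcome: SummaryTable,
    ld: LDTable | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
    palindrome_policy: str = "infer_by_eaf",
) -> MVMRInput:
    """Build a joint instrument set across several exposures.

    Instruments are the union of each exposure's p-value-selected SNPs,
    clumped jointly with priority given to the smallest p across exposures,
    then harmonized to every exposure and to the outcome (orientation
    anchored on the contributing exposure's alleles). Variants missing a
    beta for any exposure are dropped and counted.
    """
    if len(exposure_tables) < 2:
        raise ConfigurationError("assemble_mvmr needs at least 2 exposures")

    selected = [select_by_pvalue(t, p_threshold) for t in exposure_tables]

    # Union with per-variant minimum p; the record (alleles, eaf, position)
    # comes from the exposure where the variant is most significant.
    best: dict[str, tuple[float, pd.Series]] = {}
    for tab in selected:
        for _, row in tab.records.iterrows():
            vid = row["variant_id"]
            if vid not in best or row["pvalue"] < best[vid][0]:
                best[vid] = (row["pvalue"], row)
    if not best:
        raise EstimationImpossibleError("no instruments pass the p-value threshold")
    union_df = pd.DataFrame([r for _, r in best.values()]).reset_index(drop=True)
    union = SummaryTable("mvmr_union", "continuous", union_df)
    if ld is not None:
        union = clump(union, ld, r2_threshold=r2_threshold, window_bp=window_bp)

    # Harmonize every table to the union's allele orientation.
    aligned: list[pd.DataFrame] = []
    for tab in exposure_tables + [outcome]:
        hs = harmonize(union, tab, palindrome_policy=palindrome_policy)
        aligned.append(
            hs.retained.set_index("variant_id")[["beta_outcome", "se_outcome"]]
        )

    common = aligned[0].index
    for a in aligned[1:]:
        common = common.intersection(a.index)
    n_dropped = len(union) - len(common)
    if n_dropped:
        logger.info("%d union variants missing a beta in some table; dropped", n_dropped)
    if len(common) == 0:
        raise EstimationImpossibleError("no variant is present in every table")
    common = sorted(common)

    betas = np.column_stack([a.loc[common, "beta_outcome"] for a in aligned[:-1]])
    ses = np.column_stack([a.loc[common, "se_outcome"] for a in aligned[:-1]])
    return MVMRInput(
        exposure_betas=betas,
        exposure_ses=ses,
        beta_outcome=aligned[-1].loc[common, "beta_outcome"].to_numpy(),
        se_outcome=aligned[-1].loc[common, "se_outcome"].to_numpy(),
        exposure_labels=[t.trait_label for t in exposure_tables],
        variant_ids=list(common),
    )
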