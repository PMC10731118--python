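"""Statistical power for binary-outcome two-sample MR.

For a case-control outcome GWAS with N individuals, case fraction
K = cases/N, and instruments explaining a fraction R² of the exposure's
variance, the power to detect a causal odds ratio OR at significance α is
driven by a noncentrality parameter. Two conventions are implemented:

* ``formula="attenuated"`` (default) — the standard MR power-calculator
  convention for binary outcomes. The causal effect is mapped to a
  risk-difference slope b = K·(OR/(1 + K·(OR−1)) − 1) per SD of exposure,
  with sampling variance v = (K(1−K) − b²)/(N·R²); the Wald statistic b²/v
  is referred to a (noncentral) χ²₁. This accounts for the attenuation of
  the linear-scale slope at a rare-outcome case fraction.
* ``formula="log_or"`` — the log-odds approximation
  power = Φ(|ln OR|·√(N·R²·K(1−K)) − z_{1−α/2}), which is the exact power
  of the IVW z-test when summary statistics are generated on the log-odds
  scale (so it matches this package's synthetic-data generator).

``sided`` switches between a two-sided α (default) and a one-sided α; both
use the one-tail power approximation (the rejection probability in the
wrong direction is ignored, negligible at usable power levels).

:func:`min_detectable_or` inverts the power function for the smallest
OR > 1 reaching a target power (default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import ConfigurationError, DomainError

FORMULAS = ("attenuated", "log_or")
SIDES = ("two", "one")


@dataclass
class PowerSpec:
    """Inputs of a binary-outcome MR power calculation."""

    n_total: int
    n_cases: int
    total_r2: float
    alpha: float = 0.05
    target_power: float = 0.80
    or_value: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_total):
            raise DomainError(
                f"need 0 < n_cases < n_total, got {self.n_cases}/{self.n_total}"
            )
        if not (0 < self.total_r2 < 1):
            raise DomainError(f"total_r2 must be in (0, 1), got {self.total_r2}")
        if not (0 < self.alpha < 1):
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (self.alpha < self.target_power < 1):
            raise DomainError(
                f"target_power must be in (alpha, 1), got {self.target_power}"
            )
        if self.or_value is not None and self.or_value <= 0:
            raise DomainError(f"or_value must be > 0, got {self.or_value}")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def _check_options(formula: str, sided: str) -> None:
    if formula not in FORMULAS:
        raise ConfigurationError(f"formula must be one of {FORMULAS}, got {formula!r}")
    if sided not in SIDES:
        raise ConfigurationError(f"sided must be one of {SIDES}, got {sided!r}")


def _ncp(spec: PowerSpec, or_value: float, formula: str) -> float:
    k = spec.case_fraction
    if formula == "log_or":
        b = np.log(or_value)
        return b * b * spec.n_total * spec.total_r2 * k * (1.0 - k)
    b = k * (or_value / (1.0 + k * (or_value - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (spec.n_total * spec.total_r2)
    if v <= 0:
        raise DomainError("degenerate spec: implied sampling variance <= 0")
    return b * b / v


def mr_power_binary(
    spec: PowerSpec,
    or_value: float | None = None,
    formula: str = "attenuated",
    sided: str = "two",
) -> float:
    """Power to detect ``or_value`` (falls back to ``spec.or_value``)."""
    _check_options(formula, sided)
    orv = or_value if or_value is not None else spec.or_value
    if orv is None:
        raise ConfigurationError("an odds ratio is required (spec.or_value or or_value)")
    if orv <= 0:
        raise DomainError(f"odds ratio must be > 0, got {orv}")
    ncp = _ncp(spec, orv, formula)
    if formula == "attenuated" and sided == "two":
        # Wald chi-square with 1 df; exact noncentral chi-square power.
        thresh = stats.chi2.ppf(1.0 - spec.alpha, 1)
        return float(stats.ncx2.sf(thresh, 1, ncp)) if ncp > 0 else float(spec.alpha)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2 if sided == "two" else 1.0 - spec.alpha)
    return float(stats.norm.cdf(np.sqrt(ncp) - z_crit))


def min_detectable_or(
    spec: PowerSpec,
    formula: str = "attenuated",
    sided: str = "two",
) -> float:
    """Smallest OR > 1 reaching ``spec.target_power``, by root bracketing."""
    _check_options(formula, sided)

    def gap(or_value: float) -> float:
        return mr_power_binary(spec, or_value, formula=formula, sided=sided) - spec.target_power

    lo, hi = 1.0 + 1e-9, 2.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise DomainError("no detectable OR below 1e6; spec is degenerate")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-8))


def min_detectable_or_closed_form(
    spec: PowerSpec,
    formula: str = "attenuated",
    sided: str = "two",
) -> float:
    """Closed-form minimal OR from the normal approximation.

    For ``log_or``: ln OR = (z_{1−α(/2)} + z_{power})/√(N·R²·K(1−K)).
    For ``attenuated`` the required noncentrality (z_{1−α(/2)} + z_{power})²
    is inverted analytically through the risk-difference mapping.
    """
    _check_options(formula, sided)
    k = spec.case_fraction
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2 if sided == "two" else 1.0 - spec.alpha)
    z_pow = stats.norm.ppf(spec.target_power)
    ncp = (z_crit + z_pow) ** 2
    nr2 = spec.n_total * spec.total_r2
    if formula == "log_or":
        return float(np.exp((z_crit + z_pow) / np.sqrt(nr2 * k * (1.0 - k))))
    b = np.sqrt(ncp * k * (1.0 - k) / (nr2 + ncp))
    r = 1.0 + b / k
    return float(r * (1.0 - k) / (1.0 - r * k))
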