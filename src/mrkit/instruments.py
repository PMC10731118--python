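"""Instrument selection and strength metrics.

Instruments for two-sample MR are SNPs passing a genome-wide significance
threshold on the exposure, pruned for linkage disequilibrium (LD clumping)
so that no retained pair is correlated above an r² threshold. Instrument
strength is summarised by the variance explained per SNP,
R² ≈ 2·β²·ƒ·(1−ƒ) for a standardized trait, and by the F-statistic

    F = (R²/k) / ((1 − R²)/(n − k − 1)),

with F ≤ 10 conventionally flagging a weak instrument. LD information comes
from a local pairwise r² table (absent pairs are treated as independent,
appropriate for published GWAS instruments that are mostly distant or
inter-chromosomal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, EstimationImpossibleError
from .gwas_io import HarmonizedSet, SummaryTable

logger = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0


class LDTable:
    """Symmetric sparse map (variant_a, variant_b) → r².

    Pairs not present are independent (r² = 0). The diagonal is implicitly 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ConfigurationError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b and r2 != 1.0:
            raise ConfigurationError(f"r2({a},{a}) must be 1")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read(cls, path, sep: str | None = None) -> "LDTable":
        """Read a three-column delimited file (id_a, id_b, r2)."""
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        cols = list(df.columns[:3])
        t = cls()
        for a, b, r2 in df[cols].itertuples(index=False):
            t.set(str(a), str(b), float(r2))
        return t

    def write(self, path, sep: str = "\t") -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(
            path, sep=sep, index=False, float_format="%.12g"
        )


def select_by_pvalue(table: SummaryTable, threshold: float) -> SummaryTable:
    """Retain records with p strictly below ``threshold``; order preserved."""
    if not (0 < threshold <= 1):
        raise ConfigurationError(f"p-value threshold must be in (0, 1], got {threshold}")
    mask = table.records["pvalue"].to_numpy(dtype=float) < threshold
    return table.subset(mask)


def clump(
    table: SummaryTable,
    ld: LDTable,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> SummaryTable:
    """Greedy LD clumping with p-value priority.

    Repeatedly take the remaining record with the smallest p-value (ties
    broken by lexicographic variant_id), emit it, and discard remaining
    records on the same chromosome within ``window_bp`` whose r² with it is
    at or above ``r2_threshold``. Records with unknown chromosome or
    position are pruned on r² alone (conservative).
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    df = table.records
    order = sorted(
        range(len(df)),
        key=lambda i: (df["pvalue"].iat[i], df["variant_id"].iat[i]),
    )
    chrom = df["chromosome"].astype(str).to_numpy()
    pos = pd.to_numeric(df["position"], errors="coerce").to_numpy(dtype=float)
    vid = df["variant_id"].to_numpy()

    kept: list[int] = []
    removed = np.zeros(len(df), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        kept.append(i)
        for j in order:
            if j == i or removed[j]:
                continue
            if ld.r2(vid[i], vid[j]) < r2_threshold:
                continue
            loc_known = (
                chrom[i] not in ("nan", "None", "")
                and chrom[j] not in ("nan", "None", "")
                and math.isfinite(pos[i])
                and math.isfinite(pos[j])
            )
            if loc_known:
                in_window = chrom[i] == chrom[j] and abs(pos[i] - pos[j]) <= window_bp
            else:
                in_window = True
            if in_window:
                removed[j] = True
    kept_mask = np.zeros(len(df), dtype=bool)
    kept_mask[kept] = True
    return table.subset(kept_mask)


def find_proxies(
    missing: list[str],
    ld: LDTable,
    candidates: SummaryTable,
    min_r2: float = 0.7,
) -> dict[str, str | None]:
    """Best LD proxy among ``candidates`` for each missing variant.

    Returns, per missing variant, the candidate with maximal r² ≥ ``min_r2``
    (ties resolved by lexicographically smallest id), or None.
    """
    cand_ids = candidates.variant_ids
    result: dict[str, str | None] = {}
    for m in missing:
        best: str | None = None
        best_r2 = -1.0
        for c in sorted(cand_ids):
            if c == m:
                continue
            r2 = ld.r2(m, c)
            if r2 >= min_r2 and r2 > best_r2:
                best, best_r2 = c, r2
        result[m] = best
    return result


def variance_explained(beta: float, eaf: float) -> float:
    """Per-SNP variance explained for a standardized trait: 2·β²·ƒ·(1−ƒ)."""
    if not (0 < eaf < 1):
        raise DomainError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def f_statistic(total_r2: float, k: int, n: int) -> float:
    """Instrument-strength F-statistic (R²/k) / ((1−R²)/(n−k−1))."""
    if not (0 <= total_r2 < 1):
        raise DomainError(f"total_r2 must be in [0, 1), got {total_r2}")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise DomainError(f"need n > k + 1, got n={n}, k={k}")
    return (total_r2 / k) / ((1.0 - total_r2) / (n - k - 1))


@dataclass
class InstrumentSet:
    """Harmonized instruments with strength metrics.

    ``per_snp_r2`` / ``total_r2`` / ``f_stat`` are None when any instrument
    lacks an effect-allele frequency (never fabricated).
    """

    harmonized: HarmonizedSet
    k: int
    exposure_gwas_n: int | None
    per_snp_r2: list[float] | None = None
    total_r2: float | None = None
    f_stat: float | None = None
    weak: bool | None = field(default=None)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.harmonized.retained["variant_id"])


def build_instrument_set(
    harmonized: HarmonizedSet,
    exposure_gwas_n: int | None = None,
    exposure_eafs: dict[str, float] | None = None,
) -> InstrumentSet:
    """Attach R², k and F to a harmonized instrument set.

    Frequencies default to the harmonized exposure EAF column; an explicit
    ``exposure_eafs`` mapping (variant_id → ƒ) overrides it. If any
    instrument's frequency is missing, R² and F are reported as unavailable.
    """
    ret = harmonized.retained
    k = len(ret)
    if k == 0:
        raise EstimationImpossibleError("no retained instruments")

    eafs = []
    for r in ret.itertuples(index=False):
        f = None
        if exposure_eafs is not None and r.variant_id in exposure_eafs:
            f = exposure_eafs[r.variant_id]
        elif isinstance(r.eaf_exposure, float) and math.isfinite(r.eaf_exposure):
            f = r.eaf_exposure
        eafs.append(f)

    if any(f is None for f in eafs) or exposure_gwas_n is None:
        if any(f is None for f in eafs):
            logger.warning("missing EAF for some instruments; R2/F unavailable")
        return InstrumentSet(harmonized, k, exposure_gwas_n)

    per_snp = [
        variance_explained(b, f)
        for b, f in zip(ret["beta_exposure"].to_numpy(dtype=float), eafs)
    ]
    total = float(sum(per_snp))
    if total >= 1:
        raise DomainError(f"total R2 {total:.3f} >= 1; betas are not in SD units?")
    f_stat = f_statistic(total, k, exposure_gwas_n)
    weak = f_stat <= WEAK_INSTRUMENT_F
    if weak:
        logger.warning("weak instrument: F = %.2f <= %.0f", f_stat, WEAK_INSTRUMENT_F)
    return InstrumentSet(harmonized, k, exposure_gwas_n, per_snp, total, f_stat, weak)
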