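"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization joins per-variant association estimates
from an exposure GWAS and an outcome GWAS. Before any estimation the two
tables must be *harmonized*: the outcome effect must be expressed for the
same effect allele as the exposure effect. This module provides

* :class:`SummaryTable` — a validated per-variant summary-statistics table;
* :func:`read_summary_table` / :func:`write_summary_table` — delimited-text
  I/O with configurable header names (the GWAS-SSF column vocabulary is
  recognised out of the box);
* :func:`harmonize` — allele alignment including strand-complement repair
  and frequency-based orientation of palindromic (A/T, C/G) variants.

Alleles are arbitrary-length strings over {A,C,G,T} so indels are allowed;
strand complementing is only ever applied to single-base alleles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EstimationImpossibleError,
    InputError,
)

logger = logging.getLogger(__name__)

#: Canonical column order used by :func:`write_summary_table`.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
    "n_controls",
]

MANDATORY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: Alternative header names accepted without an explicit column_map
#: (GWAS-SSF vocabulary plus a few widespread variants).
DEFAULT_SYNONYMS: Mapping[str, Sequence[str]] = {
    "variant_id": ("variant_id", "rsid", "snp", "rs_id", "markername", "id"),
    "chromosome": ("chromosome", "chr", "chrom"),
    "position": ("position", "base_pair_location", "pos", "bp"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "non_effect_allele"),
    "eaf": ("eaf", "effect_allele_frequency", "freq", "maf", "af"),
    "beta": ("beta", "effect", "b"),
    "se": ("se", "standard_error", "stderr"),
    "pvalue": ("pvalue", "p_value", "p", "pval"),
    "n": ("n", "sample_size", "n_total"),
    "n_cases": ("n_cases", "ncase", "n_case", "cases"),
    "n_controls": ("n_controls", "ncontrol", "n_control", "controls"),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VALID_TRAIT_TYPES = ("continuous", "binary")

#: Harmonization actions; only the first three participate in estimation.
RETAINED_ACTIONS = ("kept", "sign_flipped", "palindromic_inferred")
DROPPED_ACTIONS = ("dropped_palindromic", "dropped_incompatible")


def _is_valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) > 0 and all(c in "ACGT" for c in a)


def _complement(allele: str) -> str | None:
    """Strand complement for single-base alleles; None for indels."""
    if len(allele) != 1:
        return None
    return _COMPLEMENT[allele]


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT[ea] == oa


@dataclass
class SummaryTable:
    """One GWAS's per-variant association records.

    Parameters
    ----------
    trait_label
        Human-readable trait name.
    trait_type
        ``"continuous"`` (beta in SD units) or ``"binary"`` (beta = log odds
        ratio).
    records
        DataFrame with the :data:`CANONICAL_COLUMNS`; ``variant_id`` unique.
    gwas_n
        Total GWAS sample size (the *n* entering the F-statistic).
    """

    trait_label: str
    trait_type: str
    records: pd.DataFrame
    gwas_n: int | None = None
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in VALID_TRAIT_TYPES:
            raise ConfigurationError(
                f"trait_type must be one of {VALID_TRAIT_TYPES}, got {self.trait_type!r}"
            )
        df = self.records.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.records = df[CANONICAL_COLUMNS].reset_index(drop=True)
        dup = self.records["variant_id"][self.records["variant_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate variant_id: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records["variant_id"])

    def subset(self, mask_or_ids) -> "SummaryTable":
        """New table restricted to a boolean mask or an id collection."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            len(mask_or_ids) == len(self.records)
            and pd.api.types.is_bool_dtype(np.asarray(mask_or_ids))
        ):
            sub = self.records[np.asarray(mask_or_ids)]
        else:
            ids = set(mask_or_ids)
            sub = self.records[self.records["variant_id"].isin(ids)]
        return SummaryTable(self.trait_label, self.trait_type, sub, self.gwas_n)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into (valid rows, rejects-with-reasons)."""
    reasons: list[tuple[object, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        problems = []
        ea, oa = row.effect_allele, row.other_allele
        if not _is_valid_allele(ea) or not _is_valid_allele(oa):
            problems.append("invalid allele string")
        elif ea == oa:
            problems.append("effect_allele equals other_allele")
        if not (isinstance(row.beta, (int, float)) and math.isfinite(row.beta)):
            problems.append("non-finite beta")
        se = row.se
        if not (isinstance(se, (int, float)) and math.isfinite(se) and se > 0):
            problems.append("se must be finite and > 0")
        p = row.pvalue
        if not (isinstance(p, (int, float)) and math.isfinite(p) and 0 < p <= 1):
            problems.append("pvalue must be in (0, 1]")
        eaf = row.eaf
        if eaf is not None and not (isinstance(eaf, float) and math.isnan(eaf)):
            if not (0 < eaf < 1):
                problems.append("eaf outside (0, 1)")
        if problems:
            keep[i] = False
            reasons.append((row.variant_id, "; ".join(problems)))
            logger.warning("rejecting %s: %s", row.variant_id, "; ".join(problems))
    rejects = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    return df[keep].reset_index(drop=True), rejects


def read_summary_table(
    path,
    trait_label: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    gwas_n: int | None = None,
    sep: str | None = None,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical field names (``beta``, ``se``, ...) to the
    file's header names; headers matching the GWAS-SSF vocabulary are
    resolved automatically. Rows violating the per-record invariants are
    dropped, logged, and kept in ``table.rejected`` with a reason.
    """
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    lower = {c.lower(): c for c in raw.columns}

    resolved: dict[str, str] = {}
    column_map = dict(column_map or {})
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            if column_map[canon] not in raw.columns:
                raise ConfigurationError(
                    f"column_map names {column_map[canon]!r} for {canon!r}, "
                    f"not present in {path}"
                )
            resolved[canon] = column_map[canon]
            continue
        for syn in DEFAULT_SYNONYMS.get(canon, (canon,)):
            if syn in lower:
                resolved[canon] = lower[syn]
                break

    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise ConfigurationError(f"cannot resolve mandatory columns {missing} in {path}")

    df = pd.DataFrame({canon: raw[col] for canon, col in resolved.items()})
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("eaf", "beta", "se", "pvalue"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    valid, rejects = _validate_rows(df)
    table = SummaryTable(trait_label, trait_type, valid, gwas_n)
    table.rejected = rejects
    return table


def write_summary_table(table: SummaryTable, path, sep: str = "\t") -> None:
    """Write a table as delimited text; floats round-trip exactly."""
    df = table.records
    for col in ("beta", "se"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InputError(f"non-finite {col} in table; refusing to write")
    out = df.copy()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass
class HarmonizedSet:
    """Exposure/outcome records joined on variant with alleles aligned.

    ``frame`` holds one row per joined variant with a ``harmonization_action``
    column; :attr:`retained` restricts to rows that participate in
    estimation (kept / sign_flipped / palindromic_inferred).
    """

    frame: pd.DataFrame
    n_unmatched_exposure: int = 0
    n_unmatched_outcome: int = 0

    COLUMNS = [
        "variant_id",
        "chromosome",
        "position",
        "effect_allele",
        "other_allele",
        "beta_exposure",
        "se_exposure",
        "beta_outcome",
        "se_outcome",
        "eaf_exposure",
        "eaf_outcome",
        "harmonization_action",
    ]

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        ret = self.retained
        for col in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            vals = ret[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise InputError(f"retained harmonized rows contain non-finite {col}")
        for col in ("se_exposure", "se_outcome"):
            if np.any(ret[col].to_numpy(dtype=float) <= 0):
                raise InputError(f"retained harmonized rows contain {col} <= 0")

    @property
    def retained(self) -> pd.DataFrame:
        return self.frame[self.frame["harmonization_action"].isin(RETAINED_ACTIONS)]

    @property
    def n_retained(self) -> int:
        return int(len(self.retained))

    def __len__(self) -> int:
        return self.n_retained

    @property
    def action_counts(self) -> dict[str, int]:
        return self.frame["harmonization_action"].value_counts().to_dict()

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) for the retained rows."""
        r = self.retained
        return (
            r["beta_exposure"].to_numpy(dtype=float),
            r["se_exposure"].to_numpy(dtype=float),
            r["beta_outcome"].to_numpy(dtype=float),
            r["se_outcome"].to_numpy(dtype=float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        eaf=None,
        variant_ids=None,
    ) -> "HarmonizedSet":
        """Build an already-aligned set directly from effect arrays."""
        bx = np.asarray(beta_exposure, dtype=float)
        j = len(bx)
        ids = list(variant_ids) if variant_ids is not None else [f"snp{i+1}" for i in range(j)]
        frame = pd.DataFrame(
            {
                "variant_id": ids,
                "chromosome": ["1"] * j,
                "position": np.arange(1, j + 1),
                "effect_allele": ["A"] * j,
                "other_allele": ["G"] * j,
                "beta_exposure": bx,
                "se_exposure": np.asarray(se_exposure, dtype=float),
                "beta_outcome": np.asarray(beta_outcome, dtype=float),
                "se_outcome": np.asarray(se_outcome, dtype=float),
                "eaf_exposure": np.asarray(eaf, dtype=float) if eaf is not None else np.nan,
                "eaf_outcome": np.asarray(eaf, dtype=float) if eaf is not None else np.nan,
                "harmonization_action": ["kept"] * j,
            }
        )
        return cls(frame)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per variant.

    Variants are joined on ``variant_id``. Per variant:

    * same allele coding → kept unchanged;
    * swapped alleles → outcome beta negated, eaf replaced by 1 − eaf;
    * strand-complement coding (single-base alleles) → complemented, then
      aligned as above;
    * palindromic variants (A/T or C/G) cannot be resolved from alleles:
      under ``infer_by_eaf`` the orientation is chosen so both frequencies
      fall on the same side of 0.5, and the variant is dropped if either
      frequency is missing or lies inside ``eaf_ambiguity_window``;
      under ``drop_all`` every palindromic variant is dropped;
    * any other allele combination → dropped as incompatible.
    """
    if palindrome_policy not in ("infer_by_eaf", "drop_all"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    lo, hi = eaf_ambiguity_window
    if not (0 <= lo <= hi <= 1):
        raise ConfigurationError("eaf_ambiguity_window must satisfy 0 <= lo <= hi <= 1")

    ex = exposure.records
    out = outcome.records
    merged = ex.merge(out, on="variant_id", how="inner", suffixes=("_exp", "_out"))
    n_unmatched_exposure = len(ex) - len(merged)
    n_unmatched_outcome = len(out) - len(merged)
    if n_unmatched_exposure:
        logger.info("%d exposure variants absent from outcome", n_unmatched_exposure)
    if n_unmatched_outcome:
        logger.info("%d outcome variants not used", n_unmatched_outcome)
    if merged.empty:
        raise EstimationImpossibleError("no shared variants between exposure and outcome")

    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_exp, r.other_allele_exp
        ea_y, oa_y = r.effect_allele_out, r.other_allele_out
        beta_y, eaf_y = r.beta_out, r.eaf_out
        eaf_x = r.eaf_exp

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                action = "dropped_incompatible"
            elif palindrome_policy == "drop_all":
                action = "dropped_palindromic"
            else:
                eaf_missing = not (isinstance(eaf_x, float) and math.isfinite(eaf_x)) or not (
                    isinstance(eaf_y, float) and math.isfinite(eaf_y)
                )
                ambiguous = eaf_missing or (lo <= eaf_x <= hi) or (lo <= eaf_y <= hi)
                if ambiguous:
                    action = "dropped_palindromic"
                else:
                    # Allele labels carry no strand information here: orient
                    # purely so both frequencies sit on the same side of 0.5.
                    if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                        beta_y = -beta_y
                        eaf_y = 1.0 - eaf_y
                    action = "palindromic_inferred"
        else:
            cea, coa = _complement(ea_y), _complement(oa_y)
            if (ea_y, oa_y) == (ea_x, oa_x):
                action = "kept"
            elif (ea_y, oa_y) == (oa_x, ea_x):
                action = "sign_flipped"
            elif cea is not None and (cea, coa) == (ea_x, oa_x):
                action = "kept"
            elif cea is not None and (cea, coa) == (oa_x, ea_x):
                action = "sign_flipped"
            else:
                action = "dropped_incompatible"
            if action == "sign_flipped":
                beta_y = -beta_y
                if isinstance(eaf_y, float) and math.isfinite(eaf_y):
                    eaf_y = 1.0 - eaf_y

        rows.append(
            {
                "variant_id": r.variant_id,
                "chromosome": r.chromosome_exp,
                "position": r.position_exp,
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "beta_exposure": r.beta_exp,
                "se_exposure": r.se_exp,
                "beta_outcome": beta_y,
                "se_outcome": r.se_out,
                "eaf_exposure": eaf_x,
                "eaf_outcome": eaf_y,
                "harmonization_action": action,
            }
        )

    frame = pd.DataFrame(rows, columns=HarmonizedSet.COLUMNS)
    hs = HarmonizedSet(frame, n_unmatched_exposure, n_unmatched_outcome)
    if hs.n_retained == 0:
        raise EstimationImpossibleError("all joined variants were dropped in harmonization")
    return hs
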