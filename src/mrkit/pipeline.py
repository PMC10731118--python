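"""Study orchestration: per exposure-outcome pair, run the full MR chain.

``run_mr_study`` mirrors the standard reporting layout of two-sample MR
studies: one row per (exposure, method) with OR, 95% CI, p, number of
SNPs, instrument R² and F, the MR-Egger intercept p and Cochran's Q p.
Fixed-effects IVW is the headline method; a multiplicative random-effects
IVW row is added whenever Q's p-value falls below 0.05. MR-Egger, weighted
median and weighted mode run with 3+ instruments, MR-PRESSO with 4+, and
multivariable MR for any configured adjustment sets. A failure in one
exposure is reported in that exposure's rows without aborting the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, presso
from .exceptions import ConfigurationError, MRKitError
from .gwas_io import SummaryTable, harmonize, read_summary_table
from .instruments import (
    LDTable,
    build_instrument_set,
    clump,
    find_proxies,
    select_by_pvalue,
)
from .mvmr import assemble_mvmr, mvmr_ivw

logger = logging.getLogger(__name__)

HETEROGENEITY_TRIGGER_P = 0.05

#: Fixed column order of the per-method report table.
REPORT_COLUMNS = [
    "exposure",
    "method",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "pvalue",
    "n_snps",
    "r2",
    "f_statistic",
    "egger_intercept_pvalue",
    "cochran_q_pvalue",
    "theta",
    "se",
    "note",
]


@dataclass
class ExposureSpec:
    path: str
    label: str
    trait_type: str = "continuous"
    gwas_n: int | None = None
    p_threshold: float = 5e-8
    column_map: dict | None = None


@dataclass
class OutcomeSpec:
    path: str
    label: str = "outcome"
    n_cases: int | None = None
    n_controls: int | None = None
    column_map: dict | None = None


@dataclass
class StudyConfig:
    exposures: list[ExposureSpec]
    outcome: OutcomeSpec
    seed: int
    ld_path: str | None = None
    r2_threshold: float = 0.001
    window_bp: int = 10_000_000
    proxy_min_r2: float = 0.7
    palindrome_policy: str = "infer_by_eaf"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_significance: float = 0.05
    run_presso: bool = True
    mvmr_adjustments: list[list[str]] = field(default_factory=list)
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
            outcome = OutcomeSpec(**raw.pop("outcome"))
            return cls(exposures=exposures, outcome=outcome, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad study config {path}: {exc}") from exc

    def validate_paths(self) -> None:
        for e in self.exposures:
            if not Path(e.path).exists():
                raise ConfigurationError(f"exposure file not found: {e.path}")
        if not Path(self.outcome.path).exists():
            raise ConfigurationError(f"outcome file not found: {self.outcome.path}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise ConfigurationError(f"LD table not found: {self.ld_path}")


@dataclass
class StudyReport:
    rows: list[dict]
    per_snp: dict[str, pd.DataFrame]
    presso: dict[str, dict]
    log: list[str]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        for col in REPORT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        return df[REPORT_COLUMNS]


def _estimate_row(exposure_label, est, inst, q, egger_intercept_p, note=""):
    return {
        "exposure": exposure_label,
        "method": est.method,
        "odds_ratio": est.odds_ratio,
        "ci_low": est.or_ci[0],
        "ci_high": est.or_ci[1],
        "pvalue": est.pvalue,
        "n_snps": est.n_snps,
        "r2": inst.total_r2 if inst is not None else None,
        "f_statistic": inst.f_stat if inst is not None else None,
        "egger_intercept_pvalue": egger_intercept_p,
        "cochran_q_pvalue": q.pvalue if q is not None else None,
        "theta": est.theta,
        "se": est.se,
        "note": note,
    }


def _analyse_exposure(exp_spec, exposure, outcome, ld, config, seed):
    """All report rows and per-SNP diagnostics for one exposure."""
    log: list[str] = []
    selected = select_by_pvalue(exposure, exp_spec.p_threshold)
    log.append(f"{exp_spec.label}: {len(selected)}/{len(exposure)} SNPs pass "
               f"p < {exp_spec.p_threshold:g}")
    if ld is not None:
        clumped = clump(selected, ld, config.r2_threshold, config.window_bp)
        log.append(f"{exp_spec.label}: {len(clumped)}/{len(selected)} SNPs after clumping")
    else:
        clumped = selected

    # Substitute LD proxies for instruments absent from the outcome GWAS.
    outcome_ids = set(outcome.variant_ids)
    missing = [v for v in clumped.variant_ids if v not in outcome_ids]
    if missing and ld is not None:
        candidates = outcome.subset(
            [v for v in outcome.variant_ids if v in set(exposure.variant_ids)]
        )
        proxies = find_proxies(missing, ld, candidates, config.proxy_min_r2)
        kept_ids = [v for v in clumped.variant_ids if v not in missing]
        for m, p in proxies.items():
            if p is not None and p not in kept_ids:
                kept_ids.append(p)
                log.append(f"{exp_spec.label}: {m} proxied by {p}")
            elif p is None:
                log.append(f"{exp_spec.label}: {m} absent from outcome, no proxy")
        clumped = exposure.subset(kept_ids)
    elif missing:
        log.append(f"{exp_spec.label}: {len(missing)} instruments absent from outcome")

    h = harmonize(clumped, outcome, palindrome_policy=config.palindrome_policy)
    for action, count in sorted(h.action_counts.items()):
        log.append(f"{exp_spec.label}: harmonization {action}: {count}")
    inst = build_instrument_set(h, exposure_gwas_n=exp_spec.gwas_n)

    rows = []
    est, q = estimators.ivw(h)
    k = h.n_retained
    if k == 1:
        est = MREstimateAsWald(est)
    egger_p = None
    if k >= 3:
        egg = estimators.egger(h)
        egger_p = egg.intercept_pvalue
    rows.append(_estimate_row(exp_spec.label, est, inst, q, egger_p))
    if q.df > 0 and q.pvalue < HETEROGENEITY_TRIGGER_P:
        est_r, _ = estimators.ivw(h, effects="random_multiplicative")
        rows.append(_estimate_row(exp_spec.label, est_r, inst, q, egger_p,
                                  note="added because Cochran's Q p < 0.05"))
        log.append(f"{exp_spec.label}: heterogeneity detected (Q p = {q.pvalue:.3g}); "
                   "random-effects IVW added")
    if k >= 3:
        rows.append(_estimate_row(exp_spec.label, egg.slope, inst, q, egger_p))
        med = estimators.weighted_median(h, n_boot=config.n_boot, seed=seed)
        rows.append(_estimate_row(exp_spec.label, med, inst, q, egger_p))
        mode = estimators.weighted_mode(h, n_boot=config.n_boot, seed=seed + 1)
        rows.append(_estimate_row(exp_spec.label, mode, inst, q, egger_p))
    else:
        log.append(f"{exp_spec.label}: Egger/median/mode not applicable with {k} SNP(s)")

    presso_report = None
    if config.run_presso and k >= presso.MIN_INSTRUMENTS:
        pres = presso.mr_presso(h, n_sim=config.presso_n_sim, seed=seed + 2,
                                significance=config.presso_significance)
        presso_report = {
            "rss_observed": pres.rss_observed,
            "global_pvalue": pres.global_pvalue,
            "outlier_ids": pres.outlier_ids,
            "distortion_pvalue": pres.distortion_pvalue,
            "n_sim": pres.n_sim,
        }
        if pres.theta_outlier_corrected is not None:
            rows.append(_estimate_row(exp_spec.label, pres.theta_outlier_corrected,
                                      inst, q, egger_p,
                                      note=f"outliers removed: {','.join(pres.outlier_ids)}"))

    ret = h.retained
    bx = ret["beta_exposure"].to_numpy(dtype=float)
    per_snp = pd.DataFrame(
        {
            "variant_id": ret["variant_id"],
            "beta_exposure": bx,
            "se_exposure": ret["se_exposure"],
            "beta_outcome": ret["beta_outcome"],
            "se_outcome": ret["se_outcome"],
            "wald_ratio": ret["beta_outcome"].to_numpy(dtype=float) / bx,
            "ivw_weight": bx**2 / ret["se_outcome"].to_numpy(dtype=float) ** 2,
        }
    )
    return rows, per_snp, presso_report, log


def MREstimateAsWald(est):
    """Relabel a single-SNP IVW estimate as the Wald ratio it reduces to."""
    est.method = "wald"
    return est


def run_mr_study(config: StudyConfig) -> StudyReport:
    """Run the configured exposures against the outcome; never aborts on a
    single exposure's failure."""
    config.validate_paths()
    outcome = read_summary_table(
        config.outcome.path, config.outcome.label, "binary",
        column_map=config.outcome.column_map,
    )
    ld = LDTable.read(config.ld_path) if config.ld_path else None

    rows: list[dict] = []
    per_snp: dict[str, pd.DataFrame] = {}
    presso_out: dict[str, dict] = {}
    log: list[str] = []
    tables: dict[str, SummaryTable] = {}

    for i, exp_spec in enumerate(config.exposures):
        seed = config.seed + 101 * i
        try:
            exposure = read_summary_table(
                exp_spec.path, exp_spec.label, exp_spec.trait_type,
                column_map=exp_spec.column_map, gwas_n=exp_spec.gwas_n,
            )
            tables[exp_spec.label] = exposure
            r, ps, pr, lg = _analyse_exposure(exp_spec, exposure, outcome, ld, config, seed)
            rows.extend(r)
            per_snp[exp_spec.label] = ps
            if pr is not None:
                presso_out[exp_spec.label] = pr
            log.extend(lg)
        except MRKitError as exc:
            msg = f"{exp_spec.label}: estimation impossible: {exc}"
            logger.error(msg)
            log.append(msg)
            rows.append({"exposure": exp_spec.label, "method": "failed", "note": str(exc)})

    for adj_set in config.mvmr_adjustments:
        labels = list(adj_set)
        try:
            specs = {e.label: e for e in config.exposures}
            exp_tabs = [tables[lab] for lab in labels]
            thresholds = min(specs[lab].p_threshold for lab in labels)
            inp = assemble_mvmr(exp_tabs, outcome, ld, p_threshold=thresholds,
                                r2_threshold=config.r2_threshold,
                                window_bp=config.window_bp,
                                palindrome_policy=config.palindrome_policy)
            for est in mvmr_ivw(inp):
                rows.append(_estimate_row("+".join(labels), est, None, None, None,
                                          note="multivariable (direct effects)"))
            log.append(f"MVMR {'+'.join(labels)}: {inp.n_snps} joint instruments")
        except (MRKitError, KeyError) as exc:
            msg = f"MVMR {'+'.join(labels)}: failed: {exc}"
            logger.error(msg)
            log.append(msg)

    return StudyReport(rows, per_snp, presso_out, log)


def write_report(report: StudyReport, output_dir, formats=("tsv", "json")) -> list[Path]:
    """Write the report table (TSV, fixed column order), a JSON version and
    per-SNP diagnostics for scatter/forest rendering."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    df = report.frame()
    if "tsv" in formats:
        p = out / "mr_report.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)
    if "json" in formats:
        p = out / "mr_report.json"
        payload = {
            "rows": report.rows,
            "presso": report.presso,
            "log": report.log,
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
        written.append(p)
    for label, ps in report.per_snp.items():
        p = out / f"per_snp_{label.replace(' ', '_')}.tsv"
        ps.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)
    return written
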