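"""The whole chain from summary-statistics files to a report table.

Writes simulated exposure/outcome GWAS files to a temporary directory,
builds a YAML study configuration, and runs selection -> clumping ->
harmonization -> instrument strength -> all estimators -> MR-PRESSO,
producing the standard per-method report.
"""

import tempfile
from pathlib import Path

import yaml

from mrkit import (
    StudyConfig,
    run_mr_study,
    scenario,
    simulate_two_sample,
    write_report,
    write_summary_table,
)

study = simulate_two_sample(scenario("effect_valid", seed=1))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_summary_table(study.exposure, tmp / "exposure.tsv")
    write_summary_table(study.outcome, tmp / "outcome.tsv")
    cfg = {
        "exposures": [{"path": str(tmp / "exposure.tsv"), "label": "simulated_bmd",
                       "gwas_n": 300_000, "p_threshold": 5e-8}],
        "outcome": {"path": str(tmp / "outcome.tsv"), "label": "simulated_ais",
                    "n_cases": 5_327, "n_controls": 73_884},
        "seed": 42,
    }
    (tmp / "study.yaml").write_text(yaml.safe_dump(cfg))

    report = run_mr_study(StudyConfig.from_yaml(tmp / "study.yaml"))
    cols = ["exposure", "method", "odds_ratio", "ci_low", "ci_high",
            "pvalue", "n_snps", "r2", "f_statistic"]
    print(report.frame()[cols].round(4).to_string(index=False))
    print(f"\nMR-PRESSO global p = {report.presso['simulated_bmd']['global_pvalue']:.3f}")
    files = write_report(report, tmp / "out")
    print("\nreport files written:", ", ".join(f.name for f in files))

print("\none row per method; with clean simulated instruments all odds ratios"
      "\nsit near exp(0.3) ~ 1.35 and the diagnostics stay quiet.")
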