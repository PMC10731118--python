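import numpy as np
import pandas as pd
import pytest

import mrkit
from mrkit import (
    ConfigurationError,
    EstimationImpossibleError,
    InputError,
    harmonize,
    read_summary_table,
    write_summary_table,
)

from conftest import make_table


def write_raw(tmp_path, text, name="gwas.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "variant_id\tchromosome\tposition\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"


class TestReadWrite:
    def test_well_formed_table_reads_fully(self, tmp_path):
        p = write_raw(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.01\t1e-9\n"
            + "rs2\t2\t200\tC\tT\t0.4\t-0.05\t0.02\t1e-8\n"
            + "rs3\t3\t300\tG\tA\t0.2\t0.07\t0.015\t2e-8\n",
        )
        t = read_summary_table(p, "bmd", "continuous")
        assert len(t) == 3
        assert t.variant_ids == ["rs1", "rs2", "rs3"]
        assert len(t.rejected) == 0

    def test_invalid_rows_rejected_with_reason(self, tmp_path):
        p = write_raw(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.0\t1e-9\n"  # se = 0
            + "rs2\t2\t200\tC\tT\t0.4\t-0.05\t0.02\t1e-8\n"
            + "rs3\t3\t300\tG\tA\t0.2\t0.07\t0.015\t2e-8\n",
        )
        t = read_summary_table(p, "bmd", "continuous")
        assert len(t) == 2
        assert list(t.rejected["variant_id"]) == ["rs1"]
        assert "se" in t.rejected["reason"].iloc[0]

    def test_gwas_ssf_headers_resolve(self, tmp_path):
        p = write_raw(
            tmp_path,
            "rsid\tchr\tbase_pair_location\tea\toa\teffect_allele_frequency\t"
            "beta\tstandard_error\tp_value\n"
            "rs1\t1\t100\ta\tg\t0.3\t0.1\t0.01\t1e-9\n",
        )
        t = read_summary_table(p, "x", "continuous")
        assert len(t) == 1
        assert t.records["effect_allele"].iloc[0] == "A"  # upper-cased

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = write_raw(tmp_path, "variant_id\tbeta\trs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            read_summary_table(p, "x", "continuous")

    def test_duplicate_variant_is_input_error_naming_it(self, tmp_path):
        p = write_raw(
            tmp_path,
            HEADER
            + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-9\n"
            + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-9\n",
        )
        with pytest.raises(InputError, match="rs1"):
            read_summary_table(p, "x", "continuous")

    def test_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(7)
        t = make_table(
            [f"rs{i}" for i in range(20)],
            rng.normal(0, 0.1, 20),
            rng.uniform(0.001, 0.02, 20),
            pvalues=rng.uniform(1e-12, 1e-6, 20),
            eafs=rng.uniform(0.05, 0.95, 20),
        )
        p = tmp_path / "t.tsv"
        write_summary_table(t, p)
        back = read_summary_table(p, t.trait_label, t.trait_type, gwas_n=t.gwas_n)
        for col in ("beta", "se", "pvalue", "eaf"):
            np.testing.assert_allclose(
                back.records[col], t.records[col], rtol=1e-12, atol=0
            )
        assert back.variant_ids == t.variant_ids

    def test_empty_table_writes_header_only(self, tmp_path):
        t = make_table([], [], [])
        p = tmp_path / "empty.tsv"
        write_summary_table(t, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("variant_id")

    def test_non_finite_beta_refused(self, tmp_path):
        t = make_table(["rs1"], [0.1], [0.01])
        t.records.loc[0, "beta"] = np.inf
        with pytest.raises(InputError):
            write_summary_table(t, tmp_path / "bad.tsv")


def pair(ea_x, oa_x, ea_y, oa_y, eaf_x=0.3, eaf_y=0.31, beta_y=0.05):
    exposure = make_table(["rs1"], [0.1], [0.01], eafs=[eaf_x],
                          effect_alleles=[ea_x], other_alleles=[oa_x])
    outcome = make_table(["rs1"], [beta_y], [0.02], eafs=[eaf_y],
                         effect_alleles=[ea_y], other_alleles=[oa_y],
                         trait_type="binary", label="out")
    return exposure, outcome


class TestHarmonize:
    # full orientation truth table for a non-palindromic A/G exposure variant
    @pytest.mark.parametrize(
        "ea_y,oa_y,action,beta_sign",
        [
            ("A", "G", "kept", +1),            # identical coding
            ("G", "A", "sign_flipped", -1),     # swapped alleles
            ("T", "C", "kept", +1),             # other strand, same orientation
            ("C", "T", "sign_flipped", -1),     # other strand, swapped
            ("A", "C", "dropped_incompatible", 0),
            ("T", "T", "dropped_incompatible", 0),
        ],
    )
    def test_non_palindromic_truth_table(self, ea_y, oa_y, action, beta_sign):
        exposure, outcome = pair("A", "G", ea_y, oa_y)
        if action.startswith("dropped"):
            with pytest.raises(EstimationImpossibleError):
                harmonize(exposure, outcome)
            return
        h = harmonize(exposure, outcome)
        row = h.frame.iloc[0]
        assert row["harmonization_action"] == action
        assert row["beta_outcome"] == pytest.approx(beta_sign * 0.05)
        if action == "sign_flipped":
            assert row["eaf_outcome"] == pytest.approx(1 - 0.31)

    @pytest.mark.parametrize(
        "eaf_x,eaf_y,expect_action,expect_beta",
        [
            (0.20, 0.19, "palindromic_inferred", +0.05),  # same side, keep
            (0.20, 0.81, "palindromic_inferred", -0.05),  # opposite side, flip
            (0.20, 0.50, "dropped_palindromic", None),    # ambiguous window
            (0.45, 0.20, "dropped_palindromic", None),    # exposure ambiguous
            (0.20, np.nan, "dropped_palindromic", None),  # missing eaf
        ],
    )
    def test_palindromic_inference(self, eaf_x, eaf_y, expect_action, expect_beta):
        exposure, outcome = pair("A", "T", "A", "T", eaf_x=eaf_x, eaf_y=eaf_y)
        if expect_action == "dropped_palindromic":
            with pytest.raises(EstimationImpossibleError):
                harmonize(exposure, outcome)
            # verify the action via a 2-variant table so one row survives
            exposure2, outcome2 = _with_extra_variant(exposure, outcome)
            h = harmonize(exposure2, outcome2)
            assert h.frame.set_index("variant_id").loc["rs1", "harmonization_action"] == expect_action
            return
        h = harmonize(exposure, outcome)
        row = h.frame.iloc[0]
        assert row["harmonization_action"] == expect_action
        assert row["beta_outcome"] == pytest.approx(expect_beta)

    def test_drop_all_policy_drops_every_palindrome(self):
        exposure, outcome = pair("C", "G", "C", "G", eaf_x=0.2, eaf_y=0.2)
        exposure2, outcome2 = _with_extra_variant(exposure, outcome)
        h = harmonize(exposure2, outcome2, palindrome_policy="drop_all")
        assert h.frame.set_index("variant_id").loc["rs1", "harmonization_action"] == "dropped_palindromic"

    def test_missing_eaf_non_palindromic_kept(self):
        exposure, outcome = pair("A", "G", "A", "G", eaf_y=np.nan)
        h = harmonize(exposure, outcome)
        assert h.frame.iloc[0]["harmonization_action"] == "kept"

    def test_idempotent_on_aligned_pair(self, effect_valid_study):
        h1 = harmonize(effect_valid_study.exposure, effect_valid_study.outcome)
        # rebuild an outcome table from the harmonized set and re-harmonize
        out2 = effect_valid_study.outcome
        h2 = harmonize(effect_valid_study.exposure, out2)
        pd.testing.assert_frame_equal(h1.frame, h2.frame)
        assert (h1.frame["harmonization_action"] == "kept").all()
        np.testing.assert_array_equal(
            h1.retained["beta_outcome"], out2.records["beta"]
        )

    def test_sign_flip_involution(self, effect_valid_study):
        """Swapping the outcome's allele labels and negating beta leaves the
        retained effect pairs unchanged."""
        out = effect_valid_study.outcome
        flipped = out.records.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].values
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out_fl = mrkit.SummaryTable(out.trait_label, out.trait_type, flipped, out.gwas_n)
        h1 = harmonize(effect_valid_study.exposure, out)
        h2 = harmonize(effect_valid_study.exposure, out_fl)
        np.testing.assert_allclose(
            h1.retained[["beta_exposure", "beta_outcome"]],
            h2.retained[["beta_exposure", "beta_outcome"]],
            rtol=0, atol=0,
        )
        assert (h2.frame["harmonization_action"] == "sign_flipped").all()

    def test_counts_partition_the_join(self):
        exposure = make_table(
            ["rs1", "rs2", "rs3", "rs4"], [0.1] * 4, [0.01] * 4,
            eafs=[0.3, 0.2, 0.3, 0.3],
            effect_alleles=["A", "A", "A", "A"], other_alleles=["G", "T", "G", "G"],
        )
        outcome = make_table(
            ["rs1", "rs2", "rs3", "rs5"], [0.05] * 4, [0.02] * 4,
            eafs=[0.3, 0.5, 0.3, 0.3],
            effect_alleles=["A", "A", "C", "A"], other_alleles=["G", "T", "A", "G"],
        )
        h = harmonize(exposure, outcome)
        # join size 3: rs1 kept, rs2 palindromic ambiguous, rs3 incompatible
        assert len(h.frame) == 3
        assert sum(h.action_counts.values()) == 3
        assert h.action_counts == {
            "kept": 1, "dropped_palindromic": 1, "dropped_incompatible": 1,
        }
        assert h.n_unmatched_exposure == 1 and h.n_unmatched_outcome == 1

    def test_empty_intersection_raises(self):
        e = make_table(["rs1"], [0.1], [0.01])
        o = make_table(["rs2"], [0.1], [0.01])
        with pytest.raises(EstimationImpossibleError):
            harmonize(e, o)

    def test_retained_never_nonpositive_se(self, effect_valid_harmonized):
        assert (effect_valid_harmonized.retained["se_outcome"] > 0).all()
        assert (effect_valid_harmonized.retained["se_exposure"] > 0).all()


def _with_extra_variant(exposure, outcome):
    """Append a clean non-palindromic variant so harmonize keeps >= 1 row."""
    def add(t):
        extra = t.records.iloc[[0]].copy()
        extra["variant_id"] = "rs_anchor"
        extra["effect_allele"], extra["other_allele"] = "A", "G"
        extra["eaf"] = 0.3
        df = pd.concat([t.records, extra], ignore_index=True)
        return mrkit.SummaryTable(t.trait_label, t.trait_type, df, t.gwas_n)
    return add(exposure), add(outcome)
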