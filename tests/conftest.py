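import numpy as np
import pandas as pd
import pytest

from mrkit import SummaryTable, scenario, simulate_two_sample


def make_table(
    variant_ids,
    betas,
    ses,
    pvalues=None,
    eafs=None,
    effect_alleles=None,
    other_alleles=None,
    chroms=None,
    positions=None,
    label="trait",
    trait_type="continuous",
    gwas_n=100_000,
):
    """Small hand-rolled summary table for unit tests."""
    j = len(variant_ids)
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chroms if chroms is not None else ["1"] * j,
            "position": positions if positions is not None else list(range(1, j + 1)),
            "effect_allele": effect_alleles if effect_alleles is not None else ["A"] * j,
            "other_allele": other_alleles if other_alleles is not None else ["G"] * j,
            "eaf": eafs if eafs is not None else [0.3] * j,
            "beta": betas,
            "se": ses,
            "pvalue": pvalues if pvalues is not None else [1e-9] * j,
            "n": gwas_n,
            "n_cases": np.nan,
            "n_controls": np.nan,
        }
    )
    return SummaryTable(label, trait_type, df, gwas_n)


@pytest.fixture(scope="session")
def effect_valid_study():
    return simulate_two_sample(scenario("effect_valid", seed=1))


@pytest.fixture(scope="session")
def effect_valid_harmonized(effect_valid_study):
    return effect_valid_study.harmonized()
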